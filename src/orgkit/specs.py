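"""Parameter records for the synthetic outer-retina simulator.

Defaults encode the study conditions this package targets: a rodent
NIR-OCT optoretinography setup (840 nm centre wavelength, 2 um axial
resolution in tissue, 1.07 mm image depth in air over 1024 pixels) and
stimulus-locked outer-retina kinetics — a fast photoreceptor outer-segment
(OS) elongation peaking ~0.5 s after the flash with a slow undershoot, a
slow retinal-pigment-epithelium (RPE) contraction, and a delayed subretinal
space (SRS) expansion of order 250 nm peaking around 20 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class KineticsSpec:
    """Ground-truth stimulus-locked layer kinetics (all OPL values in nm).

    ``type_I_*`` parameterize the fast OS elongation signature; ``type_II_*``
    the slow RPE-referenced rise; ``srs_*`` the subretinal-space expansion;
    ``is_compression_amp`` the transient inner-segment compression;
    ``rpe_contraction_amp`` the slow RPE thinning.
    """

    type_I_amp: float = 50.0            # nm, peak OS elongation
    type_I_peak_latency: float = 0.5    # s
    type_I_undershoot_amp: float = 20.0  # nm (magnitude of negative phase)
    type_I_undershoot_latency: float = 10.0  # s
    type_I_recovery_time: float = 30.0  # s, return to baseline
    type_II_rate: float = 12.0          # nm/s initial rise rate
    type_II_onset: float = 0.5          # s
    srs_peak_amp: float = 250.0         # nm
    srs_peak_latency: float = 20.0      # s
    srs_slope: float = 15.0             # nm/s mid-rise expansion rate
    srs_onset: float = 1.5              # s
    is_compression_amp: float = 10.0    # nm
    rpe_contraction_amp: float = 20.0   # nm, peak RPE thinning
    rpe_contraction_latency: float = 3.0  # s

    def __post_init__(self) -> None:
        for name in (
            "type_I_peak_latency",
            "type_I_undershoot_latency",
            "type_I_recovery_time",
            "srs_peak_latency",
            "rpe_contraction_latency",
        ):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(
            self.srs_peak_latency > self.type_I_peak_latency,
            "SRS peak latency must exceed the Type-I peak latency",
        )
        import math

        for name in ("type_I_amp", "type_I_undershoot_amp", "type_II_rate",
                     "srs_peak_amp", "srs_slope", "is_compression_amp",
                     "rpe_contraction_amp"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")


@dataclass(frozen=True)
class MotionSpec:
    """Rigid in-plane bulk motion: slow drift plus physiological oscillations.

    The heartbeat/respiration frequencies are stand-ins at rat-physiology
    values (the artifacts are named by the acquisition context, their
    frequencies are configuration).
    """

    drift_amplitude: float = 1.5     # px peak-to-zero over the recording
    heartbeat_freq: float = 5.0      # Hz
    heartbeat_amp: float = 0.3       # px
    respiration_freq: float = 1.0    # Hz
    respiration_amp: float = 0.2     # px
    lateral_fraction: float = 0.6    # lateral motion amplitude relative to axial
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.heartbeat_freq >= 0 and self.respiration_freq >= 0,
                 "frequencies must be >= 0")
        _require(
            min(self.drift_amplitude, self.heartbeat_amp, self.respiration_amp) >= 0,
            "amplitudes must be >= 0",
        )


@dataclass(frozen=True)
class OpticsSpec:
    """Imaging-system optics and per-layer signal-to-noise ratios."""

    center_wavelength: float = 840.0         # nm
    axial_resolution_tissue: float = 2.0     # um, intensity FWHM
    axial_pixel_pitch_air: float = 1.05      # um (1.07 mm depth / 1024 px)
    lateral_beam_diameter: float = 12.2      # um, 1/e^2 width
    lateral_pixel_pitch: float = 8.0         # um (synthetic grid)
    tissue_refractive_index: float = 1.38
    snr_profile: dict | None = None          # layer name -> linear amplitude SNR

    def __post_init__(self) -> None:
        _require(self.center_wavelength > 0, "wavelength must be > 0")
        _require(
            self.axial_pixel_pitch_air < 2.0 * self.axial_resolution_tissue,
            "axial pitch must sample the PSF (pitch < 2 x resolution)",
        )

    @property
    def carrier_cycles_per_px(self) -> float:
        from .fourier import carrier_cycles_per_px

        return carrier_cycles_per_px(self.center_wavelength, self.axial_pixel_pitch_air)

    @property
    def axial_sigma_px(self) -> float:
        """Amplitude-PSF Gaussian sigma in depth pixels (air-OPL domain).

        The quoted axial resolution is the round-trip coherence length,
        i.e. the FWHM of the amplitude envelope; tissue resolution maps to
        an OPL extent via the tissue index.
        """
        fwhm_air_um = self.axial_resolution_tissue * self.tissue_refractive_index
        return fwhm_air_um / 2.3548 / self.axial_pixel_pitch_air

    @property
    def lateral_sigma_px(self) -> float:
        # 1/e^2 intensity radius w0 -> amplitude ~ exp(-x^2/w0^2), sigma = w0/sqrt(2)
        w0 = 0.5 * self.lateral_beam_diameter / self.lateral_pixel_pitch
        return w0 / 1.4142135623730951


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition protocol: B-scan/volume rates, duration and baseline."""

    a_scans_per_bscan: int = 1000
    bscan_rate: float = 200.0    # Hz
    bscans_per_volume: int = 1
    volume_rate: float = 0.0     # Hz; 0 for repeated-B-scan protocols
    duration: float = 5.0        # s
    baseline: float = 1.0        # s before stimulus onset

    def __post_init__(self) -> None:
        _require(self.bscan_rate > 0, "bscan_rate must be > 0")
        _require(self.duration > self.baseline >= 0,
                 "need duration > baseline >= 0")

    @property
    def frame_interval(self) -> float:
        """Seconds between successive B-scans at one location."""
        if self.volume_rate > 0:
            return 1.0 / self.volume_rate
        return 1.0 / self.bscan_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    def times(self):
        """Frame times in seconds relative to stimulus onset."""
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval - self.baseline


#: The three acquisition protocols: fast repeated B-scans, prolonged
#: repeated B-scans, and repeated volumes.
PROTOCOL_1 = ProtocolSpec(a_scans_per_bscan=1000, bscan_rate=200.0,
                          duration=5.0, baseline=1.0)
PROTOCOL_2 = ProtocolSpec(a_scans_per_bscan=1000, bscan_rate=25.0,
                          duration=55.0, baseline=5.0)
PROTOCOL_3 = ProtocolSpec(a_scans_per_bscan=1000, bscan_rate=200.0,
                          bscans_per_volume=25, volume_rate=8.0,
                          duration=5.0, baseline=1.0)

PROTOCOLS = {1: PROTOCOL_1, 2: PROTOCOL_2, 3: PROTOCOL_3}


@dataclass(frozen=True)
class LayerSpec:
    """One reflective slab: anterior surface depth, thickness, reflectivity.

    ``snr`` is the linear amplitude SNR of the slab's speckle relative to
    the additive noise floor.  The ground-truth *boundary* of a slab is its
    anterior surface, where the dark-to-light transition sits.
    """

    name: str
    top_px: float
    thickness_px: float
    snr: float

    def __post_init__(self) -> None:
        _require(self.thickness_px > 0, "thickness must be > 0")
        _require(self.snr >= 0, "snr must be >= 0")


def default_retina_layers(depth_px: int = 160) -> list[LayerSpec]:
    """Outer-retina slab stack: ELM, IS/OS, OS, OS tips, RPE, BrM.

    Depths scale with the image height so the stack sits in the posterior
    half with clear margins; the IS/OS junction is the brightest band, as in
    NIR-OCT of the rodent outer retina.
    """
    z0 = int(round(depth_px * 0.38))

    def L(name, off, thick, snr):
        return LayerSpec(name, z0 + off, thick, snr)

    return [
        L("ELM", 0, 3.0, 30.0),
        L("ISOS", 12, 3.0, 60.0),
        L("OS", 15, 9.0, 6.0),       # dim outer-segment interior
        L("OStips", 24, 3.0, 45.0),
        L("IZ", 27, 2.0, 3.0),       # dim interdigitation zone (microvilli)
        L("RPE", 29, 4.0, 35.0),     # thin epithelial monolayer
        L("BrM", 36, 3.0, 45.0),
    ]
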