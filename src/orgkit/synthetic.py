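"""Synthetic complex OCT data with known ground truth.

Three generators mirror the three acquisition protocols: labelled phase
traces (for the classification pipeline), complex B-scan time series (for
the full image pipeline) and repeated-volume series (for en-face mapping).

The B-scan forward model: each reflective slab is a fixed field of
circular-complex scatterers convolved with the complex system PSF (axial
Gaussian envelope on the interferometric carrier, lateral Gaussian).  The
speckle realisation is frozen over time; stimulus-evoked kinetics displace
each slab sub-pixel via frequency-domain phase ramps at the true (unaliased)
axial frequencies, so a slab moving by dz acquires the physical phase shift
4*pi*dz/lambda_c.  Rigid bulk motion and additive circular-complex noise are
applied on top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fourier
from .containers import FrameSeries
from .kinetics import (
    CLASS_CURVES,
    layer_displacements,
    pairwise_signals,
    type_i_curve,
    type_ii_curve,
)
from .specs import (
    KineticsSpec,
    LayerSpec,
    MotionSpec,
    OpticsSpec,
    ProtocolSpec,
    default_retina_layers,
)

__all__ = [
    "simulate_phase_traces",
    "simulate_bscan_series",
    "simulate_volume_series",
    "TRACE_CLASSES",
]

TRACE_CLASSES = ("type_I", "type_II", "intermediate", "outlier")

#: default depth distributions (px anterior of BrM): Type-I (OS) shallower
#: than Type-II (RPE), which sits just anterior to BrM; separation >= 3 px.
DEPTH_MEANS_PX = {"type_I": 7.0, "type_II": 2.0}
DEPTH_SD_PX = 1.0


def nm_to_rad(dopl_nm: np.ndarray, wavelength_nm: float) -> np.ndarray:
    """Reflection-geometry conversion: phi = 4*pi*dOPL/lambda_c."""
    return 4.0 * np.pi * np.asarray(dopl_nm) / wavelength_nm


def simulate_phase_traces(
    kinetics: KineticsSpec = KineticsSpec(),
    protocol: ProtocolSpec | None = None,
    n_traces_per_class: int = 500,
    noise_sd_mrad: float = 30.0,
    seed: int = 0,
    wavelength_nm: float = 840.0,
    mixture_range: tuple[float, float] = (0.35, 0.65),
) -> pd.DataFrame:
    """Labelled synthetic phase traces for the four signal classes.

    Returns a long-format table (trace_id, class, depth_px_to_brm, t_s,
    phase_rad) sampled at the protocol's frame interval.  Intermediate
    traces are convex mixtures ``a*TypeI + (1-a)*TypeII`` (transition band);
    outliers are post-stimulus shape-shuffled copies of a random class
    trace, so the pre-stimulus baseline stays flat for every class.
    """
    from .specs import PROTOCOL_1

    if protocol is None:
        protocol = PROTOCOL_1
    if n_traces_per_class < 1:
        raise ValueError("n_traces_per_class must be >= 1")
    if noise_sd_mrad < 0:
        raise ValueError("noise_sd_mrad must be >= 0")

    rng = np.random.default_rng(seed)
    t = protocol.times()
    post = t >= 0
    templates = {
        name: nm_to_rad(curve(t, kinetics), wavelength_nm)
        for name, curve in CLASS_CURVES.items()
    }
    sd_rad = noise_sd_mrad * 1e-3

    block = max(1, int(round(0.25 / protocol.frame_interval)))  # shuffle 0.25 s blocks
    rows_id, rows_cls, rows_depth, phis = [], [], [], []
    for cls in TRACE_CLASSES:
        for i in range(n_traces_per_class):
            if cls == "type_I":
                phi = templates["type_I"].copy()
                depth = rng.normal(DEPTH_MEANS_PX["type_I"], DEPTH_SD_PX)
            elif cls == "type_II":
                phi = templates["type_II"].copy()
                depth = rng.normal(DEPTH_MEANS_PX["type_II"], DEPTH_SD_PX)
            elif cls == "intermediate":
                a = rng.uniform(*mixture_range)
                phi = a * templates["type_I"] + (1 - a) * templates["type_II"]
                depth = a * rng.normal(
                    DEPTH_MEANS_PX["type_I"], DEPTH_SD_PX
                ) + (1 - a) * rng.normal(DEPTH_MEANS_PX["type_II"], DEPTH_SD_PX)
            else:
                # outlier: post-stimulus shape destroyed by shuffling coarse
                # (0.25 s) blocks — each permutation yields a different
                # arbitrary low-frequency shape, scattering outliers into
                # low-density regions of the feature space
                src = templates[("type_I", "type_II")[int(rng.integers(2))]].copy()
                seg = src[post]
                n_blocks = max(2, len(seg) // block)
                pieces = np.array_split(seg, n_blocks)
                order = rng.permutation(n_blocks)
                phi = src
                phi[post] = np.concatenate([pieces[j] for j in order])
                depth = rng.uniform(0.0, 10.0)
            phi = phi + rng.normal(0.0, sd_rad, size=t.shape)
            rows_id.append(f"{cls}_{i:05d}")
            rows_cls.append(cls)
            rows_depth.append(depth)
            phis.append(phi)

    n = len(phis)
    return pd.DataFrame(
        {
            "trace_id": np.repeat(rows_id, len(t)),
            "class": np.repeat(rows_cls, len(t)),
            "depth_px_to_brm": np.repeat(rows_depth, len(t)),
            "t_s": np.tile(t, n),
            "phase_rad": np.concatenate(phis),
        }
    )


def _bulk_motion(t: np.ndarray, motion: MotionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Axial and lateral rigid bulk-motion traces (px)."""
    rng = np.random.default_rng(motion.seed)
    ph = rng.uniform(0, 2 * np.pi, size=4)
    x = (t - t[0]) / max(t[-1] - t[0], 1e-12)
    dz = (
        motion.drift_amplitude * x
        + motion.heartbeat_amp * np.sin(2 * np.pi * motion.heartbeat_freq * t + ph[0])
        + motion.respiration_amp * np.sin(2 * np.pi * motion.respiration_freq * t + ph[1])
    )
    f = motion.lateral_fraction
    dx = (
        -motion.drift_amplitude * f * x
        + motion.heartbeat_amp * f * np.sin(2 * np.pi * motion.heartbeat_freq * t + ph[2])
        + motion.respiration_amp * f * np.sin(2 * np.pi * motion.respiration_freq * t + ph[3])
    )
    return dz, dx


def _layer_field(
    rng: np.random.Generator,
    depth_px: int,
    width_px: int,
    layer: LayerSpec,
    optics: OpticsSpec,
) -> np.ndarray:
    """Frozen speckle field of one slab, PSF-convolved, scaled to its SNR."""
    z = np.arange(depth_px)
    # fractional row coverage of [top, top+thickness)
    cover = np.clip(
        np.minimum(z + 1.0, layer.top_px + layer.thickness_px) - np.maximum(z * 1.0, layer.top_px),
        0.0,
        1.0,
    )
    raw = np.sqrt(cover)[:, None] * (
        rng.standard_normal((depth_px, width_px))
        + 1j * rng.standard_normal((depth_px, width_px))
    )
    nu_z = fourier._true_axial_freqs(depth_px, optics.carrier_cycles_per_px)
    sig_z = 1.0 / (2.0 * np.pi * optics.axial_sigma_px)
    h_z = np.exp(-0.5 * ((nu_z - optics.carrier_cycles_per_px) / sig_z) ** 2)
    nu_x = np.fft.fftfreq(width_px)
    sig_x = 1.0 / (2.0 * np.pi * optics.lateral_sigma_px)
    h_x = np.exp(-0.5 * (nu_x / sig_x) ** 2)
    field = np.fft.ifft2(np.fft.fft2(raw) * h_z[:, None] * h_x[None, :])
    core = cover >= 0.999
    if core.any():
        ref = np.sqrt(np.mean(np.abs(field[core]) ** 2))
    else:
        ref = np.sqrt(np.mean(np.abs(field[cover > 0]) ** 2))
    if ref > 0:
        field *= layer.snr / ref
    return field


def _validate_layers(layers: list[LayerSpec], depth_px: int) -> None:
    ordered = sorted(layers, key=lambda l: l.top_px)
    canonical = ("ELM", "ISOS", "OStips", "RPE", "BrM")
    names_by_depth = [l.name for l in ordered if l.name in canonical]
    expected = [n for n in canonical if n in names_by_depth]
    if names_by_depth != expected:
        raise ValueError("anatomical layer ordering violated")
    for a, b in zip(ordered, ordered[1:]):
        if a.top_px + a.thickness_px > b.top_px + 1e-9:
            raise ValueError(f"layers {a.name} and {b.name} overlap")
    for l in layers:
        if l.top_px < 0 or l.top_px + l.thickness_px > depth_px:
            raise ValueError(f"layer {l.name} outside the depth grid")


def simulate_bscan_series(
    layers: list[LayerSpec] | None = None,
    kinetics: KineticsSpec = KineticsSpec(),
    motion: MotionSpec = MotionSpec(),
    optics: OpticsSpec = OpticsSpec(),
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    depth_px: int = 160,
    lateral_px: int = 64,
    noise_sigma: float = 1.0,
    amplitude_scale: float = 1.0,
    fresh_speckle_per_frame: bool = False,
) -> FrameSeries:
    """Complex B-scan time series with frozen speckle and known kinetics.

    ``amplitude_scale`` multiplies every kinetic displacement (used by the
    volume generator for regionally varying response amplitude).
    ``fresh_speckle_per_frame`` redraws the scatterer fields each frame,
    emulating a raster over neighbouring positions (independent speckle, as
    used for despeckling) instead of a repeated scan of one location.  The
    ground-truth record stores bulk shifts, per-layer displacements and the
    pairwise structure signals needed by every downstream quantity.
    """
    from .specs import PROTOCOL_1

    if protocol is None:
        protocol = PROTOCOL_1
    if layers is None:
        layers = default_retina_layers(depth_px)
    _validate_layers(layers, depth_px)

    rng = np.random.default_rng(seed)
    t = protocol.times()
    disp_nm = {
        k: amplitude_scale * v for k, v in layer_displacements(t, kinetics).items()
    }
    pitch_nm = optics.axial_pixel_pitch_air * 1e3
    dz_bulk, dx_bulk = _bulk_motion(t, motion)
    carrier = optics.carrier_cycles_per_px

    fields = {l.name: _layer_field(rng, depth_px, lateral_px, l, optics) for l in layers}
    specs_z = {name: np.fft.fft(f, axis=0) for name, f in fields.items()}
    nu_z = fourier._true_axial_freqs(depth_px, carrier)[:, None]

    frames = np.empty((len(t), depth_px, lateral_px), dtype=np.complex64)
    for i in range(len(t)):
        if fresh_speckle_per_frame and i > 0:
            fields = {
                l.name: _layer_field(rng, depth_px, lateral_px, l, optics) for l in layers
            }
            specs_z = {name: np.fft.fft(f, axis=0) for name, f in fields.items()}
        acc = np.zeros((depth_px, lateral_px), dtype=np.complex128)
        for name, spec in specs_z.items():
            u_px = disp_nm.get(name, np.zeros_like(t))[i] / pitch_nm + dz_bulk[i]
            acc += spec * np.exp(-2j * np.pi * nu_z * u_px)
        frame = np.fft.ifft(acc, axis=0)
        if dx_bulk[i] != 0.0:
            frame = fourier.lateral_shift(frame, dx_bulk[i], axis=1)
        if noise_sigma > 0:
            frame = frame + noise_sigma * np.sqrt(0.5) * (
                rng.standard_normal(frame.shape) + 1j * rng.standard_normal(frame.shape)
            )
        frames[i] = frame.astype(np.complex64)

    gt: dict[str, np.ndarray] = {
        "t_s": t,
        "bulk_dz_px": dz_bulk,
        "bulk_dx_px": dx_bulk,
    }
    for name, u in disp_nm.items():
        gt[f"u_{name}_nm"] = u
    for name, sig in pairwise_signals(t, kinetics).items():
        gt[f"signal_{name}_nm"] = amplitude_scale * sig
    for l in layers:
        gt[f"top_px_{l.name}"] = np.array(l.top_px)
        gt[f"snr_{l.name}"] = np.array(l.snr)

    return FrameSeries(
        frames=frames,
        center_wavelength_nm=optics.center_wavelength,
        pixel_pitch_um_air=optics.axial_pixel_pitch_air,
        frame_rate_hz=1.0 / protocol.frame_interval,
        stimulus_onset_s=protocol.baseline,
        protocol_id=2 if protocol.bscan_rate <= 30 else 1,
        ground_truth=gt,
    )


def simulate_volume_series(
    amplitude_map: np.ndarray | None = None,
    kinetics: KineticsSpec = KineticsSpec(),
    motion: MotionSpec | None = None,
    optics: OpticsSpec = OpticsSpec(),
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    depth_px: int = 96,
    lateral_px: int = 60,
    fov_deg: float = 12.0,
    cell_deg: tuple[float, float] = (1.2, 0.48),
) -> FrameSeries:
    """Repeated-volume series with an en-face grid of response amplitudes.

    The field of view is split into ``fov/cell`` cells in x (within B-scan)
    and one B-scan position per cell in y; ``amplitude_map[ix, iy]`` scales
    the kinetics of that cell (default: uniform ones).  Frames have shape
    ``[time, y, depth, x]``.
    """
    from .specs import PROTOCOL_3

    if protocol is None:
        protocol = PROTOCOL_3
    if motion is None:
        motion = MotionSpec(drift_amplitude=0.0, heartbeat_amp=0.0, respiration_amp=0.0)
    n_x = int(round(fov_deg / cell_deg[0]))
    n_y = int(round(fov_deg / cell_deg[1]))
    if protocol.bscans_per_volume != n_y:
        raise ValueError(
            f"protocol provides {protocol.bscans_per_volume} B-scans/volume but the "
            f"cell grid needs {n_y} y positions"
        )
    if amplitude_map is None:
        amplitude_map = np.ones((n_x, n_y))
    amplitude_map = np.asarray(amplitude_map, dtype=float)
    if amplitude_map.shape != (n_x, n_y):
        raise ValueError(f"amplitude_map must have shape {(n_x, n_y)}")
    if lateral_px % n_x:
        raise ValueError("lateral_px must be divisible by the number of x cells")

    block = lateral_px // n_x
    t = protocol.times()
    n_t = len(t)
    frames = np.empty((n_t, n_y, depth_px, lateral_px), dtype=np.complex64)
    rng = np.random.default_rng(seed)
    dz_bulk, dx_bulk = _bulk_motion(t, motion)
    carrier = optics.carrier_cycles_per_px
    base_gt: dict[str, np.ndarray] = {
        f"signal_{name}_nm": sig for name, sig in pairwise_signals(t, kinetics).items()
    }
    for l in default_retina_layers(depth_px):
        base_gt[f"top_px_{l.name}"] = np.array(l.top_px)

    for iy in range(n_y):
        slab = np.zeros((n_t, depth_px, lateral_px), dtype=np.complex64)
        for ix in range(n_x):
            sub = simulate_bscan_series(
                layers=default_retina_layers(depth_px),
                kinetics=kinetics,
                motion=MotionSpec(drift_amplitude=0, heartbeat_amp=0, respiration_amp=0),
                optics=optics,
                protocol=protocol,
                seed=int(rng.integers(2**31 - 1)),
                depth_px=depth_px,
                lateral_px=block,
                noise_sigma=0.0,
                amplitude_scale=float(amplitude_map[ix, iy]),
            )
            slab[:, :, ix * block : (ix + 1) * block] = sub.frames
        for i in range(n_t):
            frame = slab[i].astype(np.complex128)
            if dz_bulk[i] or dx_bulk[i]:
                frame = fourier.subpixel_shift(frame, dz_bulk[i], dx_bulk[i], carrier)
            frame = frame + np.sqrt(0.5) * (
                rng.standard_normal(frame.shape) + 1j * rng.standard_normal(frame.shape)
            )
            frames[i, iy] = frame.astype(np.complex64)

    gt = dict(base_gt)
    gt["amplitude_map"] = amplitude_map
    gt["bulk_dz_px"] = dz_bulk
    gt["bulk_dx_px"] = dx_bulk
    gt["t_s"] = t
    return FrameSeries(
        frames=frames,
        center_wavelength_nm=optics.center_wavelength,
        pixel_pitch_um_air=optics.axial_pixel_pitch_air,
        frame_rate_hz=protocol.volume_rate,
        stimulus_onset_s=protocol.baseline,
        protocol_id=3,
        ground_truth=gt,
    )
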