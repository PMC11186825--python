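"""Self-referenced phase traces, OPL conversion, filtering and QC.

For each target pixel the temporal phase is measured against a reference
layer of the same A-scan: ``phi = arg(S_target * conj(mean S_ref))`` with a
complex (amplitude-weighted) mean over the reference-layer pixels.  Traces
are temporally unwrapped, zeroed at stimulus onset, converted to ΔOPL by
the reflection-geometry relation ``ΔOPL = s * lambda_c * dphi / (4*pi)``
with ``s = -1`` when the target lies anterior to the reference (so an OPL
increase always reads as expansion of the inter-layer space), band-stop
filtered against heartbeat/breathing artifacts, and excluded when the
pre-stimulus standard deviation exceeds a threshold (default 60 mrad,
strict inequality).

The 10 Hz low-pass is applied only on the classification branch, never to
reported signals; see :mod:`orgkit.patterns`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import FrameSeries, LayerBoundaries, ORGSignal, PhaseTrace

__all__ = [
    "ConversionParams",
    "extract_phase_trace",
    "extract_band_traces",
    "phase_to_opl",
    "filter_trace",
    "qc_exclude",
    "average_band_trace",
    "DEFAULT_BANDSTOPS",
    "QC_THRESHOLD_MRAD",
]

#: default band-stop bands (Hz) bracketing the simulator's heartbeat and
#: respiration defaults; configurable since the artifacts' frequencies are
#: subject physiology, not constants.
DEFAULT_BANDSTOPS = ((4.9, 5.1), (0.95, 1.05))

#: pre-stimulus phase-SD exclusion threshold (mrad); "larger than" is strict.
QC_THRESHOLD_MRAD = 60.0


@dataclass(frozen=True)
class ConversionParams:
    """Phase-to-OPL conversion constants."""

    center_wavelength: float = 840.0       # nm
    tissue_refractive_index: float = 1.41  # for physical deformation only

    def __post_init__(self) -> None:
        if self.center_wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.tissue_refractive_index < 1:
            raise ValueError("refractive index must be >= 1")


def _onset_index(t: np.ndarray) -> int:
    return int(np.searchsorted(t, 0.0))


def extract_phase_trace(
    series: FrameSeries,
    target_pixel: tuple[int, int],
    boundaries: LayerBoundaries,
    reference_layer: str = "ISOS",
    reference_halfwidth: int = 1,
    min_reference_snr: float = 3.0,
    target_layer: str = "",
) -> PhaseTrace:
    """Temporal phase of one pixel relative to a reference layer.

    ``target_pixel`` is (depth, ascan).  The reference signal per frame is
    the complex mean over the reference layer's pixels (boundary row ±
    ``reference_halfwidth``) in the same A-scan, demodulated by the aliased
    axial carrier first — without demodulation the carrier rotates adjacent
    rows against each other (by pi per pixel at the default pitch) and the
    mean cancels instead of averaging down noise.  The trace is unwrapped
    frame-to-frame (differences mapped to (-pi, pi]) and zeroed at stimulus
    onset; it is flagged invalid when the reference magnitude falls below
    ``min_reference_snr`` times the noise floor (estimated from the frame
    median magnitude).
    """
    if series.is_volume:
        raise ValueError("pass one y-slice of a volume series")
    z, a = target_pixel
    ref_row = int(boundaries.paths[reference_layer][a])
    rows = slice(
        max(ref_row - reference_halfwidth, 0), ref_row + reference_halfwidth + 1
    )
    target = series.frames[:, z, a]
    nu_alias = (series.carrier_cycles_per_px + 0.5) % 1.0 - 0.5
    zz = np.arange(rows.start, rows.stop)
    demod = np.exp(-2j * np.pi * nu_alias * zz)
    ref = (series.frames[:, rows, a] * demod).mean(axis=1)
    noise_floor = float(np.median(np.abs(series.frames[0])))
    valid = bool(np.all(np.abs(ref) > 0)) and (
        float(np.abs(ref).mean()) >= min_reference_snr * noise_floor
    )

    raw = np.angle(target * np.conj(ref))
    phi = np.concatenate(([raw[0]], raw[0] + np.cumsum(_wrap(np.diff(raw)))))
    t = series.times()
    onset = _onset_index(t)
    phi = phi - phi[onset]
    pre = phi[:onset]
    prestim_sd = float(np.std(pre)) * 1e3 if len(pre) else 0.0
    depth_to_brm = float(boundaries.paths["BrM"][a] - z)
    return PhaseTrace(
        t=t,
        phi=phi,
        depth_to_brm=depth_to_brm,
        target_layer=target_layer,
        reference_layer=reference_layer,
        prestim_sd=prestim_sd,
        valid=valid,
        trace_id=f"z{z}_a{a}",
    )


def _wrap(dphi: np.ndarray) -> np.ndarray:
    """Map frame-to-frame phase differences to (-pi, pi]."""
    return dphi - 2 * np.pi * np.ceil((dphi - np.pi) / (2 * np.pi))


def extract_band_traces(
    series: FrameSeries,
    boundaries: LayerBoundaries,
    band: tuple[np.ndarray, np.ndarray] | str,
    reference_layer: str = "ISOS",
    **kwargs,
) -> list[PhaseTrace]:
    """Phase traces for every pixel of a depth band.

    ``band`` is either a named layer (pixels on that boundary row) or a
    per-A-scan ``(top, bottom)`` pair of depth index arrays, bottom
    exclusive.
    """
    traces = []
    n_ascans = series.frames.shape[2]
    for a in range(n_ascans):
        if isinstance(band, str):
            zs = [int(boundaries.paths[band][a])]
            name = band
        else:
            top, bot = band
            zs = range(int(top[a]), int(bot[a]))
            name = "band"
        for z in zs:
            traces.append(
                extract_phase_trace(
                    series,
                    (z, a),
                    boundaries,
                    reference_layer=reference_layer,
                    target_layer=name,
                    **kwargs,
                )
            )
    return traces


def phase_to_opl(
    trace: PhaseTrace,
    params: ConversionParams = ConversionParams(),
    target_anterior_to_reference: bool = True,
) -> np.ndarray:
    """Convert unwrapped phase (rad) to ΔOPL (nm), expansion-positive.

    ``ΔOPL = s * lambda_c * dphi / (4*pi)``; the negative sign applies when
    the target layer is anterior to the reference so that an increase
    always means expansion of the space between the two layers.
    """
    s = -1.0 if target_anterior_to_reference else 1.0
    return s * params.center_wavelength * trace.phi / (4.0 * np.pi)


def opl_to_deformation(dopl_nm: np.ndarray, params: ConversionParams = ConversionParams()) -> np.ndarray:
    """Physical deformation (nm) from OPL change using the tissue index."""
    return np.asarray(dopl_nm) / params.tissue_refractive_index


def filter_trace(
    trace: PhaseTrace,
    bandstop_bands: tuple[tuple[float, float], ...] = DEFAULT_BANDSTOPS,
    lowpass_cutoff: float | None = None,
    trim: int = 0,
    order: int = 2,
    lowpass_order: int = 4,
) -> PhaseTrace:
    """Zero-phase band-stop (+ optional low-pass) filtering, then end-trim.

    Filtering is forward-backward (``sosfiltfilt``), so the passband has no
    phase distortion and DC is preserved.  ``trim`` samples are dropped at
    both ends where edge effects concentrate.  Bands at or above the trace
    Nyquist are skipped (they cannot alias into the sampled signal).
    """
    fs = trace.fs
    nyq = fs / 2.0
    phi = trace.phi.astype(float)
    min_len = 12 * order + 1
    if len(phi) <= min_len:
        raise ValueError("trace shorter than the filter warm-up length")
    if lowpass_cutoff is not None and lowpass_cutoff >= nyq:
        raise ValueError("low-pass cutoff must be below the trace Nyquist frequency")
    for lo, hi in bandstop_bands:
        if lo >= nyq:
            continue
        hi = min(hi, nyq * 0.999)
        sos = sps.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
        phi = sps.sosfiltfilt(sos, phi)
    if lowpass_cutoff is not None:
        sos = sps.butter(lowpass_order, lowpass_cutoff, btype="lowpass", fs=fs, output="sos")
        phi = sps.sosfiltfilt(sos, phi)
    sl = slice(trim, len(phi) - trim if trim else None)
    t = trace.t[sl]
    phi = phi[sl]
    onset = _onset_index(t)
    phi = phi - phi[onset]
    pre = phi[:onset]
    return PhaseTrace(
        t=t,
        phi=phi,
        depth_to_brm=trace.depth_to_brm,
        target_layer=trace.target_layer,
        reference_layer=trace.reference_layer,
        prestim_sd=float(np.std(pre)) * 1e3 if len(pre) else 0.0,
        valid=trace.valid,
        trace_id=trace.trace_id,
    )


def qc_exclude(
    traces: list[PhaseTrace],
    threshold_mrad: float = QC_THRESHOLD_MRAD,
    min_prestim_samples: int = 5,
) -> tuple[list[PhaseTrace], dict[str, int]]:
    """Retain traces with pre-stimulus SD <= threshold; log exclusions.

    The rule is strict ("larger than" excludes): a trace at exactly the
    threshold is retained.  Traces flagged invalid (low reference SNR) are
    excluded separately.
    """
    retained, log = [], {"retained": 0, "high_prestim_sd": 0, "invalid_reference": 0}
    for tr in traces:
        n_pre = int(np.sum(tr.t < 0))
        if n_pre < min_prestim_samples:
            raise ValueError(
                f"trace {tr.trace_id!r} has {n_pre} pre-stimulus samples; need >= {min_prestim_samples}"
            )
        if not tr.valid:
            log["invalid_reference"] += 1
        elif tr.prestim_sd > threshold_mrad:
            log["high_prestim_sd"] += 1
        else:
            retained.append(tr)
            log["retained"] += 1
    return retained, log


def average_band_trace(
    traces: list[PhaseTrace],
    structure: str,
    params: ConversionParams = ConversionParams(),
    target_anterior_to_reference: bool = True,
) -> ORGSignal:
    """Spatial average of QC-passed unwrapped traces, converted to ΔOPL."""
    if not traces:
        raise ValueError("no traces in band after QC")
    t = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t.shape or not np.allclose(tr.t, t):
            raise ValueError("traces must share a time grid")
    phi = np.mean([tr.phi for tr in traces], axis=0)
    mean_trace = PhaseTrace(t=t, phi=phi, depth_to_brm=np.mean([tr.depth_to_brm for tr in traces]))
    dopl = phase_to_opl(mean_trace, params, target_anterior_to_reference)
    return ORGSignal(structure=structure, t=t, dopl=dopl, n_pixels=len(traces))
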