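"""End-to-end analysis of a complex B-scan series.

``analyze_bscan_series`` runs the full chain: phase-restoring
registration, layer segmentation on the time-averaged intensity, per-pixel
phase traces of the mixed (OS+RPE) layer against the IS/OS reference,
band-stop filtering and 60 mrad QC, unsupervised pattern discovery
(low-pass filtered branch), and composition of the structure-level
signals: OS (Type-I pixels), Type-II (RPE rel IS/OS), IS (IS/OS rel ELM)
and SRS = Type-II + IS.  Reported signals use the band-stop-only branch —
the 10 Hz low-pass touches only the classification features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FrameSeries, LayerBoundaries, ORGSignal, PhaseTrace
from .patterns import (
    FEATURE_WINDOW,
    classification_lowpass,
    discover_patterns,
)
from .registration import register_series
from .segmentation import despeckle, segment_layers
from .traces import (
    ConversionParams,
    DEFAULT_BANDSTOPS,
    average_band_trace,
    extract_band_traces,
    filter_trace,
    qc_exclude,
)

__all__ = [
    "analyze_bscan_series",
    "analyze_volume_series",
    "extract_classification_table",
    "synthetic_classification_cv",
]


def synthetic_classification_cv(
    n_traces_per_class: int = 500, seed: int = 0, cv_seed: int | None = None
) -> float:
    """10-fold CV accuracy of the SVM on pipeline-labelled synthetic traces.

    Generates labelled phase traces for the four classes, applies the
    classification branch (10 Hz low-pass, windowing, normalization, PCA,
    min-max feature space, coverage-radius outlier rule, Ward cut to 3
    clusters, depth-based naming), trains the standardized Gaussian-kernel
    SVM with grid-searched hyperparameters, and returns its 10-fold
    cross-validation accuracy (fraction in [0, 1]).
    """
    from .synthetic import simulate_phase_traces
    from .patterns import discover_patterns, table_to_matrix

    table = simulate_phase_traces(n_traces_per_class=n_traces_per_class, seed=seed)
    t, X, depth, _, _ = table_to_matrix(table)
    Xc = classification_lowpass(t, X)
    _, model = discover_patterns(
        t, Xc, depth, seed=seed if cv_seed is None else cv_seed, train_svm=True
    )
    return model.cv_accuracy


def _trace_matrix(traces: list[PhaseTrace]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = traces[0].t
    X = np.stack([tr.phi for tr in traces])
    depth = np.array([tr.depth_to_brm for tr in traces])
    return t, X, depth


def extract_classification_table(
    registered: FrameSeries,
    boundaries: LayerBoundaries,
    bandstops=DEFAULT_BANDSTOPS,
    qc_threshold_mrad: float = 60.0,
    mixed_margin_px: int = 4,
    trim_s: float = 0.2,
) -> tuple[list[PhaseTrace], dict]:
    """QC-passed, band-stop-filtered mixed-layer pixel traces rel IS/OS.

    ``mixed_margin_px`` keeps the band clear of the IS/OS reference: pixels
    within the PSF support of the reference layer share its speckle, so
    self-referencing there is degenerate (their phase difference is biased
    toward zero regardless of motion).  The default is ~3.5 axial PSF
    sigmas.  ``trim_s`` seconds are dropped at both ends after zero-phase
    filtering, where edge transients concentrate.
    """
    isos = boundaries.paths["ISOS"]
    brm = boundaries.paths["BrM"]
    band = (isos + mixed_margin_px, brm - 1)  # keep clear of both references
    raw = extract_band_traces(registered, boundaries, band, reference_layer="ISOS")
    trim = int(round(trim_s * raw[0].fs))
    filtered = [filter_trace(tr, bandstop_bands=bandstops, trim=trim) for tr in raw]
    retained, log = qc_exclude(filtered, threshold_mrad=qc_threshold_mrad)
    return retained, log


def analyze_bscan_series(
    series: FrameSeries,
    seed: int = 0,
    upsample: int = 100,
    bandstops=DEFAULT_BANDSTOPS,
    qc_threshold_mrad: float = 60.0,
    params: ConversionParams | None = None,
    train_svm: bool = False,
) -> dict:
    """Full image pipeline; returns signals, metrics, labels and QC logs.

    Pattern discovery runs unsupervised on this series' own traces (the
    persisted-SVM route is for classifying new datasets against an
    existing model).  Structure signals are averages of the unwrapped,
    band-stop-only traces of each labelled group.
    """
    if params is None:
        params = ConversionParams(center_wavelength=series.center_wavelength_nm)

    registered, shifts = register_series(series, upsample=upsample)
    mean_intensity = despeckle(registered)
    boundaries = segment_layers(mean_intensity)

    mixed, qc_log = extract_classification_table(
        registered, boundaries, bandstops, qc_threshold_mrad
    )
    if not mixed:
        raise RuntimeError("no mixed-layer traces survived QC")
    t, X, depth = _trace_matrix(mixed)
    Xc = classification_lowpass(t, X)
    label_table, model = discover_patterns(t, Xc, depth, seed=seed, train_svm=train_svm)
    labels = label_table["label"].to_numpy()

    def group_signal(name: str, structure: str) -> ORGSignal | None:
        sel = [tr for tr, lab in zip(mixed, labels) if lab == name]
        if not sel:
            return None
        return average_band_trace(sel, structure, params, target_anterior_to_reference=False)

    os_signal = group_signal("type_I", "OS")
    type_ii_signal = group_signal("type_II", "TypeII")

    elm_raw = extract_band_traces(registered, boundaries, "ELM", reference_layer="ISOS")
    trim = int(round(0.2 * elm_raw[0].fs))
    elm_filt = [filter_trace(tr, bandstop_bands=bandstops, trim=trim) for tr in elm_raw]
    elm_ret, elm_log = qc_exclude(elm_filt, threshold_mrad=qc_threshold_mrad)
    is_signal = (
        average_band_trace(elm_ret, "IS", params, target_anterior_to_reference=True)
        if elm_ret
        else None
    )

    srs_signal = None
    if type_ii_signal is not None and is_signal is not None:
        from .quantify import compose_srs

        srs_signal = compose_srs(type_ii_signal, is_signal)

    metrics: dict[str, object] = {}
    from .quantify import peak_metrics, srs_slope

    if os_signal is not None:
        win_hi = min(3.5, float(os_signal.t[-1]))
        metrics["OS"] = peak_metrics(os_signal, window=(0.0, win_hi))
    if srs_signal is not None and srs_signal.t[-1] >= 10.0:
        metrics["SRS_slope"] = srs_slope(srs_signal)
        win_hi = min(40.0, float(srs_signal.t[-1]))
        metrics["SRS"] = peak_metrics(srs_signal, window=(0.0, win_hi))

    return {
        "registered": registered,
        "shifts": shifts,
        "boundaries": boundaries,
        "traces": mixed,
        "labels": labels,
        "label_table": label_table,
        "model": model,
        "signals": {
            k: v
            for k, v in {
                "OS": os_signal,
                "TypeII": type_ii_signal,
                "IS": is_signal,
                "SRS": srs_signal,
            }.items()
            if v is not None
        },
        "metrics": metrics,
        "qc_log": {"mixed": qc_log, "ELM": elm_log},
    }


def _slice_series(volume: FrameSeries, iy: int) -> FrameSeries:
    return FrameSeries(
        frames=volume.frames[:, iy],
        center_wavelength_nm=volume.center_wavelength_nm,
        pixel_pitch_um_air=volume.pixel_pitch_um_air,
        frame_rate_hz=volume.frame_rate_hz,
        stimulus_onset_s=volume.stimulus_onset_s,
        protocol_id=volume.protocol_id,
    )


def analyze_volume_series(
    volume: FrameSeries,
    seed: int = 0,
    n_x_cells: int = 10,
    upsample: int = 100,
    qc_threshold_mrad: float = 60.0,
) -> dict:
    """Per-slice registration + classification of a repeated-volume series.

    The pattern model is learned unsupervised from the first y-slice's
    traces and then applied to the remaining slices (the train-once,
    classify-new-data route, matching how slower protocols are handled).
    Returns per-trace cell indices, labels and ΔOPL series ready for
    en-face mapping.
    """
    if not volume.is_volume:
        raise ValueError("expected a volume series [t, y, z, x]")
    from .patterns import classify_new
    from .traces import phase_to_opl

    n_y = volume.frames.shape[1]
    width = volume.frames.shape[3]
    if width % n_x_cells:
        raise ValueError("lateral width must divide into n_x_cells")
    block = width // n_x_cells
    params = ConversionParams(center_wavelength=volume.center_wavelength_nm)

    model = None
    rows = []
    for iy in range(n_y):
        sl = _slice_series(volume, iy)
        registered, _ = register_series(sl, upsample=upsample)
        boundaries = segment_layers(despeckle(registered))
        mixed, _ = extract_classification_table(
            registered, boundaries, qc_threshold_mrad=qc_threshold_mrad, trim_s=0.0
        )
        if not mixed:
            continue
        t, X, depth = _trace_matrix(mixed)
        Xc = classification_lowpass(t, X)
        if model is None:
            _, model = discover_patterns(t, Xc, depth, seed=seed, train_svm=True)
        labels = classify_new(t, Xc, depth, model)
        for tr, lab in zip(mixed, labels):
            a = int(tr.trace_id.split("_a")[1])
            dopl = phase_to_opl(tr, params, target_anterior_to_reference=False)
            rows.append((iy, a // block, lab, dopl))

    cell_y = np.array([r[0] for r in rows])
    cell_x = np.array([r[1] for r in rows])
    labels = np.array([r[2] for r in rows], dtype=object)
    dopl = np.stack([r[3] for r in rows])
    return {
        "model": model,
        "cell_x": cell_x,
        "cell_y": cell_y,
        "labels": labels,
        "dopl": dopl,
        "t": volume.times(),
        "grid_shape": (n_x_cells, n_y),
    }
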