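"""Outer-retina layer segmentation by shortest-path dynamic programming.

Each boundary (ELM, IS/OS, BrM) is the minimum-cost left-to-right path on a
graph whose node cost favours dark-to-light vertical transitions, found by
dynamic programming with a bounded step between neighbouring A-scans —
the standard graph-based retinal-layer scheme.  Boundaries are found
sequentially (BrM first as the most posterior prominent band, then IS/OS,
then ELM), each restricting the next search region.  The thick OS+RPE
"mixed layer" between IS/OS and BrM is split into equal-depth sub-bands.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks

from .containers import FrameSeries, LayerBoundaries

__all__ = [
    "despeckle",
    "dp_shortest_path",
    "segment_layers",
    "define_mixed_bands",
    "SegmentationError",
]

EPS = 1e-5


class SegmentationError(RuntimeError):
    """No valid boundary path for a named layer.

    ``partial`` holds a :class:`LayerBoundaries` with the layers that were
    segmented successfully before the failure.
    """

    def __init__(self, layer: str, msg: str = "", partial: LayerBoundaries | None = None):
        self.layer = layer
        self.partial = partial
        super().__init__(f"segmentation failed for layer {layer!r}" + (f": {msg}" if msg else ""))


def despeckle(series: FrameSeries, n_average: int | None = None) -> np.ndarray:
    """Average registered frames' intensities to suppress speckle.

    Averaging ``n`` independent speckle realisations reduces the speckle
    contrast by ~1/sqrt(n) on homogeneous regions; frames must be
    registered first or the average also blurs boundaries.
    """
    if series.n_frames == 0:
        raise ValueError("empty series")
    n = series.n_frames if n_average is None else int(n_average)
    if not 1 <= n <= series.n_frames:
        raise ValueError("n_average must be in [1, n_frames]")
    return np.mean(np.abs(series.frames[:n]) ** 2, axis=0)


def _gradient_cost(image: np.ndarray) -> np.ndarray:
    """Node cost ``2 - normalized dark-to-light vertical gradient + eps``."""
    img = np.asarray(image, dtype=float)
    grad = np.zeros_like(img)
    grad[1:] = img[1:] - img[:-1]  # dark above, light below -> positive
    lo, hi = grad.min(), grad.max()
    norm = (grad - lo) / (hi - lo) if hi > lo else np.zeros_like(grad)
    return 2.0 - norm + EPS


def dp_shortest_path(
    cost: np.ndarray,
    max_jump: int = 2,
    depth_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Minimum-cost lateral path through a per-pixel cost map.

    Returns one depth index per column; consecutive columns differ by at
    most ``max_jump`` pixels.  ``depth_range`` restricts the search to
    ``[lo, hi)`` rows.
    """
    cost = np.asarray(cost, dtype=float)
    depth, width = cost.shape
    lo, hi = (0, depth) if depth_range is None else depth_range
    lo, hi = max(0, int(lo)), min(depth, int(hi))
    if hi - lo < 1:
        raise ValueError("empty depth range")
    sub = cost[lo:hi]
    acc = sub[:, 0].copy()
    back = np.zeros((hi - lo, width), dtype=int)
    size = 2 * max_jump + 1
    offsets = np.arange(hi - lo)
    for x in range(1, width):
        prev_min = minimum_filter1d(acc, size=size, mode="reflect")
        # recover argmin within the window for backtracking
        idx = np.empty(hi - lo, dtype=int)
        for dz in range(-max_jump, max_jump + 1):
            cand = np.clip(offsets + dz, 0, hi - lo - 1)
            hit = acc[cand] == prev_min
            idx[hit] = cand[hit]
        back[:, x] = idx
        acc = sub[:, x] + prev_min
    path = np.empty(width, dtype=int)
    path[-1] = int(np.argmin(acc))
    for x in range(width - 1, 0, -1):
        path[x - 1] = back[path[x], x]
    return path + lo


def _profile_peaks(image: np.ndarray, min_prominence: float) -> np.ndarray:
    profile = image.mean(axis=1)
    profile = profile / profile.max() if profile.max() > 0 else profile
    peaks, _ = find_peaks(profile, prominence=min_prominence)
    return peaks


def segment_layers(
    image: np.ndarray,
    max_jump: int = 2,
    search_halfwidth: int = 5,
    min_separation: int = 6,
    min_prominence: float = 0.05,
    search_windows: dict[str, tuple[int, int]] | None = None,
) -> LayerBoundaries:
    """Segment ELM, IS/OS and BrM boundaries from an intensity B-scan.

    Candidate layer depths come from prominent peaks of the lateral-mean
    axial profile (BrM = most posterior, IS/OS = brightest sufficiently
    anterior, ELM = brightest anterior of IS/OS); each boundary is then the
    minimum-cost dark-to-light path within ``search_halfwidth`` of its
    candidate.  Explicit per-layer ``search_windows`` override the peak
    heuristic.  A layer with no usable peak raises
    :class:`SegmentationError` naming the layer; callers may pass windows
    for the remaining layers to segment those.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 3:
        raise ValueError("image must be 2-D with at least 3 depth pixels")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    cost = _gradient_cost(image)
    depth = image.shape[0]
    profile = image.mean(axis=1)

    def window_for(layer: str) -> tuple[int, int]:
        if search_windows and layer in search_windows:
            lo, hi = search_windows[layer]
            return max(0, int(lo)), min(depth, int(hi))
        raise KeyError

    windows: dict[str, tuple[int, int]] = {}
    missing: tuple[str, str] | None = None
    if search_windows is not None:
        for layer in ("BrM", "ISOS", "ELM"):
            try:
                windows[layer] = window_for(layer)
            except KeyError:
                missing = missing or (layer, "no search window given")
    else:
        peaks = _profile_peaks(image, min_prominence)
        if len(peaks) == 0:
            raise SegmentationError("BrM", "no prominent bands in the axial profile")
        brm_peak = int(peaks[-1])
        windows["BrM"] = (brm_peak - search_halfwidth, brm_peak + search_halfwidth + 1)
        def brightest_posterior(cands: np.ndarray) -> int:
            """Brightest candidate; near-ties (within 5%) resolved posteriorly."""
            vals = profile[cands]
            top = cands[vals >= 0.95 * vals.max()]
            return int(top.max())

        anterior = peaks[peaks <= brm_peak - min_separation]
        if len(anterior) == 0:
            missing = ("ISOS", "no band anterior to BrM")
        else:
            isos_peak = brightest_posterior(anterior)
            windows["ISOS"] = (isos_peak - search_halfwidth, isos_peak + search_halfwidth + 1)
            pre = anterior[anterior <= isos_peak - min_separation]
            if len(pre) == 0:
                missing = ("ELM", "no band anterior to IS/OS")
            else:
                elm_peak = brightest_posterior(pre)
                windows["ELM"] = (elm_peak - search_halfwidth, elm_peak + search_halfwidth + 1)

    paths: dict[str, np.ndarray] = {}
    brm = dp_shortest_path(cost, max_jump, windows["BrM"])
    paths["BrM"] = brm
    if "ISOS" in windows:
        isos_hi = min(windows["ISOS"][1], int(brm.min()) - 1)
        paths["ISOS"] = dp_shortest_path(cost, max_jump, (windows["ISOS"][0], isos_hi))
        if "ELM" in windows:
            elm_hi = min(windows["ELM"][1], int(paths["ISOS"].min()) - 1)
            paths["ELM"] = dp_shortest_path(cost, max_jump, (windows["ELM"][0], elm_hi))
    result = LayerBoundaries(paths=paths)
    if missing is not None:
        raise SegmentationError(missing[0], missing[1], partial=result)
    return result


def define_mixed_bands(boundaries: LayerBoundaries, n_bands: int = 5) -> np.ndarray:
    """Split the IS/OS -> BrM mixed layer into equal-depth sub-bands.

    Returns an int array ``[n_ascans, n_bands + 1]`` of band edges per
    A-scan.  Uneven intervals use a deterministic largest-remainder split
    (anterior bands get the extra pixels first); band 1 is the most
    anterior ("top band", presumed OS tips).
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    isos = boundaries.paths["ISOS"]
    brm = boundaries.paths["BrM"]
    widths = brm - isos
    if np.any(widths < n_bands):
        raise ValueError("mixed layer thinner than n_bands pixels")
    edges = np.empty((len(isos), n_bands + 1), dtype=int)
    for a, (z0, w) in enumerate(zip(isos, widths)):
        base, rem = divmod(int(w), n_bands)
        sizes = np.full(n_bands, base)
        sizes[:rem] += 1
        edges[a] = z0 + np.concatenate(([0], np.cumsum(sizes)))
    return edges
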