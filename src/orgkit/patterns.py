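"""Unsupervised discovery and supervised classification of ORG signals.

Pipeline: window each filtered phase trace to the feature window
(default -1.0 s to +3.5 s around stimulus onset, resampled to 5 ms),
normalize (zero mean, unit SD), extract the top two principal components
as temporal features, add the axial distance to BrM as the spatial
feature, min-max normalize the three axes, remove low-density outliers by
the coverage-radius rule, cut a Ward-linkage dendrogram into three
clusters, name them Type-I / intermediate / Type-II by depth, and train a
Gaussian-kernel SVM on the four labels (outlier included) for classifying
new traces — including traces from slower protocols, which are linearly
interpolated to the 5 ms grid and Gaussian-smoothed first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FEATURE_WINDOW",
    "FEATURE_DT",
    "OutlierParams",
    "FeatureSpace",
    "PatternModel",
    "normalize_trace",
    "normalize_traces",
    "resample_traces",
    "fit_pca",
    "build_feature_space",
    "detect_outliers",
    "ward_cluster",
    "assign_type_labels",
    "train_classifier",
    "classify_new",
    "discover_patterns",
    "table_to_matrix",
]

FEATURE_WINDOW = (-1.0, 3.5)  # s around stimulus onset
FEATURE_DT = 0.005            # s (5 ms grid)

LABELS = ("outlier", "intermediate", "type_I", "type_II")


@dataclass(frozen=True)
class OutlierParams:
    """Coverage-radius outlier rule.

    For each point, the radius of the smallest sphere covering a
    ``coverage_fraction`` share of the remaining points is its local
    density proxy; points with radius above ``Q3 + (Q3 - Q1)/divisor``
    (quartiles over all radii) are outliers.
    """

    coverage_fraction: float = 0.02
    divisor: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.coverage_fraction < 1:
            raise ValueError("coverage_fraction must be in (0, 1)")


def classification_lowpass(t: np.ndarray, X: np.ndarray, cutoff_hz: float = 10.0, order: int = 4) -> np.ndarray:
    """Zero-phase 10 Hz low-pass used ONLY on the classification branch.

    Reported signals are never low-pass filtered (to avoid distorting the
    fast OS response); this filter exists solely to stabilise the feature
    extraction.
    """
    from scipy import signal as sps

    fs = 1.0 / float(np.median(np.diff(np.asarray(t, dtype=float))))
    if cutoff_hz >= fs / 2:
        return np.asarray(X, dtype=float)
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(X, dtype=float), axis=1)


def table_to_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pivot a long trace table into (t, X, depth, ids, classes)."""
    wide = table.pivot_table(index="trace_id", columns="t_s", values="phase_rad", sort=False)
    meta = table.drop_duplicates("trace_id").set_index("trace_id")
    ids = wide.index.to_numpy()
    t = wide.columns.to_numpy(dtype=float)
    X = wide.to_numpy(dtype=float)
    depth = meta.loc[ids, "depth_px_to_brm"].to_numpy(dtype=float)
    classes = (
        meta.loc[ids, "class"].to_numpy() if "class" in meta else np.full(len(ids), "")
    )
    return t, X, depth, ids, classes


def resample_traces(
    t: np.ndarray,
    X: np.ndarray,
    window: tuple[float, float] = FEATURE_WINDOW,
    dt: float = FEATURE_DT,
    smooth_native_dt_ratio: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto the 5 ms feature grid, smoothing low-rate data.

    Traces already sampled at (or finer than) the target grid pass through
    unchanged apart from windowing.  Slower traces (native interval more
    than ``smooth_native_dt_ratio`` times the target) are linearly
    interpolated and then Gaussian-smoothed with a sigma of half the native
    interval, suppressing the interpolation's spectral replicas.
    """
    t = np.asarray(t, dtype=float)
    native_dt = float(np.median(np.diff(t)))
    if t[0] > window[0] + 1e-9 or t[-1] < window[1] - 1e-9:
        raise ValueError(
            f"trace span [{t[0]:.3f}, {t[-1]:.3f}] s does not cover the feature window {window}"
        )
    grid = np.arange(window[0], window[1] + dt / 2, dt)
    out = np.empty((X.shape[0], len(grid)))
    for i, row in enumerate(np.atleast_2d(X)):
        out[i] = np.interp(grid, t, row)
    if native_dt > smooth_native_dt_ratio * dt:
        sigma = 0.5 * native_dt / dt
        out = gaussian_filter1d(out, sigma=sigma, axis=1, mode="nearest")
    return grid, out


def normalize_trace(x: np.ndarray) -> np.ndarray:
    """Standardize one trace to zero mean, unit SD (amplitude-invariant)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant trace cannot be normalized")
    return (x - x.mean()) / sd


def normalize_traces(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise standardization; constant rows are flagged, not normalized."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    out = np.zeros_like(X)
    out[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    return out, ok


def fit_pca(X_norm: np.ndarray, n_components: int = 2) -> PCA:
    """Principal components of the normalized traces (pooled across subjects)."""
    X_norm = np.asarray(X_norm, dtype=float)
    if X_norm.ndim != 2 or X_norm.shape[0] < 3:
        raise ValueError("need >= 3 traces of equal length")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X_norm)
    return pca


@dataclass
class FeatureSpace:
    """Min-max axis normalization of (PC1, PC2, depth) with frozen constants."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, scores: np.ndarray, depth: np.ndarray) -> "FeatureSpace":
        raw = np.column_stack([scores[:, 0], scores[:, 1], depth])
        mins, maxs = raw.min(axis=0), raw.max(axis=0)
        if np.any(maxs == mins):
            raise ValueError("degenerate feature axis (max == min)")
        return cls(mins=mins, maxs=maxs)

    def transform(self, scores: np.ndarray, depth: np.ndarray) -> np.ndarray:
        """Project with the SAME constants; new points may fall outside [0, 1]."""
        raw = np.column_stack([scores[:, 0], scores[:, 1], np.asarray(depth, dtype=float)])
        return (raw - self.mins) / (self.maxs - self.mins)

    @staticmethod
    def in_range(points: np.ndarray) -> np.ndarray:
        """Flag points inside the training [0, 1]^3 cube (new points may leave it)."""
        points = np.asarray(points)
        return np.all((points >= 0.0) & (points <= 1.0), axis=1)


def build_feature_space(scores: np.ndarray, depth: np.ndarray) -> tuple[np.ndarray, FeatureSpace]:
    fs = FeatureSpace.fit(scores, depth)
    return fs.transform(scores, depth), fs


def coverage_radii(points: np.ndarray, coverage_fraction: float = 0.02) -> tuple[np.ndarray, int]:
    """Distance to the k-th nearest other point, k = ceil(f * (N - 1))."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    k = max(1, int(np.ceil(coverage_fraction * (n - 1))))
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for coverage k={k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    return dist[:, k], k  # column 0 is the point itself


def detect_outliers(points: np.ndarray, params: OutlierParams = OutlierParams()) -> np.ndarray:
    """Boolean outlier mask by the coverage-radius quartile rule."""
    radii, _ = coverage_radii(points, params.coverage_fraction)
    q1, q3 = np.percentile(radii, [25, 75])
    return radii > q3 + (q3 - q1) / params.divisor


def ward_cluster(points: np.ndarray, n_clusters: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage agglomerative clustering cut to ``n_clusters``.

    Returns (labels in 0..n_clusters-1, scipy linkage matrix).  Merge
    heights are non-decreasing (Ward is reducible), so cutting by cluster
    count equals thresholding the dendrogram.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < n_clusters:
        raise ValueError("fewer points than clusters")
    Z = linkage(points, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return labels, Z


def assign_type_labels(
    cluster_labels: np.ndarray,
    depth_norm: np.ndarray,
    traces: np.ndarray | None = None,
    t: np.ndarray | None = None,
) -> dict[int, str]:
    """Name 3 clusters by depth: nearest BrM = Type-II, farthest = Type-I.

    ``depth_norm`` is the normalized distance to BrM, so the Type-II (RPE)
    cluster has the *smallest* mean and the Type-I (OS) cluster the
    largest; the middle cluster is the intermediate transition band.  Depth
    ties break deterministically by cluster-mean peak latency (Type-I peaks
    earlier).  If trace data are given, the latency ordering is sanity
    checked and a warning is emitted on violation.
    """
    ids = np.unique(cluster_labels)
    if len(ids) != 3:
        raise ValueError("expected exactly 3 clusters")

    def latency(c: int) -> float:
        if traces is None or t is None:
            return 0.0
        mean_trace = traces[cluster_labels == c].mean(axis=0)
        post = t >= 0
        return float(t[post][np.argmax(mean_trace[post])])

    order = sorted(ids, key=lambda c: (float(depth_norm[cluster_labels == c].mean()), latency(c)))
    mapping = {order[0]: "type_II", order[1]: "intermediate", order[2]: "type_I"}
    if traces is not None and t is not None:
        inv = {v: k for k, v in mapping.items()}
        if latency(inv["type_I"]) > latency(inv["type_II"]):
            warnings.warn(
                "Type-I cluster peaks later than Type-II; depth-based naming may be unreliable",
                stacklevel=2,
            )
    return mapping


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_folds: int = 10,
    param_grid: dict | None = None,
) -> tuple[Pipeline, float]:
    """Gaussian-kernel SVM with standardized inputs and CV-tuned hyperparameters.

    Returns the refit best pipeline and its ``n_folds``-fold
    cross-validation accuracy.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    if param_grid is None:
        param_grid = {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale", 1.0, 3.0, 10.0]}
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, param_grid, cv=cv, scoring="accuracy", n_jobs=1)
    search.fit(np.asarray(features, dtype=float), labels)
    return search.best_estimator_, float(search.best_score_)


@dataclass
class PatternModel:
    """Persistable bundle: PCA basis, axis constants, SVM, provenance."""

    pca: PCA
    feature_space: FeatureSpace
    svm: Pipeline
    cv_accuracy: float
    seed: int
    feature_window: tuple[float, float] = FEATURE_WINDOW
    feature_dt: float = FEATURE_DT
    version: str = "1"

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "PatternModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError("file does not contain a PatternModel bundle")
        return model


def discover_patterns(
    t: np.ndarray,
    X: np.ndarray,
    depth: np.ndarray,
    seed: int = 0,
    outlier_params: OutlierParams = OutlierParams(),
    n_clusters: int = 3,
    train_svm: bool = True,
    window: tuple[float, float] = FEATURE_WINDOW,
) -> tuple[pd.DataFrame, PatternModel | None]:
    """Run the full unsupervised pipeline on windowed, filtered traces.

    Returns a per-trace table (label, pc1, pc2, depth_norm) and, when
    ``train_svm``, the fitted :class:`PatternModel`.  Constant traces are
    labelled outliers up front.
    """
    grid, Xw = resample_traces(t, X, window=window)
    Xn, ok = normalize_traces(Xw)
    pca = fit_pca(Xn[ok])
    scores = pca.transform(Xn[ok])
    feats, fs = build_feature_space(scores, depth[ok])
    out_mask = detect_outliers(feats, outlier_params)
    labels = np.full(len(feats), "outlier", dtype=object)
    keep = ~out_mask
    clusters, _ = ward_cluster(feats[keep], n_clusters)
    mapping = assign_type_labels(clusters, feats[keep][:, 2], Xn[ok][keep], grid)
    labels[keep] = [mapping[c] for c in clusters]

    all_labels = np.full(len(X), "outlier", dtype=object)
    all_labels[ok] = labels
    pc = np.full((len(X), 3), np.nan)
    pc[ok] = feats
    table = pd.DataFrame(
        {
            "label": all_labels,
            "pc1": pc[:, 0],
            "pc2": pc[:, 1],
            "depth_norm": pc[:, 2],
        }
    )
    model = None
    if train_svm:
        svm, acc = train_classifier(feats, labels, seed=seed)
        model = PatternModel(pca=pca, feature_space=fs, svm=svm, cv_accuracy=acc,
                             seed=seed, feature_window=window)
    return table, model


def classify_new(
    t: np.ndarray,
    X: np.ndarray,
    depth: np.ndarray,
    model: PatternModel,
) -> np.ndarray:
    """Classify new traces (any protocol rate) with a trained model.

    Low-rate traces are linearly interpolated to the 5 ms grid and
    Gaussian-smoothed, then normalized and projected with the SAME PCA
    basis and axis constants before SVM prediction.
    """
    _, Xw = resample_traces(t, X, window=model.feature_window, dt=model.feature_dt)
    Xn, ok = normalize_traces(Xw)
    labels = np.full(len(Xw), "outlier", dtype=object)
    if ok.any():
        scores = model.pca.transform(Xn[ok])
        feats = model.feature_space.transform(scores, np.asarray(depth)[ok])
        labels[ok] = model.svm.predict(feats)
    return labels
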