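"""In-memory containers and HDF5 / TSV input-output.

The on-disk container is a single HDF5 file:

* ``/frames_real``, ``/frames_imag`` — float32, ``[time, depth, lateral]``
  for B-scan series or ``[time, y, depth, x]`` for volume series
* ``/ground_truth`` — optional group of simulator ground-truth datasets
* attributes: ``center_wavelength_nm``, ``pixel_pitch_um_air``,
  ``frame_rate_hz``, ``stimulus_onset_s``, ``protocol_id``, ``schema_version``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "v1"

_REQUIRED_ATTRS = (
    "center_wavelength_nm",
    "pixel_pitch_um_air",
    "frame_rate_hz",
    "stimulus_onset_s",
    "protocol_id",
)


class SchemaError(ValueError):
    """Container file does not conform to the FrameSeries schema."""


@dataclass
class FrameSeries:
    """Time series of complex-valued OCT frames plus acquisition metadata.

    ``frames`` is complex with shape ``[time, depth, lateral]`` (B-scan
    series) or ``[time, y, depth, x]`` (volume series).  ``frame_rate_hz``
    is the rate at which the same location is revisited.
    """

    frames: np.ndarray
    center_wavelength_nm: float
    pixel_pitch_um_air: float
    frame_rate_hz: float
    stimulus_onset_s: float
    protocol_id: int = 1
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if not np.iscomplexobj(self.frames):
            raise ValueError("frames must be complex-valued")
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be [t, z, x] or [t, y, z, x]")

    @property
    def is_volume(self) -> bool:
        return self.frames.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def carrier_cycles_per_px(self) -> float:
        from .fourier import carrier_cycles_per_px

        return carrier_cycles_per_px(self.center_wavelength_nm, self.pixel_pitch_um_air)

    def times(self) -> np.ndarray:
        """Frame times (s) relative to stimulus onset."""
        return np.arange(self.n_frames) / self.frame_rate_hz - self.stimulus_onset_s

    def intensity(self) -> np.ndarray:
        return np.abs(self.frames) ** 2

    def with_frames(self, frames: np.ndarray) -> "FrameSeries":
        return FrameSeries(
            frames=frames,
            center_wavelength_nm=self.center_wavelength_nm,
            pixel_pitch_um_air=self.pixel_pitch_um_air,
            frame_rate_hz=self.frame_rate_hz,
            stimulus_onset_s=self.stimulus_onset_s,
            protocol_id=self.protocol_id,
            ground_truth=dict(self.ground_truth),
        )


def write_frameseries(path: str | Path, series: FrameSeries) -> None:
    """Write a :class:`FrameSeries` container (complex stored as float32 pairs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames_real", data=series.frames.real.astype(np.float32))
        f.create_dataset("frames_imag", data=series.frames.imag.astype(np.float32))
        gt = f.create_group("ground_truth")
        for key, value in series.ground_truth.items():
            gt.create_dataset(key, data=np.asarray(value))
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["center_wavelength_nm"] = series.center_wavelength_nm
        f.attrs["pixel_pitch_um_air"] = series.pixel_pitch_um_air
        f.attrs["frame_rate_hz"] = series.frame_rate_hz
        f.attrs["stimulus_onset_s"] = series.stimulus_onset_s
        f.attrs["protocol_id"] = series.protocol_id


def read_frameseries(path: str | Path) -> FrameSeries:
    """Read a :class:`FrameSeries` container, validating the schema."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"container schema {version!r} does not match {SCHEMA_VERSION!r}; "
                "re-export the file with this version of the package"
            )
        for name in ("frames_real", "frames_imag"):
            if name not in f:
                raise SchemaError(f"missing dataset {name!r}")
        missing = [a for a in _REQUIRED_ATTRS if a not in f.attrs]
        if missing:
            raise SchemaError(f"missing required attributes: {missing}")
        frames = f["frames_real"][...].astype(np.float32) + 1j * f["frames_imag"][
            ...
        ].astype(np.float32)
        gt = {}
        if "ground_truth" in f:
            for key in f["ground_truth"]:
                gt[key] = f["ground_truth"][key][...]
        return FrameSeries(
            frames=frames,
            center_wavelength_nm=float(f.attrs["center_wavelength_nm"]),
            pixel_pitch_um_air=float(f.attrs["pixel_pitch_um_air"]),
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            stimulus_onset_s=float(f.attrs["stimulus_onset_s"]),
            protocol_id=int(f.attrs["protocol_id"]),
            ground_truth=gt,
        )


@dataclass
class LayerBoundaries:
    """Per-frame, per-A-scan depth indices of named layer boundaries.

    ``paths`` maps layer name ('ELM', 'ISOS', 'BrM', ...) to an int array of
    shape ``[n_ascans]`` (single frame) holding the boundary depth index of
    each A-scan.  ``mixed_band_edges`` optionally holds, per A-scan, the
    ``n_bands + 1`` depth edges splitting the IS/OS -> BrM mixed layer.
    """

    paths: dict[str, np.ndarray]
    mixed_band_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.paths = {k: np.asarray(v, dtype=int) for k, v in self.paths.items()}
        order = [n for n in ("ELM", "ISOS", "BrM") if n in self.paths]
        for a, b in zip(order, order[1:]):
            if not np.all(self.paths[a] < self.paths[b]):
                raise ValueError(f"layer ordering violated: {a} must be anterior to {b}")

    def depth_to_brm(self, depth_px: np.ndarray, ascan: np.ndarray) -> np.ndarray:
        """Distance to BrM in pixels (positive anterior of BrM)."""
        return self.paths["BrM"][ascan] - np.asarray(depth_px)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for layer, path in self.paths.items():
            for a, z in enumerate(path):
                rows.append((0, a, layer, int(z)))
        return pd.DataFrame(rows, columns=["frame", "ascan", "layer", "depth_px"])


@dataclass
class PhaseTrace:
    """Unwrapped temporal phase trace of one pixel against a reference layer."""

    t: np.ndarray               # s, relative to stimulus onset
    phi: np.ndarray             # rad, unwrapped, zeroed at onset
    depth_to_brm: float         # px
    target_layer: str = ""
    reference_layer: str = ""
    prestim_sd: float = 0.0     # mrad
    valid: bool = True
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.t.shape != self.phi.shape:
            raise ValueError("t and phi must have matching shapes")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


@dataclass
class ORGSignal:
    """Average ΔOPL(t) in nm for a named retinal structure."""

    structure: str              # OS, RPE, IS, SRS, ELM_BrM, band_k, ...
    t: np.ndarray               # s
    dopl: np.ndarray            # nm
    n_pixels: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dopl = np.asarray(self.dopl, dtype=float)
        if self.t.shape != self.dopl.shape:
            raise ValueError("t and dopl must have matching shapes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": self.structure,
                "t_s": self.t,
                "dopl_nm": self.dopl,
                "n_pixels": self.n_pixels,
            }
        )


def traces_to_table(traces: list[PhaseTrace], labels: list[str] | None = None) -> pd.DataFrame:
    """Long-format TSV-ready table (trace_id, class, depth_px_to_brm, t_s, phase_rad)."""
    parts = []
    for i, tr in enumerate(traces):
        parts.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id or str(i),
                    "class": labels[i] if labels is not None else "",
                    "depth_px_to_brm": tr.depth_to_brm,
                    "t_s": tr.t,
                    "phase_rad": tr.phi,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def table_to_traces(table: pd.DataFrame) -> tuple[list[PhaseTrace], list[str]]:
    """Inverse of :func:`traces_to_table`."""
    traces, labels = [], []
    for tid, grp in table.groupby("trace_id", sort=False):
        grp = grp.sort_values("t_s")
        traces.append(
            PhaseTrace(
                t=grp["t_s"].to_numpy(),
                phi=grp["phase_rad"].to_numpy(),
                depth_to_brm=float(grp["depth_px_to_brm"].iloc[0]),
                trace_id=str(tid),
            )
        )
        labels.append(str(grp["class"].iloc[0]))
    return traces, labels
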