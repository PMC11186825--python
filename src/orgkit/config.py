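"""Run configuration: a single YAML file, schema-validated, explicit units.

Every analysis constant is surfaced as a named key with its default: the
60 mrad QC threshold, the 10 Hz classification low-pass, the 2% outlier
coverage and its quartile-rule divisor, the 5 ms feature grid, the
3-cluster dendrogram cut, the 840 nm centre wavelength and the 1.41 tissue
refractive index.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    protocol_id: int = 1

    # registration
    upsample: int = 100                      # cross-correlation refinement factor
    taper: float = 0.05                      # raised-cosine window fraction

    # segmentation
    max_jump_px: int = 2                     # lateral smoothness constraint
    n_mixed_bands: int = 5                   # sub-bands of the mixed layer

    # traces
    center_wavelength_nm: float = 840.0
    tissue_refractive_index: float = 1.41    # physical-deformation conversion only
    bandstop_bands_hz: list = field(
        default_factory=lambda: [[4.9, 5.1], [0.95, 1.05]]
    )
    lowpass_cutoff_hz: float = 10.0          # classification branch only
    qc_threshold_mrad: float = 60.0          # strict ">" excludes
    trim_s: float = 0.2

    # feature space / clustering
    feature_window_s: list = field(default_factory=lambda: [-1.0, 3.5])
    feature_dt_s: float = 0.005              # 5 ms interpolation grid
    outlier_coverage_fraction: float = 0.02
    outlier_divisor: float = 5.0             # threshold Q3 + (Q3 - Q1)/divisor
    n_clusters: int = 3

    # quantification
    srs_slope_window_s: list = field(default_factory=lambda: [2.0, 10.0])
    photosensitivity_um2: float = 1.26e-8    # rhodopsin photosensitivity P
    fov_deg: float = 12.0
    cell_deg: list = field(default_factory=lambda: [1.2, 0.48])

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; unknown keys raise ``ValueError``."""
    data: dict = {}
    if path is not None:
        with open(path) as f:
            data = yaml.safe_load(f) or {}
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
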