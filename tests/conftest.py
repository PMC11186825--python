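"""Shared fixtures: small synthetic recordings reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest

from orgkit.specs import KineticsSpec, MotionSpec, OpticsSpec, ProtocolSpec
from orgkit.synthetic import simulate_bscan_series

STILL = MotionSpec(drift_amplitude=0.0, heartbeat_amp=0.0, respiration_amp=0.0)


@pytest.fixture(scope="session")
def optics():
    return OpticsSpec()


@pytest.fixture(scope="session")
def static_series():
    """Short noise-free-kinetics series with no bulk motion (speckle only)."""
    protocol = ProtocolSpec(bscan_rate=50.0, duration=1.0, baseline=0.2)
    kin = replace(
        KineticsSpec(),
        type_I_amp=0.0,
        type_I_undershoot_amp=0.0,
        type_II_rate=0.0,
        srs_peak_amp=0.0,
        srs_slope=1e-6,
        is_compression_amp=0.0,
        rpe_contraction_amp=0.0,
    )
    return simulate_bscan_series(
        kinetics=kin, motion=STILL, protocol=protocol,
        depth_px=160, lateral_px=64, seed=101,
    )


@pytest.fixture(scope="session")
def speckle_frame(static_series):
    """One complex speckle B-scan."""
    return static_series.frames[0].astype(complex)


@pytest.fixture(scope="session")
def prolonged_analysis():
    """Full image-pipeline result on a prolonged (slow-rate) recording.

    Programmed kinetics: 100 nm OS elongation, 250 nm SRS expansion peaking
    around 20 s.  Shared by trace-, quantify- and acceptance-level tests.
    """
    from orgkit.pipeline import analyze_bscan_series

    kin = replace(KineticsSpec(), type_I_amp=100.0)
    protocol = ProtocolSpec(bscan_rate=25.0, duration=30.0, baseline=2.0)
    series = simulate_bscan_series(
        kinetics=kin, protocol=protocol, depth_px=160, lateral_px=64, seed=11
    )
    result = analyze_bscan_series(series, seed=3)
    return series, result
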