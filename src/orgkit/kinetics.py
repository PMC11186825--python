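"""Analytic stimulus-locked kinetics templates and layer-displacement model.

All templates are zero for t <= onset (flat pre-stimulus baseline), smooth,
and evaluable on arbitrary time grids, in nm of optical path length (OPL).

The B-scan simulator anchors Bruch's membrane (BrM) and derives per-layer
axial displacements (positive = posterior, toward larger depth index) such
that the programmed pairwise signals hold exactly:

* ``OS tips rel IS/OS``      = Type-I OS elongation ``O(t)``
* ``RPE rel IS/OS``          = Type-II signal ``S(t) - isl(t)``
* ``IS/OS rel ELM``          = inner-segment length change ``isl(t)``
* SRS (RPE apical rel ELM)   = ``S(t)``

so the telescoping identity SRS = Type-II + (IS/OS rel ELM expansion) is
exact on the ground truth.
"""

from __future__ import annotations

import numpy as np

from .specs import KineticsSpec

__all__ = [
    "gamma_pulse",
    "type_i_curve",
    "type_ii_curve",
    "srs_curve",
    "is_length_curve",
    "rpe_contraction_curve",
    "layer_displacements",
    "CLASS_CURVES",
]

#: fraction of the SRS expansion mirrored by the inner segment after its
#: initial compression (IS follows SRS at lower amplitude).
IS_SRS_COUPLING = 0.4


def gamma_pulse(t: np.ndarray, t_peak: float, k: float) -> np.ndarray:
    """Unit-peak gamma-shaped pulse: ``(t/tp)^k * exp(k*(1 - t/tp))``, 0 for t<=0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_peak
    out[pos] = x**k * np.exp(k * (1.0 - x))
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def type_i_curve(t: np.ndarray, kin: KineticsSpec) -> np.ndarray:
    """Fast OS elongation: rapid rise to the peak, then a slow undershoot.

    The undershoot pulse width is set so the trace returns to within 5% of
    baseline by ``type_I_recovery_time``.
    """
    ratio = kin.type_I_recovery_time / kin.type_I_undershoot_latency
    r = ratio * np.exp(1.0 - ratio)
    k_u = np.log(0.05) / np.log(r) if 0 < r < 1 else 2.5
    rise = kin.type_I_amp * gamma_pulse(t, kin.type_I_peak_latency, 4.0)
    under = kin.type_I_undershoot_amp * gamma_pulse(t, kin.type_I_undershoot_latency, k_u)
    return rise - under


def type_ii_curve(t: np.ndarray, kin: KineticsSpec, tau: float = 20.0) -> np.ndarray:
    """Slow RPE-referenced rise: initial rate ``type_II_rate``, saturating."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - kin.type_II_onset, 0.0, None)
    return kin.type_II_rate * tau * (1.0 - np.exp(-dt / tau))


def srs_curve(t: np.ndarray, kin: KineticsSpec,
              smooth_s: float = 0.7, recovery_tau: float = 40.0) -> np.ndarray:
    """Subretinal-space expansion: delayed smoothed ramp with slow recovery.

    Rises at ``srs_slope`` from ``srs_onset`` until ``srs_peak_amp`` is
    reached, holds to ``srs_peak_latency``, then decays with time constant
    ``recovery_tau``; corners smoothed over ``smooth_s`` seconds.
    """
    t = np.asarray(t, dtype=float)
    t_reach = kin.srs_onset + kin.srs_peak_amp / max(kin.srs_slope, 1e-9)
    b = smooth_s
    ramp = kin.srs_slope * b * (
        _softplus((t - kin.srs_onset) / b) - _softplus((t - t_reach) / b)
    )
    br = 2.0
    rec = np.exp(-_softplus((t - kin.srs_peak_latency) / br) * br / recovery_tau)
    return ramp * rec


def is_length_curve(t: np.ndarray, kin: KineticsSpec) -> np.ndarray:
    """Inner-segment length change: fast ~10 nm compression, then follows SRS."""
    dip = -kin.is_compression_amp * gamma_pulse(t, 1.0, 2.0)
    return dip + IS_SRS_COUPLING * srs_curve(t, kin)


def rpe_contraction_curve(t: np.ndarray, kin: KineticsSpec) -> np.ndarray:
    """RPE thinning (positive = contraction), peaking a few seconds post-flash."""
    return kin.rpe_contraction_amp * gamma_pulse(t, kin.rpe_contraction_latency, 2.0)


def layer_displacements(t: np.ndarray, kin: KineticsSpec) -> dict[str, np.ndarray]:
    """Per-layer axial OPL displacement (nm, positive posterior), BrM anchored."""
    S = srs_curve(t, kin)
    O = type_i_curve(t, kin)
    isl = is_length_curve(t, kin)
    C = rpe_contraction_curve(t, kin)
    u_rpe = C                     # apical surface moves posteriorly on thinning
    u_elm = u_rpe - S             # SRS expansion pushes ELM anteriorly
    u_isos = u_elm + isl
    u_tips = u_isos + O
    u_os = 0.5 * (u_isos + u_tips)
    zeros = np.zeros_like(np.asarray(t, dtype=float))
    return {
        "ELM": u_elm,
        "ISOS": u_isos,
        "OS": u_os,
        "OStips": u_tips,
        "IZ": u_rpe,   # microvilli move with the RPE apical surface
        "RPE": u_rpe,
        "BrM": zeros,
    }


def pairwise_signals(t: np.ndarray, kin: KineticsSpec) -> dict[str, np.ndarray]:
    """Ground-truth structure signals implied by :func:`layer_displacements`."""
    S = srs_curve(t, kin)
    isl = is_length_curve(t, kin)
    return {
        "OS": type_i_curve(t, kin),        # OS tips rel IS/OS
        "TypeII": S - isl,                 # RPE rel IS/OS
        "IS": isl,                         # IS/OS rel ELM (expansion-positive)
        "SRS": S,                          # RPE apical rel ELM
        "RPE": -rpe_contraction_curve(t, kin),  # BrM rel RPE (expansion-positive)
    }


#: trace-class templates used by the phase-trace simulator
CLASS_CURVES = {
    "type_I": type_i_curve,
    "type_II": type_ii_curve,
}
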