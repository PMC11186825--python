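"""Band-pass-aware sub-pixel Fourier shifts for complex OCT frames.

A reconstructed complex OCT A-scan is a band-pass signal in depth: a
reflector at optical path length (OPL) ``z`` contributes an envelope around
``z`` carrying the interferometric phase ``4*pi*z/lambda_c`` (double-pass
reflection geometry).  Sampled at the axial pixel pitch, the carrier is
usually aliased, so an ordinary (baseband) FFT shift would translate the
envelope while assigning the wrong phase to the moved reflector.  The shift
operators here apply the linear phase ramp at the *true*, unaliased axial
frequencies recovered from the known carrier — equivalently, they multiply
the exponential terms in the spectral (depth-conjugate) domain — so that a
translated reflector also acquires the physically correct phase offset.
Both the synthetic scatterer simulator and the phase-restoring motion
correction are built on this single operator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "carrier_cycles_per_px",
    "axial_shift",
    "lateral_shift",
    "subpixel_shift",
]


def carrier_cycles_per_px(center_wavelength_nm: float, pixel_pitch_um_air: float) -> float:
    """Signed axial carrier frequency in cycles per depth pixel.

    The double-pass phase advances by ``4*pi/lambda_c`` per unit OPL, i.e.
    ``2 * pitch / lambda_c`` cycles per pixel in magnitude.  The complex
    image of a reflector at depth ``z`` carries ``exp(+i * 4*pi*z/lambda)``
    from the reflector position but oscillates as
    ``exp(-i * 4*pi*p/lambda)`` along the image depth axis ``p``, so the
    signed carrier is negative: translating content deeper *increases* its
    phase.  The value is typically super-Nyquist; aliasing is handled by
    the shift operators.
    """
    if center_wavelength_nm <= 0 or pixel_pitch_um_air <= 0:
        raise ValueError("wavelength and pitch must be positive")
    return -2.0 * (pixel_pitch_um_air * 1e3) / center_wavelength_nm


def _true_axial_freqs(n: int, carrier: float) -> np.ndarray:
    """Unalias FFT bin frequencies into the band centred on ``carrier``.

    Each baseband frequency ``nu_a`` in [-0.5, 0.5) is mapped to the unique
    congruent frequency in ``[carrier - 0.5, carrier + 0.5)``.
    """
    nu_a = np.fft.fftfreq(n)
    return nu_a + np.round(carrier - nu_a)


def axial_shift(frame: np.ndarray, dz_px: float, carrier: float, axis: int = 0) -> np.ndarray:
    """Translate a complex frame by ``dz_px`` pixels along the depth axis.

    Positive ``dz_px`` moves content toward larger depth index (posteriorly)
    and advances the reflector phase by ``2*pi*carrier*dz_px``.
    """
    if not np.isfinite(dz_px):
        raise ValueError("shift must be finite")
    if dz_px == 0.0:
        return frame.astype(np.complex128, copy=True)
    n = frame.shape[axis]
    nu = _true_axial_freqs(n, carrier)
    ramp = np.exp(-2j * np.pi * nu * dz_px)
    shape = [1] * frame.ndim
    shape[axis] = n
    spec = np.fft.fft(frame, axis=axis)
    return np.fft.ifft(spec * ramp.reshape(shape), axis=axis)


def lateral_shift(frame: np.ndarray, dx_px: float, axis: int = -1) -> np.ndarray:
    """Translate a complex frame by ``dx_px`` pixels along the lateral axis.

    The lateral axis carries no interferometric carrier, so this is an
    ordinary baseband Fourier shift (linear ramp in the lateral
    spatial-frequency domain).
    """
    if not np.isfinite(dx_px):
        raise ValueError("shift must be finite")
    if dx_px == 0.0:
        return frame.astype(np.complex128, copy=True)
    n = frame.shape[axis]
    nu = np.fft.fftfreq(n)
    ramp = np.exp(-2j * np.pi * nu * dx_px)
    shape = [1] * frame.ndim
    shape[axis] = n
    spec = np.fft.fft(frame, axis=axis)
    return np.fft.ifft(spec * ramp.reshape(shape), axis=axis)


def subpixel_shift(
    frame: np.ndarray,
    dz_px: float,
    dx_px: float,
    carrier: float,
    depth_axis: int = 0,
    lateral_axis: int = -1,
) -> np.ndarray:
    """Rigid in-plane translation (depth, lateral) with phase restoration."""
    out = frame
    if dz_px != 0.0:
        out = axial_shift(out, dz_px, carrier, axis=depth_axis)
    if dx_px != 0.0:
        out = lateral_shift(out, dx_px, axis=lateral_axis)
    if out is frame:
        out = frame.astype(np.complex128, copy=True)
    return out
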