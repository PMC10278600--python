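"""Phase reconstruction from off-axis holograms.

An off-axis hologram encodes the object phase on a spatial carrier:
``I = 1 + c·cos(2π f·x + φ)``. In the Fourier plane this produces a DC
term and two conjugate sidebands centred at ±f; the object phase is the
argument of the demodulated +1 sideband.

Implementation notes. The textbook recipe (FFT, mask the +1 sideband,
inverse FFT) suffers from spectral leakage at the field border whenever
the carrier does not complete an integer number of cycles, which is the
generic case. Here the hologram is instead demodulated in real space
(multiplied by ``exp(-2πi f·x)``), so the object term sits exactly at
baseband for any carrier direction; the complex product is
reflection-padded — reflection keeps the object term at baseband and
every interferer at radius ≥ |f| — apodised with a Tukey window whose
taper lies entirely in the padding, low-pass filtered with a circular
raised-cosine window of radius |f|/2, and cropped back. Residual border
leakage from the DC offset and the conjugate sideband is removed by a
short fixed-point iteration that re-estimates both terms from the
current phase estimate and subtracts them before re-demodulating; each
pass contracts the leakage by the leakage ratio itself, so a handful of
iterations reach ≈ 1e-5 rad on noise-free fringes. Finally the phase is
2-D unwrapped, a plane fitted on the (assumed specimen-free) border
ring is removed, and the border median is set to 0 rad.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift
from scipy.signal.windows import tukey
from skimage.restoration import unwrap_phase

__all__ = ["reconstruct_phase", "detrend_background", "estimate_carrier"]


def estimate_carrier(intensity: np.ndarray) -> tuple[float, float]:
    """Locate the +1 sideband peak of a hologram (cycles/pixel, (fy, fx)).

    Searches the magnitude spectrum outside a small DC exclusion zone,
    restricted to the fx ≥ 0 half plane (the conjugate sideband is
    redundant).
    """
    I = np.asarray(intensity, dtype=np.float64)
    H, W = I.shape
    F = fftshift(fft2(I - I.mean()))
    mag = np.abs(F)
    fy = np.fft.fftshift(np.fft.fftfreq(H))
    fx = np.fft.fftshift(np.fft.fftfreq(W))
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    mag[(FX < 0) | (np.hypot(FY, FX) < 2.0 / min(H, W))] = 0.0
    iy, ix = np.unravel_index(np.argmax(mag), mag.shape)
    return float(fy[iy]), float(fx[ix])


def reconstruct_phase(
    intensity: np.ndarray,
    carrier_frequency: float | tuple[float, float] | None = None,
    border_px: int = 4,
    pad_frac: float = 0.15,
    n_iter: int = 4,
) -> np.ndarray:
    """Demodulate an off-axis hologram into a phase map (radians).

    Parameters
    ----------
    intensity
        Recorded hologram, non-negative.
    carrier_frequency
        Carrier in cycles/pixel (scalar → fringes along x). Estimated
        from the spectrum when omitted.
    border_px
        Width of the border ring assumed specimen-free, used to remove
        the residual carrier tilt and to zero the background median.
    pad_frac
        Reflection padding per side as a fraction of the field size.
    n_iter
        Fixed-point passes of DC/conjugate re-estimation.

    Raises
    ------
    ValueError
        If the carrier is so low that the sideband filter would overlap
        the DC term, or so high that the aliased conjugate sideband
        (at 1 − 2|f| cycles/pixel) would enter the passband.
    """
    I = np.asarray(intensity, dtype=np.float64)
    if I.ndim != 2:
        raise ValueError("hologram must be a 2-D intensity image")
    if I.min() < -1e-9:
        raise ValueError("hologram intensities must be non-negative")
    H, W = I.shape
    if carrier_frequency is None:
        f = np.array(estimate_carrier(I))
    elif np.isscalar(carrier_frequency):
        f = np.array([0.0, float(carrier_frequency)])
    else:
        f = np.asarray(carrier_frequency, dtype=np.float64)
    fmag = float(np.hypot(*f))
    if not 0 < fmag < 0.5:
        raise ValueError("carrier magnitude must lie in (0, 0.5) cycles/pixel")
    radius = fmag / 2.0
    edge = 0.25 * radius
    if radius * min(H, W) < 3:
        raise ValueError(
            "sideband filter radius below 3 frequency bins: the sideband would "
            "overlap the DC term — increase the carrier frequency")
    if 1.0 - 2.0 * fmag < radius + edge:
        raise ValueError(
            "carrier too high: the aliased conjugate sideband at "
            f"{1 - 2 * fmag:.3f} cycles/pixel falls inside the demodulation "
            "passband — lower the carrier below ≈ 0.38 cycles/pixel")

    yy, xx = np.mgrid[:H, :W]
    carrier = np.exp(2j * np.pi * (f[0] * yy + f[1] * xx))
    pad = max(8, int(np.ceil(pad_frac * min(H, W))))

    def lowpass_baseband(z: np.ndarray) -> np.ndarray:
        """Demodulate by the carrier, reflect-pad, apodise, low-pass, crop."""
        bp = np.pad(z * np.conj(carrier), pad, mode="reflect")
        Hp, Wp = bp.shape
        alpha = 2.0 * pad / min(Hp, Wp)  # taper confined to the padding
        bp *= np.outer(tukey(Hp, alpha), tukey(Wp, alpha))
        F = fftshift(fft2(bp))
        r = np.hypot(np.fft.fftshift(np.fft.fftfreq(Hp))[:, None],
                     np.fft.fftshift(np.fft.fftfreq(Wp))[None, :])
        window = np.where(
            r <= radius - edge, 1.0,
            np.where(r >= radius + edge, 0.0,
                     0.5 * (1 + np.cos(np.pi * (r - radius + edge) / (2 * edge)))))
        return ifft2(ifftshift(F * window))[pad:pad + H, pad:pad + W]

    # effective window response, for de-apodising the sideband estimate
    response = np.clip(lowpass_baseband(carrier).real, 0.2, None)
    dc = I.mean()
    sideband = np.zeros_like(I, dtype=complex)
    demod = None
    for _ in range(max(1, n_iter)):
        demod = lowpass_baseband(I - dc - np.conj(sideband))
        sideband = (demod / response) * carrier
        dc = float((I - 2.0 * np.real(sideband)).mean())

    phase = np.asarray(unwrap_phase(np.angle(demod)), dtype=np.float64)
    # flatten: remove the plane fitted on the border ring, zero its median
    b = max(1, border_px)
    ring = np.zeros((H, W), dtype=bool)
    ring[:b], ring[-b:], ring[:, :b], ring[:, -b:] = True, True, True, True
    A = np.column_stack([np.ones(int(ring.sum())), yy[ring], xx[ring]])
    coef, *_ = np.linalg.lstsq(A, phase[ring], rcond=None)
    phase = phase - (coef[0] + coef[1] * yy + coef[2] * xx)
    phase -= np.median(phase[ring])
    return phase


def detrend_background(
    phase: np.ndarray,
    background_mask: np.ndarray,
    degree: int = 2,
) -> np.ndarray:
    """Remove a smooth background surface from a phase map.

    Fits a 2-D polynomial of the given degree over the cell-free pixels
    and subtracts it, so the background median becomes 0 rad (and the
    dry-mass density reads 0 pg/µm² off-cell). When fewer than 10% of
    the pixels are background a warning is emitted and only the global
    median is subtracted.
    """
    phase = np.asarray(phase, dtype=np.float64)
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != phase.shape:
        raise ValueError("background mask shape must match the phase map")
    if mask.sum() < 0.10 * mask.size:
        warnings.warn(
            "fewer than 10% background pixels: subtracting the global median only",
            stacklevel=2)
        return phase - np.median(phase)
    H, W = phase.shape
    yy, xx = np.mgrid[:H, :W]
    # normalised coordinates keep the Vandermonde system well conditioned
    yn, xn = yy / max(H - 1, 1), xx / max(W - 1, 1)
    terms = [yn ** i * xn ** j
             for i in range(degree + 1) for j in range(degree + 1 - i)]
    A = np.column_stack([t[mask] for t in terms])
    coef, *_ = np.linalg.lstsq(A, phase[mask], rcond=None)
    surface = sum(c * t for c, t in zip(coef, terms))
    out = phase - surface
    out -= np.median(out[mask])
    return out
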