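"""Two-channel colocalization: Pearson correlation and ICCS.

Image cross-correlation spectroscopy (ICCS) extends ICS to two channels: the
normalized cross-correlation

    G_ab(ξ, η) = ⟨δI_a(x, y) · δI_b(x + ξ, y + η)⟩ / (⟨I_a⟩·⟨I_b⟩)

has zero-lag amplitude proportional to the density of particles present in
*both* channels, so the amplitude ratio G_ab(0)/G_bb(0) estimates the
fraction of a-channel clusters interacting with b-channel clusters (and
symmetrically with aa for the other direction).  All three amplitudes are
taken from Lorentzian fits of the central profiles, as in single-channel ICS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import FitError
from .ics import AutocorrSurface, autocorrelate, extract_g_curve, fit_lorentzian
from .images import HyphaMask, Image2D

__all__ = ["ColocResult", "pearson", "cross_correlate", "iccs_fraction"]


@dataclass
class ColocResult:
    """Colocalization summary for a channel pair (a, b)."""

    pearson_r: float
    iccs_fraction: float          # fraction of a-clusters interacting with b
    fraction_b_with_a: float
    g_aa0: float
    g_bb0: float
    g_ab0: float
    n_pixels_used: int

    @property
    def pathological(self) -> bool:
        """Amplitude ratios far above 1 indicate a fit pathology."""
        return self.iccs_fraction > 1.5 or self.fraction_b_with_a > 1.5


def pearson(a: Image2D, b: Image2D, mask: HyphaMask | None = None) -> float:
    """Sample Pearson correlation of the two channels over in-mask pixels."""
    if a.shape != b.shape:
        raise ValueError("channels must share shape")
    if mask is not None:
        if mask.mask.shape != a.shape:
            raise ValueError("mask must share the image shape")
        va, vb = a.pixels[mask.mask], b.pixels[mask.mask]
    else:
        va, vb = a.pixels.ravel(), b.pixels.ravel()
    if va.size < 2:
        raise ValueError("need at least 2 pixels in scope")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant channel: correlation undefined")
    return float(sstats.pearsonr(va, vb).statistic)


def cross_correlate(a: Image2D, b: Image2D) -> AutocorrSurface:
    """Normalized fluctuation cross-correlation G_ab via FFT, zero lag centered."""
    if a.shape != b.shape:
        raise ValueError("channels must share shape")
    h, w = a.shape
    if h != w or (h & (h - 1)) != 0:
        raise ValueError("channels must be 2^n × 2^n")
    mean_a, mean_b = a.pixels.mean(), b.pixels.mean()
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("channel means must be positive")
    da = a.pixels - mean_a
    db = b.pixels - mean_b
    corr = np.fft.ifft2(np.fft.fft2(da) * np.conj(np.fft.fft2(db))).real / da.size
    g = np.fft.fftshift(corr) / (mean_a * mean_b)
    return AutocorrSurface(g=g, n_pix=h)


def iccs_fraction(a: Image2D, b: Image2D, mode: str = "horizontal",
                  exclude_zero_lag: bool = True) -> ColocResult:
    """Interacting-cluster fractions from fitted ICCS amplitudes.

    Fits Lorentzians to the central profiles of G_aa, G_bb and G_ab and
    returns G_ab(0)/G_bb(0) (fraction of a interacting with b) together with
    the reverse direction and the whole-frame Pearson coefficient.  Both
    channels are expected background-subtracted.
    """
    curves = {}
    for name, surface in (("aa", autocorrelate(a)), ("bb", autocorrelate(b)),
                          ("ab", cross_correlate(a, b))):
        try:
            curves[name] = fit_lorentzian(
                extract_g_curve(surface, mode=mode),
                exclude_zero_lag=exclude_zero_lag)
        except FitError as exc:
            raise FitError(f"ICCS fit failed for G_{name}: {exc}",
                           exc.diagnostics) from exc
    g_aa0, g_bb0, g_ab0 = (curves[k].g0 for k in ("aa", "bb", "ab"))
    if g_aa0 <= 0 or g_bb0 <= 0:
        raise FitError("non-positive autocorrelation amplitude")
    return ColocResult(
        pearson_r=pearson(a, b),
        iccs_fraction=float(g_ab0 / g_bb0),
        fraction_b_with_a=float(g_ab0 / g_aa0),
        g_aa0=float(g_aa0),
        g_bb0=float(g_bb0),
        g_ab0=float(g_ab0),
        n_pixels_used=int(a.pixels.size),
    )
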