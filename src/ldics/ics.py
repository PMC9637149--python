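"""Image Correlation Spectroscopy on THG images.

The normalized spatial fluctuation autocorrelation

    G(ξ, η) = ⟨δI(x, y) · δI(x + ξ, y + η)⟩ / ⟨I⟩²,   δI = I − ⟨I⟩,

computed by FFT with periodic lags, has zero-lag amplitude inversely
proportional to the number of independent bright particles in the frame and a
central-lobe width set by the particle size.  A 1D profile through zero lag
(the G curve) is fitted with a Lorentzian L(ξ) = g0·w²/(ξ² + w²) + offset;
the droplet count follows from the amplitude and half-width as

    N_LD = N_pix² / (r² · π · G(0)),   r = FWHM / 2 = w,

with r in pixels and N_pix the side of the 2ⁿ×2ⁿ frame (the formula is
unit-consistent only when both share units).  Reported diameters are
FWHM · pixel_size in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitError
from .images import HyphaMask, Image2D

__all__ = [
    "AutocorrSurface",
    "GCurve",
    "LorentzianParams",
    "QuantResult",
    "to_pow2_square",
    "autocorrelate",
    "extract_g_curve",
    "fit_lorentzian",
    "count_lds",
    "quantify",
]


@dataclass
class AutocorrSurface:
    """2D autocorrelation G(ξ, η); zero lag at index (n_pix//2, n_pix//2)."""

    g: np.ndarray
    n_pix: int

    @property
    def zero_lag(self) -> float:
        c = self.n_pix // 2
        return float(self.g[c, c])


@dataclass
class GCurve:
    """1D autocorrelation profile through zero lag."""

    lags_pix: np.ndarray
    values: np.ndarray
    n_pix: int | None = None


@dataclass
class LorentzianParams:
    """Fitted Lorentzian G-curve parameters.

    ``w_pix`` is the half width at half maximum; the mean droplet radius is
    taken as r = FWHM/2 = w, so ``r_pix == w_pix`` and ``fwhm_pix == 2·w_pix``.
    """

    g0: float
    w_pix: float
    offset: float

    @property
    def r_pix(self) -> float:
        return self.w_pix

    @property
    def fwhm_pix(self) -> float:
        return 2.0 * self.w_pix


@dataclass
class QuantResult:
    """Droplet count, area density and mean diameter from one method."""

    n_ld: float
    density_per_um2: float
    mean_diameter_um: float
    method: str  # "ICS" or "PSA"


def to_pow2_square(image: Image2D, mode: str = "crop_center") -> Image2D:
    """Return a 2ⁿ×2ⁿ version of the image.

    ``crop_center``: largest centered power-of-2 crop that fits.
    ``pad_zero``: zero-pad (centered) up to the next power of 2.
    """
    h, w = image.shape
    if mode == "crop_center":
        side = 2 ** int(np.floor(np.log2(min(h, w))))
        r0 = (h - side) // 2
        c0 = (w - side) // 2
        return image.with_pixels(image.pixels[r0:r0 + side, c0:c0 + side])
    if mode == "pad_zero":
        side = 2 ** int(np.ceil(np.log2(max(h, w))))
        if (h, w) == (side, side):
            return image.with_pixels(image.pixels)
        out = np.zeros((side, side))
        r0 = (side - h) // 2
        c0 = (side - w) // 2
        out[r0:r0 + h, c0:c0 + w] = image.pixels
        return image.with_pixels(out)
    raise ValueError(f"unknown mode {mode!r}")


def _check_pow2_square(pixels: np.ndarray) -> int:
    h, w = pixels.shape
    if h != w or (h & (h - 1)) != 0:
        raise ValueError("image must be 2^n × 2^n; use to_pow2_square first")
    return h


def autocorrelate(image: Image2D) -> AutocorrSurface:
    """Normalized fluctuation autocorrelation via FFT (periodic lags).

    Identical to the direct-shift definition with circular shifts; the result
    is shifted so zero lag sits at the center of the grid.
    """
    n = _check_pow2_square(image.pixels)
    mean = image.pixels.mean()
    if mean <= 0:
        raise ValueError("image mean must be positive for ICS normalization")
    delta = image.pixels - mean
    f = np.fft.fft2(delta)
    corr = np.fft.ifft2(f * np.conj(f)).real / delta.size
    g = np.fft.fftshift(corr) / mean ** 2
    return AutocorrSurface(g=g, n_pix=n)


def extract_g_curve(surface: AutocorrSurface, mode: str = "horizontal") -> GCurve:
    """Extract the 1D G curve through zero lag.

    ``horizontal``/``vertical``: the central row/column (the classic profile
    through the center of the autocorrelation image).  ``radial_mean``:
    azimuthal average at 1-pixel radial bins, mirrored to negative lags —
    a variance-reduction option valid because droplets are isotropic.
    """
    n = surface.n_pix
    c = n // 2
    lags = np.arange(n) - c
    if mode == "horizontal":
        return GCurve(lags_pix=lags.astype(float), values=surface.g[c, :].copy(),
                      n_pix=n)
    if mode == "vertical":
        return GCurve(lags_pix=lags.astype(float), values=surface.g[:, c].copy(),
                      n_pix=n)
    if mode == "radial_mean":
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(yy - c, xx - c)
        bins = np.rint(r).astype(int)
        max_bin = c
        sums = np.bincount(bins.ravel(), weights=surface.g.ravel())
        counts = np.bincount(bins.ravel())
        radial = sums[: max_bin + 1] / counts[: max_bin + 1]
        lags_sym = np.arange(-max_bin, max_bin + 1, dtype=float)
        values_sym = np.concatenate([radial[::-1], radial[1:]])
        return GCurve(lags_pix=lags_sym, values=values_sym, n_pix=n)
    raise ValueError(f"unknown mode {mode!r}")


def _lorentzian(xi, g0, w, offset):
    return g0 * w ** 2 / (xi ** 2 + w ** 2) + offset


def fit_lorentzian(curve: GCurve, exclude_zero_lag: bool = True) -> LorentzianParams:
    """Least-squares Lorentzian fit of the G curve.

    With ``exclude_zero_lag`` the single ξ = 0 sample — which carries the
    uncorrelated shot-noise spike — is omitted, and G(0) is the *fitted*
    amplitude rather than the sampled zero-lag value.  The additive offset
    absorbs any residual pedestal (e.g. from incompletely removed wall).
    """
    lags = np.asarray(curve.lags_pix, dtype=float)
    values = np.asarray(curve.values, dtype=float)
    if len(lags) < 5:
        raise ValueError("G curve needs at least 5 points")
    if exclude_zero_lag:
        keep = lags != 0
        lags, values = lags[keep], values[keep]

    n = curve.n_pix if curve.n_pix is not None else int(2 * lags.max())
    w_max = max(n / 4.0, 2.0)

    offset0 = float(np.median(values[np.abs(lags) >= 0.8 * lags.max()]))
    g0_0 = float(values.max() - offset0)
    if g0_0 <= 0:
        g0_0 = max(float(values.max()), 1e-12)
    half = offset0 + g0_0 / 2.0
    below = np.abs(lags)[values <= half]
    w0 = float(below.min()) if below.size else 1.0
    w0 = min(max(w0, 1e-3), w_max * 0.99)

    p0 = (g0_0, w0, offset0)
    bounds = ([0.0, 1e-6, -np.inf], [np.inf, w_max, np.inf])
    diagnostics = {"p0": p0, "bounds": bounds, "n_points": len(lags)}
    try:
        popt, _ = optimize.curve_fit(_lorentzian, lags, values, p0=p0,
                                     bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Lorentzian fit failed: {exc}", diagnostics) from exc
    g0, w, offset = (float(v) for v in popt)
    if w <= 0 or not np.isfinite(w):
        raise FitError("non-positive fitted half-width", diagnostics)
    return LorentzianParams(g0=g0, w_pix=w, offset=offset)


def count_lds(params: LorentzianParams, n_pix: int, mask: HyphaMask,
              pixel_size_um: float) -> QuantResult:
    """Droplet number from the fitted G-curve amplitude and width.

    N_LD = N_pix² / (r²·π·G(0)) with r = w (pixels); density normalizes by
    the hypha area; mean diameter is FWHM converted to µm.
    """
    if params.g0 <= 0:
        raise ValueError("fitted G(0) must be positive to count droplets")
    if params.r_pix <= 0:
        raise ValueError("fitted radius must be positive")
    n_ld = n_pix ** 2 / (params.r_pix ** 2 * np.pi * params.g0)
    return QuantResult(
        n_ld=float(n_ld),
        density_per_um2=float(n_ld / mask.area_um2),
        mean_diameter_um=float(params.fwhm_pix * pixel_size_um),
        method="ICS",
    )


def quantify(image: Image2D, mask: HyphaMask, mode: str = "horizontal",
             exclude_zero_lag: bool = True,
             pow2_mode: str = "crop_center") -> tuple[QuantResult,
                                                      LorentzianParams, GCurve]:
    """Full ICS chain: 2ⁿ square → autocorrelate → G curve → fit → count."""
    square = to_pow2_square(image, mode=pow2_mode)
    surface = autocorrelate(square)
    curve = extract_g_curve(surface, mode=mode)
    params = fit_lorentzian(curve, exclude_zero_lag=exclude_zero_lag)
    result = count_lds(params, surface.n_pix, mask, image.pixel_size_um)
    return result, params, curve
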