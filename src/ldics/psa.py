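"""Particle Size Analysis: threshold → connected components → size metrics.

The threshold-based counterpart to ICS.  The image is binarized, 8-connected
components are labeled, components outside an area window are discarded, and
each surviving particle gets an area, equivalent-circle diameter, centroid
and circularity.  Touching droplets are not split (no watershed), a known
bias at high density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, measure

from .ics import QuantResult
from .images import Image2D

__all__ = [
    "ThresholdResult",
    "ParticleRecord",
    "ParticleTable",
    "threshold_mask",
    "analyze_particles",
    "summarize_psa",
    "compare_methods",
]


@dataclass
class ThresholdResult:
    """Binary mask plus the threshold that produced it (provenance)."""

    mask: np.ndarray
    threshold: float
    method: str


@dataclass
class ParticleRecord:
    label: int
    area_um2: float
    equivalent_diameter_um: float
    centroid_xy_pix: tuple[float, float]
    circularity: float


@dataclass
class ParticleTable:
    particles: list[ParticleRecord] = field(default_factory=list)
    hypha_area_um2: float | None = None
    threshold: float | None = None

    def __len__(self) -> int:
        return len(self.particles)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "label": p.label,
                "area_um2": p.area_um2,
                "equivalent_diameter_um": p.equivalent_diameter_um,
                "centroid_x_pix": p.centroid_xy_pix[0],
                "centroid_y_pix": p.centroid_xy_pix[1],
                "circularity": p.circularity,
            } for p in self.particles]
        )


def threshold_mask(image: Image2D, method: str = "otsu",
                   value: float | None = None) -> ThresholdResult:
    """Binarize the image: true where intensity ≥ threshold.

    ``method`` is ``"otsu"``, ``"fixed"`` (threshold ``value``) or
    ``"percentile"`` (``value``-th intensity percentile).  The realized
    threshold is recorded in the result for provenance.
    """
    pixels = image.pixels
    if method == "otsu":
        if np.ptp(pixels) == 0:
            raise ValueError("constant image: Otsu threshold undefined")
        t = float(filters.threshold_otsu(pixels))
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding needs a value")
        t = float(value)
    elif method == "percentile":
        if value is None:
            raise ValueError("percentile thresholding needs a value")
        t = float(np.percentile(pixels, value))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return ThresholdResult(mask=pixels >= t, threshold=t, method=method)


def analyze_particles(mask: np.ndarray, pixel_size_um: float,
                      min_area_um2: float = 0.02,
                      max_area_um2: float = np.inf,
                      hypha_area_um2: float | None = None) -> ParticleTable:
    """8-connected component labeling with an area filter.

    Per particle: area (µm²), equivalent-circle diameter 2·√(area/π),
    centroid (x, y) in pixels, circularity 4π·area/perimeter² (defined as 1
    for components too small to have a measurable perimeter).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if not 0 <= min_area_um2 < max_area_um2:
        raise ValueError("need 0 ≤ min_area_um2 < max_area_um2")
    labeled = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    px_area = pixel_size_um ** 2
    records = []
    for region in measure.regionprops(labeled):
        area = region.area * px_area
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        perim = region.perimeter
        # clamped at 1: rasterized perimeters of few-pixel blobs undershoot
        circ = min(4.0 * np.pi * region.area / perim ** 2, 1.0) \
            if perim > 0 else 1.0
        cy, cx = region.centroid
        records.append(ParticleRecord(
            label=len(records) + 1,
            area_um2=float(area),
            equivalent_diameter_um=float(2.0 * np.sqrt(area / np.pi)),
            centroid_xy_pix=(float(cx), float(cy)),
            circularity=float(circ),
        ))
    return ParticleTable(particles=records, hypha_area_um2=hypha_area_um2)


def summarize_psa(table: ParticleTable) -> QuantResult:
    """Count, area density and mean equivalent diameter of the table.

    An empty table yields count 0 and NaN mean diameter (flagged missing).
    """
    if table.hypha_area_um2 is None or table.hypha_area_um2 <= 0:
        raise ValueError("ParticleTable needs a positive hypha_area_um2")
    n = len(table)
    diam = (float(np.mean([p.equivalent_diameter_um for p in table.particles]))
            if n else float("nan"))
    return QuantResult(
        n_ld=float(n),
        density_per_um2=n / table.hypha_area_um2,
        mean_diameter_um=diam,
        method="PSA",
    )


def compare_methods(pairs: list[tuple[QuantResult, QuantResult]]
                    ) -> tuple[float, float, float]:
    """OLS of ICS counts against PSA counts: (slope, intercept, R²)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 (ICS, PSA) pairs")
    ics_counts = np.array([p[0].n_ld for p in pairs])
    psa_counts = np.array([p[1].n_ld for p in pairs])
    if np.ptp(psa_counts) == 0:
        raise ValueError("PSA counts have zero variance; regression undefined")
    fit = stats.linregress(psa_counts, ics_counts)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)
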