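"""Plot-level structural traits.

From the per-stem detections and diameter measurements of a microplot this
module derives:

* stem density (stems/m²) = count / sampled ground area;
* the diameter distribution, fitted by maximum likelihood to both a
  two-parameter gamma law (shape k, scale θ; mean = k·θ) and a normal law,
  with a like-for-like goodness-of-fit p-value for each (one-sample
  Kolmogorov–Smirnov against the fitted law) and the better-fitting family
  selected;
* basal area (m² of stem section per m² of ground) = mean per-stem section
  area × stem density;
* biovolume (m³/m²) = basal area × plant height, a structural proxy for
  above-ground biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .diameter import StemMeasurement

__all__ = [
    "DiameterDistribution",
    "PlotTraits",
    "sampled_area",
    "stem_density",
    "fit_diameter_distribution",
    "gamma_mean",
    "basal_area",
    "basal_area_from_diameters",
    "biovolume",
    "plot_traits",
]


@dataclass(frozen=True)
class DiameterDistribution:
    family: str  # "gamma" | "normal"
    shape: float | None  # gamma shape k
    scale: float | None  # gamma scale theta
    mu: float | None  # normal mean
    sigma: float | None  # normal sd
    p_value: float
    n: int

    @property
    def mean(self) -> float:
        if self.family == "gamma":
            return gamma_mean(self.shape, self.scale)
        return self.mu


@dataclass(frozen=True)
class PlotTraits:
    plot_id: str
    n_stems: int
    sampled_area_m2: float
    stem_density: float  # stems/m²
    mean_diameter_mm: float | None
    distribution: DiameterDistribution | None
    basal_area: float | None  # m²/m²
    height_m: float | None
    biovolume: float | None  # m³/m²


def sampled_area(n_samples: int, rows_per_sample: int, row_spacing: float,
                 length: float) -> float:
    """Ground area (m²) sampled by row segments.

    n_samples segments, each covering rows_per_sample rows of the given
    length (m), with rows row_spacing (m) apart. E.g. three samples of two
    rows by 1.0 m at 0.17 m spacing sample 1.02 m².
    """
    for name, v in (("n_samples", n_samples), ("rows_per_sample", rows_per_sample),
                    ("row_spacing", row_spacing), ("length", length)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return n_samples * rows_per_sample * row_spacing * length


def stem_density(count: int, area: float) -> float:
    """Stems per m² of ground."""
    if area <= 0:
        raise ValueError(f"sampled area must be > 0, got {area}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count / area


def gamma_mean(shape: float, scale: float) -> float:
    """Mean of a gamma law: shape × scale."""
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be > 0")
    return shape * scale


def fit_diameter_distribution(diameters) -> tuple[DiameterDistribution,
                                                  DiameterDistribution,
                                                  DiameterDistribution]:
    """Fit gamma and normal laws to per-stem diameters; select by p-value.

    Both families are fitted by maximum likelihood (gamma with location fixed
    at zero, as diameters are strictly positive) and tested with a one-sample
    Kolmogorov–Smirnov statistic against the fitted law. The same procedure
    is applied to both families so the p-value comparison is like-for-like;
    the known optimism of KS with estimated parameters cancels in the
    comparison. Returns (gamma_fit, normal_fit, selected).
    """
    d = np.asarray(diameters, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 10:
        raise ValueError(f"need at least 10 finite diameters, got {n}")
    if np.any(d <= 0):
        raise ValueError("non-positive diameter: gamma fit undefined")
    if np.ptp(d) == 0:
        raise ValueError("constant diameters: degenerate fit")
    shape, _, scale = sps.gamma.fit(d, floc=0.0)
    p_gamma = sps.kstest(d, "gamma", args=(shape, 0.0, scale)).pvalue
    mu, sigma = sps.norm.fit(d)
    p_normal = sps.kstest(d, "norm", args=(mu, sigma)).pvalue
    gfit = DiameterDistribution("gamma", shape, scale, None, None, float(p_gamma), n)
    nfit = DiameterDistribution("normal", None, None, mu, sigma, float(p_normal), n)
    selected = gfit if p_gamma >= p_normal else nfit
    return gfit, nfit, selected


def basal_area_from_diameters(diameters_mm, density: float) -> float:
    """Basal area (m²/m²) from per-stem diameters in mm and density (stems/m²)."""
    d = np.asarray(diameters_mm, dtype=float) / 1000.0  # m
    if d.size == 0:
        raise ValueError("no valid stem measurements for basal area")
    if density < 0:
        raise ValueError("density must be >= 0")
    return float(np.mean(math.pi * (d / 2.0) ** 2) * density)


def basal_area(measurements, density: float) -> float:
    """Mean per-stem section area times stem density.

    The mean of the per-stem areas is used, not the area of the mean
    diameter (by Jensen they differ whenever diameters vary).
    """
    d = [m.diameter_mm for m in measurements if m.valid]
    if not d:
        raise ValueError("no valid stem measurements for basal area")
    return basal_area_from_diameters(d, density)


def biovolume(basal: float, height: float) -> float:
    """Basal area (m²/m²) times plant height (m) -> m³/m²."""
    if basal < 0 or height < 0:
        raise ValueError("basal area and height must be >= 0")
    return basal * height


def plot_traits(
    plot_id: str,
    measurements: list[StemMeasurement],
    area_m2: float,
    height_m: float | None = None,
    fit_distribution: bool = True,
) -> PlotTraits:
    """Assemble the trait set of one microplot from its stem measurements.

    The stem count includes every accepted detection; diameter statistics use
    only the valid measurements. The distribution fit is skipped when fewer
    than 10 valid diameters are available.
    """
    n = len(measurements)
    density = stem_density(n, area_m2)
    diam = [m.diameter_mm for m in measurements if m.valid]
    mean_d = float(np.mean(diam)) if diam else None
    dist = None
    if fit_distribution and len(diam) >= 10:
        try:
            _, _, dist = fit_diameter_distribution(diam)
        except ValueError:
            dist = None
    basal = basal_area_from_diameters(diam, density) if diam else None
    biovol = None
    if basal is not None and height_m is not None:
        biovol = biovolume(basal, height_m)
    return PlotTraits(
        plot_id=plot_id,
        n_stems=n,
        sampled_area_m2=area_m2,
        stem_density=density,
        mean_diameter_mm=mean_d,
        distribution=dist,
        basal_area=basal,
        height_m=height_m,
        biovolume=biovol,
    )
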