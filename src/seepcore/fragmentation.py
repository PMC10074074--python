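"""Fragmentation and degradation indicators of buried microplastics.

The central indicator is R_N/M, the ratio of number abundance (items kg⁻¹)
to mass abundance (mg kg⁻¹): splitting particles at constant total mass
raises the count but not the mass, so R_N/M rises as a polymer fragments.
Complementary per-particle metrics — small-size fraction, the granule
("particle") to fragment/film/fiber morphology ratio, mean projected area
and the colored/colorless abundance correlation — require the optional
per-particle table and degrade gracefully to missing when it is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DomainError, MORPHOLOGIES

__all__ = [
    "rnm_ratio",
    "size_fraction",
    "morphology_ratio",
    "united_projected_area",
    "color_profile_correlation",
    "fragmentation_profile",
    "ProjectedArea",
    "ColorCorrelation",
]

SIZE_THRESHOLDS_UM = (50.0, 250.0)


def rnm_ratio(number_abundance: float, mass_abundance: float) -> float:
    """R_N/M = number / mass abundance, items mg⁻¹.

    0/0 and count/0 are not computable and return NaN (the latter warrants a
    flag upstream); higher values mean more, smaller particles per unit mass.
    """
    n = np.asarray(number_abundance, dtype=float)
    m = np.asarray(mass_abundance, dtype=float)
    if np.any(n < 0) or np.any(m < 0):
        raise DomainError("abundances must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(m > 0, n / np.where(m > 0, m, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def size_fraction(particles: pd.DataFrame, threshold_um: float) -> float:
    """Fraction of particles with max dimension below ``threshold_um``."""
    if len(particles) == 0:
        return math.nan
    d = particles["max_dimension_um"].to_numpy(dtype=float)
    return float((d < threshold_um).mean())


def morphology_ratio(particles: pd.DataFrame) -> float:
    """count(particle) / count(fragment ∪ film ∪ fiber); NaN if no non-particles."""
    if len(particles) == 0:
        return math.nan
    morph = particles["morphology"]
    bad = set(morph) - set(MORPHOLOGIES)
    if bad:
        raise DomainError(f"unknown morphologies: {sorted(bad)}")
    n_particle = int((morph == "particle").sum())
    n_other = len(morph) - n_particle
    if n_other == 0:
        return math.nan
    return n_particle / n_other


@dataclass(frozen=True)
class ProjectedArea:
    mean_um2: float                   # mean projected area per particle
    areal_load_mm2_kg: float | None   # mean area × number abundance
    n_imputed: int
    n_total: int


def united_projected_area(
    particles: pd.DataFrame,
    number_abundance: float | None = None,
    shape_factor: float = 0.5,
    impute: bool = True,
    min_coverage: float = 0.8,
) -> ProjectedArea | None:
    """Mean projected area (µm²) and, given a number abundance, the united
    areal load (mm² kg⁻¹ = mean µm² × items kg⁻¹ × 10⁻⁶).

    Records without a measured area are imputed as π·(d/2)²·shape_factor
    (circumscribed circle scaled by a compactness factor) and counted;
    imputation below ``min_coverage`` measured-area coverage is refused
    unless ``impute`` is enabled.
    """
    if len(particles) == 0:
        return None
    area = particles["projected_area_um2"].to_numpy(dtype=float)
    have = np.isfinite(area)
    coverage = have.mean()
    if not have.any() and not impute:
        return None
    if coverage < min_coverage and not impute:
        return None
    if impute and not have.all():
        d = particles["max_dimension_um"].to_numpy(dtype=float)
        area = np.where(have, area, math.pi * (d / 2.0) ** 2 * shape_factor)
    else:
        area = area[have]
    mean = float(np.mean(area))
    load = None
    if number_abundance is not None:
        load = mean * float(number_abundance) * 1e-6
    return ProjectedArea(
        mean_um2=mean,
        areal_load_mm2_kg=load,
        n_imputed=int((~have).sum()) if impute else 0,
        n_total=len(particles),
    )


@dataclass(frozen=True)
class ColorCorrelation:
    r: float
    p_value: float
    method: str
    n_layers: int
    n_permutations: int


def color_profile_correlation(
    colored,
    colorless,
    method: str = "pearson",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ColorCorrelation:
    """Correlation of colored vs colorless depth profiles with a permutation p.

    The p-value is the two-sided tail fraction of |r| over seeded
    permutations of the layer labels (with the +1 small-sample correction),
    avoiding distributional assumptions on abundances.
    """
    x = np.asarray(colored, dtype=float)
    y = np.asarray(colorless, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("profiles must be 1-D and equally long")
    if x.size < 5:
        raise DomainError("need >= 5 layers for the profile correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance in a profile: correlation undefined")
    stat = _corr(x, y, method)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        if abs(_corr(x, perm, method)) >= abs(stat) - 1e-15:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return ColorCorrelation(float(stat), float(p), method, x.size, n_permutations)


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise DomainError(f"unknown correlation method {method!r}")


def fragmentation_profile(
    inventory: pd.DataFrame,
    particles: pd.DataFrame | None = None,
    thresholds_um=SIZE_THRESHOLDS_UM,
    shape_factor: float = 0.5,
) -> pd.DataFrame:
    """Per-layer fragmentation indicators for one site.

    Metrics needing the per-particle table are NaN when it is missing.
    """
    agg = (
        inventory.groupby(["site_id", "layer_index"], as_index=False)[
            ["number_items_kg", "mass_mg_kg"]
        ].sum()
    )
    agg["rnm_items_mg"] = rnm_ratio(
        agg["number_items_kg"].to_numpy(), agg["mass_mg_kg"].to_numpy()
    )
    for t in thresholds_um:
        agg[f"frac_below_{int(t)}_um"] = np.nan
    agg["particle_to_other_ratio"] = np.nan
    agg["mean_projected_area_um2"] = np.nan
    agg["united_area_mm2_kg"] = np.nan
    if particles is not None and len(particles):
        for i, row in agg.iterrows():
            sub = particles[
                (particles["site_id"] == row["site_id"])
                & (particles["layer_index"] == row["layer_index"])
            ]
            if len(sub) == 0:
                continue
            for t in thresholds_um:
                agg.loc[i, f"frac_below_{int(t)}_um"] = size_fraction(sub, t)
            agg.loc[i, "particle_to_other_ratio"] = morphology_ratio(sub)
            pa = united_projected_area(
                sub, number_abundance=row["number_items_kg"],
                shape_factor=shape_factor,
            )
            if pa is not None:
                agg.loc[i, "mean_projected_area_um2"] = pa.mean_um2
                agg.loc[i, "united_area_mm2_kg"] = pa.areal_load_mm2_kg
    return agg
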