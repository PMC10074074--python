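"""Microplastic environmental risk indices: PLI, PHI, PRI and NPI.

Four complementary indices score a set of sampling points (here: the layers
of a core, or whole sites):

* **PLI** — pollution load index.  Contamination factor CF_i = C_i/C₀
  against the background C₀ (lowest detected abundance); per-point
  PLI_i = √CF_i and regional PLI_r the geometric mean of the PLI_i.
* **PHI** — polymer hazard index, the composition-weighted sum Σ P_n·S_n of
  monomer-toxicity hazard scores S_n.
* **PRI** — potential ecological risk index Σ P_n·C_f·S_n, combining
  composition, enrichment C_f = C_i/C₀ and hazard.
* **NPI** — Nemerow pollution index √((P̄² + P_max²)/2) of the normalised
  ratios P_i = C_i/C_s against fixed reference abundances
  (373 items kg⁻¹, 3465 mg kg⁻¹).

Each index carries a published multi-level classification; interval
conventions (documented per classifier) are left-closed except NPI, whose
published "≤ 0.7 → level I" forces left-open/right-closed interior bands.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DomainError, POLYMERS

__all__ = [
    "HazardTable",
    "DEFAULT_HAZARD_SCORES",
    "contamination_factor",
    "pli",
    "phi",
    "pri",
    "npi",
    "npi_from_inventory",
    "composition_from_inventory",
    "risk_report",
    "classify_pli",
    "classify_phi",
    "classify_pri",
    "classify_npi",
    "RiskReport",
    "NPI_REFERENCE_NUMBER",
    "NPI_REFERENCE_MASS",
]

#: Published polymer hazard scores (monomer-hazard weighting).  PTFE is in
#: the detection vocabulary but has no published score; the strict policy
#: refuses to score compositions containing it.
DEFAULT_HAZARD_SCORES: dict[str, float] = {
    "PU": 1094, "PA": 50, "PET": 4, "POM": 871, "PC": 1177, "PE": 11,
    "PP": 1, "PS": 30, "PBD": 6552, "PVC": 10001, "PSF": 1, "PMMA": 1021,
    "AC": 10599, "SI": 2, "FKM": 2, "PF": 750,
}

#: NPI reference abundances C_s.
NPI_REFERENCE_NUMBER = 373.0     # items kg⁻¹
NPI_REFERENCE_MASS = 3465.0      # mg kg⁻¹

COMPOSITION_TOL = 1e-6


class HazardTable:
    """Polymer → hazard score mapping with an unscored-polymer policy.

    policy:
      * ``"strict"``  — unscored polymer raises, naming the polymer;
      * ``"default"`` — unscored polymers get ``default_score``;
      * ``"exclude"`` — unscored polymers are dropped and the remaining
        composition renormalised.
    """

    def __init__(
        self,
        scores: dict[str, float] | None = None,
        policy: str = "strict",
        default_score: float = 0.0,
    ):
        self.scores = dict(DEFAULT_HAZARD_SCORES if scores is None else scores)
        if any(s < 0 for s in self.scores.values()):
            raise DomainError("hazard scores must be >= 0")
        if policy not in ("strict", "default", "exclude"):
            raise DomainError(f"unknown hazard policy {policy!r}")
        self.policy = policy
        self.default_score = default_score

    def __contains__(self, polymer: str) -> bool:
        return polymer in self.scores

    def score(self, polymer: str) -> float:
        if polymer in self.scores:
            return self.scores[polymer]
        if self.policy == "default":
            return self.default_score
        raise DomainError(
            f"polymer {polymer!r} has no hazard score (strict policy)"
        )

    def resolve_composition(self, composition: dict[str, float]) -> dict[str, float]:
        """Apply the policy; returns a composition summing to 1."""
        comp = {p: float(v) for p, v in composition.items()}
        if any(v < 0 for v in comp.values()):
            raise DomainError("proportions must be >= 0")
        if abs(sum(comp.values()) - 1.0) > COMPOSITION_TOL:
            raise DomainError(
                f"proportions must sum to 1 (got {sum(comp.values()):.8f})"
            )
        if self.policy == "exclude":
            comp = {p: v for p, v in comp.items() if p in self.scores}
            s = sum(comp.values())
            if s <= 0:
                raise DomainError("no scored polymers left after exclusion")
            comp = {p: v / s for p, v in comp.items()}
        else:
            for p in comp:
                self.score(p)     # strict policy raises here
        return comp

    def digest(self) -> str:
        """Stable hash of (scores, policy) for provenance echoing."""
        items = sorted(self.scores.items())
        payload = repr((items, self.policy, self.default_score)).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Elementary indices

def contamination_factor(c_i, c_0: float):
    """CF = C_i / C₀ against the background abundance C₀ (> 0)."""
    if not c_0 > 0:
        raise DomainError("background concentration C0 must be > 0")
    c = np.asarray(c_i, dtype=float)
    if np.any(c < 0):
        raise DomainError("abundance must be >= 0")
    out = c / c_0
    return float(out) if out.ndim == 0 else out


def classify_pli(pli_r: float) -> str:
    """<10 low, [10,20) medium, [20,30) high, >=30 extremely high."""
    if pli_r < 0:
        raise DomainError("PLI must be >= 0")
    if pli_r < 10:
        return "low"
    if pli_r < 20:
        return "medium"
    if pli_r < 30:
        return "high"
    return "extremely high"


def pli(cf_values, mode: str = "sqrt") -> tuple[np.ndarray, float, str]:
    """Per-point PLI_i and regional PLI_r (geometric mean) with category.

    ``mode="sqrt"`` (default) uses PLI_i = √CF_i, the standard MP pollution
    load form; ``mode="literal"`` uses PLI_i = CF_i.
    """
    cf = np.asarray(cf_values, dtype=float)
    if cf.size == 0:
        raise DomainError("need at least one contamination factor")
    if np.any(cf <= 0):
        raise DomainError("all CF must be > 0 for the geometric aggregation")
    if mode == "sqrt":
        pli_i = np.sqrt(cf)
    elif mode == "literal":
        pli_i = cf.copy()
    else:
        raise DomainError(f"unknown PLI mode {mode!r}")
    pli_r = float(np.exp(np.mean(np.log(pli_i))))
    return pli_i, pli_r, classify_pli(pli_r)


def classify_phi(value: float) -> str:
    """[0,1) I, [1,10) II, [10,100) III, [100,1000) IV, >=1000 V."""
    if value < 0:
        raise DomainError("PHI must be >= 0")
    for hi, level in ((1, "I"), (10, "II"), (100, "III"), (1000, "IV")):
        if value < hi:
            return level
    return "V"


def phi(composition: dict[str, float], hazard: HazardTable | None = None) -> tuple[float, str]:
    """Polymer hazard index PHI = Σ P_n·S_n with its level."""
    hazard = hazard or HazardTable()
    comp = hazard.resolve_composition(composition)
    value = float(sum(p * hazard.score(poly) for poly, p in comp.items()))
    return value, classify_phi(value)


def classify_pri(value: float) -> str:
    """[0,150) I, [150,300) II, [300,600) III, [600,1200) IV, >=1200 V."""
    if value < 0:
        raise DomainError("PRI must be >= 0")
    for hi, level in ((150, "I"), (300, "II"), (600, "III"), (1200, "IV")):
        if value < hi:
            return level
    return "V"


def pri(
    composition: dict[str, float],
    cf,
    hazard: HazardTable | None = None,
) -> tuple[float, str]:
    """Potential ecological risk index PRI = Σ P_n·C_f·S_n with its level.

    ``cf`` is the dimensionless enrichment C_f = C_i/C₀ of the sampling
    point (scalar), or a per-polymer mapping.
    """
    hazard = hazard or HazardTable()
    comp = hazard.resolve_composition(composition)
    if isinstance(cf, dict):
        get_cf = lambda p: float(cf[p])
    else:
        cf = float(cf)
        if cf < 0:
            raise DomainError("enrichment coefficient must be >= 0")
        get_cf = lambda p: cf
    value = float(
        sum(pn * get_cf(poly) * hazard.score(poly) for poly, pn in comp.items())
    )
    return value, classify_pri(value)


def classify_npi(value: float) -> str:
    """[0,0.7] I, (0.7,1.0] II, (1.0,2.0] III, (2.0,3.0] IV, >3.0 V.

    Interior bands are left-open/right-closed because the published scheme
    assigns "≤ 0.7" to level I.
    """
    if value < 0:
        raise DomainError("NPI must be >= 0")
    for hi, level in ((0.7, "I"), (1.0, "II"), (2.0, "III"), (3.0, "IV")):
        if value <= hi:
            return level
    return "V"


def npi(p_values) -> tuple[float, str]:
    """Nemerow pollution index NPI = √((P̄² + P_max²)/2) with its level."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DomainError("need at least one pollution ratio")
    if np.any(p < 0):
        raise DomainError("pollution ratios must be >= 0")
    value = float(math.sqrt((p.mean() ** 2 + p.max() ** 2) / 2.0))
    return value, classify_npi(value)


# ---------------------------------------------------------------------------
# Inventory-level conveniences

def _site_layer_totals(inventory: pd.DataFrame, basis: str) -> pd.DataFrame:
    col = {"number": "number_items_kg", "mass": "mass_mg_kg"}.get(basis)
    if col is None:
        raise DomainError("basis must be 'number' or 'mass'")
    return (
        inventory.groupby(["site_id", "layer_index"], as_index=False)[col]
        .sum()
        .rename(columns={col: "abundance"})
    )


def npi_from_inventory(
    inventory: pd.DataFrame,
    basis: str = "number",
    reference: float | None = None,
) -> tuple[float, str]:
    """NPI over the layers of one site's inventory, P_i = C_i/C_s."""
    if reference is None:
        reference = NPI_REFERENCE_NUMBER if basis == "number" else NPI_REFERENCE_MASS
    if not reference > 0:
        raise DomainError("reference abundance C_s must be > 0")
    totals = _site_layer_totals(inventory, basis)
    if len(totals) == 0:
        raise DomainError("empty inventory")
    return npi(totals["abundance"].to_numpy() / reference)


def composition_from_inventory(
    inventory: pd.DataFrame, basis: str = "number"
) -> dict[str, float]:
    """Polymer proportions P_n over an inventory (number basis by default)."""
    col = {"number": "number_items_kg", "mass": "mass_mg_kg"}[basis]
    sums = inventory.groupby("polymer")[col].sum()
    total = sums.sum()
    if not total > 0:
        raise DomainError("inventory has zero total abundance")
    return {p: float(v / total) for p, v in sums.items() if v > 0}


# ---------------------------------------------------------------------------
# Full report

@dataclass
class RiskReport:
    per_site: pd.DataFrame                  # one row per site with all indices
    normalized: pd.DataFrame | None         # min-max over sites, [0, 1]
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(
            per_site=self.per_site.to_dict(orient="records"),
            normalized=None if self.normalized is None
            else self.normalized.to_dict(orient="records"),
            parameters=self.parameters,
        )


def risk_report(
    inventories: dict[str, pd.DataFrame],
    hazard: HazardTable | None = None,
    c0: float | None = None,
    basis: str = "number",
    cs_number: float = NPI_REFERENCE_NUMBER,
    cs_mass: float = NPI_REFERENCE_MASS,
    pli_mode: str = "sqrt",
) -> RiskReport:
    """Assemble PLI, PHI, PRI, NPI-N and NPI-M per site.

    Layers act as the sampling points within a site.  The background C₀
    defaults to the lowest positive layer abundance across all sites (the
    lowest-detected-abundance rule); indicator columns are min-max
    normalised across sites for the radar summary, skipped with a warning
    when degenerate (single site or zero range).
    """
    hazard = hazard or HazardTable()
    if not inventories:
        raise DomainError("need at least one site")

    all_totals = pd.concat(
        [_site_layer_totals(inv, basis) for inv in inventories.values()],
        ignore_index=True,
    )
    positive = all_totals.loc[all_totals["abundance"] > 0, "abundance"]
    if c0 is None:
        if positive.empty:
            raise DomainError("no positive abundances to set the background C0")
        c0 = float(positive.min())

    rows = []
    for site, inv in inventories.items():
        totals = _site_layer_totals(inv, basis)
        cf = contamination_factor(totals["abundance"].to_numpy(), c0)
        _, pli_r, pli_level = pli(np.maximum(cf, 1e-12), mode=pli_mode)
        comp = composition_from_inventory(inv, basis=basis)
        phi_v, phi_level = phi(comp, hazard)
        site_cf = contamination_factor(float(totals["abundance"].mean()), c0)
        pri_v, pri_level = pri(comp, site_cf, hazard)
        npi_n, npi_n_level = npi_from_inventory(inv, "number", cs_number)
        npi_m, npi_m_level = npi_from_inventory(inv, "mass", cs_mass)
        rows.append(dict(
            site_id=site,
            pli_r=pli_r, pli_level=pli_level,
            phi=phi_v, phi_level=phi_level,
            pri=pri_v, pri_level=pri_level,
            npi_n=npi_n, npi_n_level=npi_n_level,
            npi_m=npi_m, npi_m_level=npi_m_level,
        ))
    per_site = pd.DataFrame(rows)

    indicator_cols = ["pli_r", "phi", "pri", "npi_n", "npi_m"]
    normalized = None
    if len(per_site) < 2:
        warnings.warn("single site: cross-site normalization skipped")
    else:
        spans = per_site[indicator_cols].max() - per_site[indicator_cols].min()
        if (spans <= 0).all():
            warnings.warn("all indicators degenerate: normalization skipped")
        else:
            normalized = per_site[["site_id"]].copy()
            for c in indicator_cols:
                if spans[c] > 0:
                    lo = per_site[c].min()
                    normalized[c] = (per_site[c] - lo) / spans[c]
                else:
                    warnings.warn(
                        f"zero range in indicator {c!r}: left unnormalized (NaN)"
                    )
                    normalized[c] = np.nan

    params = dict(
        c0=c0, basis=basis, cs_number=cs_number, cs_mass=cs_mass,
        pli_mode=pli_mode, hazard_policy=hazard.policy,
        hazard_table_digest=hazard.digest(),
    )
    return RiskReport(per_site=per_site, normalized=normalized, parameters=params)
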