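"""Domain types, unit conventions and validation shared by every pipeline stage.

Conventions
-----------
* Depths are cm below the sediment-water interface; a layer occupies the
  half-open interval ``[top_depth, bottom_depth)`` and its midpoint is used
  wherever a single depth is needed.
* Dry bulk density is g cm⁻³, radionuclide activities Bq kg⁻¹ dry sediment.
* Microplastic number abundance is items kg⁻¹ dry, mass abundance mg kg⁻¹ dry.
* Mass accumulation rates (MAR) are g cm⁻² yr⁻¹; 1 g cm⁻² yr⁻¹ = 10 kg m⁻² yr⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: ²¹⁰Pb half-life in years and the corresponding decay constant (yr⁻¹).
PB210_HALF_LIFE_YR = 22.3
LAMBDA_PB210 = math.log(2.0) / PB210_HALF_LIFE_YR

#: Unit conversion: 1 g cm⁻² yr⁻¹ expressed in kg m⁻² yr⁻¹.
G_CM2_TO_KG_M2 = 10.0

#: Detection window of the particle-sizing workflow, µm.
SIZE_WINDOW_UM = (20.0, 5000.0)

#: Closed polymer vocabulary (17 codes).
POLYMERS = (
    "PU", "PA", "PET", "POM", "PC", "PE", "PP", "PS", "PBD",
    "PTFE", "PVC", "PSF", "PMMA", "AC", "SI", "FKM", "PF",
)

#: Closed morphology vocabulary. "particle" is the granule/sphere class,
#: distinct from fragment, film and fiber.
MORPHOLOGIES = ("particle", "fragment", "film", "fiber")

#: Habitat classes: middle-stage strong/weak seepage, early seepage, none.
HABITAT_CLASSES = ("strong_seepage", "weak_seepage", "early_seepage", "non_seepage")
SEEPAGE_CLASSES = ("strong_seepage", "weak_seepage", "early_seepage")


class DomainError(ValueError):
    """Raised for inputs outside an operation's domain."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_core`."""

    field: str
    layer: int | None
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"layer {self.layer}" if self.layer is not None else "core"
        return f"{where}: {self.field}: {self.rule}"


class CoreValidationError(DomainError):
    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in violations))


@dataclass(frozen=True)
class SedimentLayer:
    """Physical and radionuclide measurements for one depth slice."""

    layer_index: int
    top_depth: float              # cm below seafloor
    bottom_depth: float           # cm
    dry_bulk_density: float       # g cm⁻³
    pb210_total: float            # Bq kg⁻¹ dry
    pb210_total_err: float | None = None
    pb210_supported: float | None = None
    cs137: float | None = None    # Bq kg⁻¹ dry

    @property
    def thickness(self) -> float:
        return self.bottom_depth - self.top_depth

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top_depth + self.bottom_depth)

    @property
    def mass_thickness(self) -> float:
        """Dry mass per unit area in the slice, g cm⁻²."""
        return self.dry_bulk_density * self.thickness


@dataclass
class Core:
    """A depth-ordered stack of :class:`SedimentLayer` for one site."""

    site_id: str
    layers: list[SedimentLayer]
    habitat_class: str = "non_seepage"

    def __post_init__(self) -> None:
        if self.habitat_class not in HABITAT_CLASSES:
            raise DomainError(
                f"habitat_class {self.habitat_class!r} not in {HABITAT_CLASSES}"
            )

    def __len__(self) -> int:
        return len(self.layers)

    # -- array views -------------------------------------------------
    def _arr(self, attr: str) -> np.ndarray:
        return np.array(
            [getattr(l, attr) if getattr(l, attr) is not None else np.nan
             for l in self.layers],
            dtype=float,
        )

    @property
    def top_depths(self) -> np.ndarray:
        return self._arr("top_depth")

    @property
    def bottom_depths(self) -> np.ndarray:
        return self._arr("bottom_depth")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.top_depths + self.bottom_depths)

    @property
    def thicknesses(self) -> np.ndarray:
        return self.bottom_depths - self.top_depths

    @property
    def densities(self) -> np.ndarray:
        return self._arr("dry_bulk_density")

    @property
    def pb210_total(self) -> np.ndarray:
        return self._arr("pb210_total")

    @property
    def cs137(self) -> np.ndarray:
        return self._arr("cs137")

    @property
    def mass_depths(self) -> np.ndarray:
        """Cumulative dry mass (g cm⁻²) at the n+1 layer boundaries."""
        return np.concatenate([[0.0], np.cumsum(self.densities * self.thicknesses)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.layers:
            rows.append(
                dict(
                    site_id=self.site_id,
                    layer_index=l.layer_index,
                    top_depth_cm=l.top_depth,
                    bottom_depth_cm=l.bottom_depth,
                    dry_bulk_density_g_cm3=l.dry_bulk_density,
                    pb210_total_bq_kg=l.pb210_total,
                    pb210_err_bq_kg=l.pb210_total_err,
                    pb210_supported_bq_kg=l.pb210_supported,
                    cs137_bq_kg=l.cs137,
                )
            )
        return pd.DataFrame(rows)


def core_violations(core: Core, contiguity_tol: float = 1e-9) -> list[Violation]:
    """Collect invariant violations of a :class:`Core` without raising."""
    out: list[Violation] = []
    if len(core.layers) < 3:
        out.append(Violation("layers", None, "fewer than 3 layers (dating needs >= 3)"))
    prev_bottom = 0.0
    for i, l in enumerate(core.layers):
        if l.top_depth < 0:
            out.append(Violation("top_depth", i, "negative depth"))
        if l.bottom_depth <= l.top_depth:
            out.append(Violation("bottom_depth", i, "bottom_depth must exceed top_depth"))
        if i == 0:
            prev_bottom = l.bottom_depth
        else:
            if l.top_depth < prev_bottom - contiguity_tol:
                out.append(Violation("top_depth", i, "overlaps previous layer"))
            elif l.top_depth > prev_bottom + contiguity_tol:
                out.append(Violation("top_depth", i, "gap after previous layer"))
            prev_bottom = l.bottom_depth
        if not l.dry_bulk_density > 0:
            out.append(Violation("dry_bulk_density", i, "must be > 0"))
        for name in ("pb210_total", "pb210_supported", "cs137"):
            v = getattr(l, name)
            if v is not None and v < 0:
                out.append(Violation(name, i, "activity must be >= 0"))
    return out


def validate_core(core: Core) -> Core:
    """Return ``core`` unchanged if all invariants hold, else raise
    :class:`CoreValidationError` carrying the structured violation list."""
    v = core_violations(core)
    if v:
        raise CoreValidationError(v)
    return core


def areal_abundance(concentration: float, mass_accumulation_rate: float) -> float:
    """Flux of a per-mass concentration through the sediment surface.

    Parameters
    ----------
    concentration
        mg kg⁻¹ dry (mass basis) or items kg⁻¹ dry (number basis).
    mass_accumulation_rate
        g cm⁻² yr⁻¹.

    Returns
    -------
    float
        mg m⁻² yr⁻¹ (or items m⁻² yr⁻¹), i.e.
        ``concentration * MAR * 10`` since 1 g cm⁻² yr⁻¹ = 10 kg m⁻² yr⁻¹.
    """
    concentration = np.asarray(concentration, dtype=float)
    mar = np.asarray(mass_accumulation_rate, dtype=float)
    if np.any(concentration < 0) or np.any(mar < 0):
        raise DomainError("concentration and MAR must be >= 0")
    out = concentration * mar * G_CM2_TO_KG_M2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Tabular schemas (shared by io and synthetic modules)

INVENTORY_COLUMNS = ("site_id", "layer_index", "polymer",
                     "number_items_kg", "mass_mg_kg")
PARTICLE_COLUMNS = ("site_id", "layer_index", "polymer", "max_dimension_um",
                    "projected_area_um2", "morphology", "colored")


def validate_inventory(df: pd.DataFrame) -> pd.DataFrame:
    """Check an MP inventory table against its invariants; returns the frame."""
    missing = [c for c in INVENTORY_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"inventory missing columns: {missing}")
    bad = set(df["polymer"]) - set(POLYMERS)
    if bad:
        raise DomainError(f"unknown polymer codes: {sorted(bad)}")
    if (df["number_items_kg"] < 0).any() or (df["mass_mg_kg"] < 0).any():
        raise DomainError("abundances must be >= 0")
    dup = df.duplicated(subset=["site_id", "layer_index", "polymer"])
    if dup.any():
        raise DomainError(
            f"duplicate (site, layer, polymer) rows at index {list(df.index[dup])}"
        )
    return df


def validate_particles(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"particle table missing columns: {missing}")
    bad = set(df["polymer"]) - set(POLYMERS)
    if bad:
        raise DomainError(f"unknown polymer codes: {sorted(bad)}")
    badm = set(df["morphology"]) - set(MORPHOLOGIES)
    if badm:
        raise DomainError(f"unknown morphologies: {sorted(badm)}")
    lo, hi = SIZE_WINDOW_UM
    d = df["max_dimension_um"]
    if (d <= 0).any() or (d > hi).any():
        raise DomainError(f"max_dimension_um must lie in (0, {hi}]")
    return df
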