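"""Table readers/writers, pipeline configuration and the end-to-end report.

All tables are UTF-8 comma-delimited with a required header whose numeric
columns carry a units suffix (``_cm``, ``_bq_kg``, ``_mg_kg`` ...).  Schema
errors report the offending file, column and (where known) row.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    Core,
    DomainError,
    HABITAT_CLASSES,
    INVENTORY_COLUMNS,
    MORPHOLOGIES,
    PARTICLE_COLUMNS,
    POLYMERS,
    SedimentLayer,
    validate_core,
    validate_inventory,
    validate_particles,
)

__all__ = [
    "SchemaError",
    "read_layers",
    "read_inventory",
    "read_particles",
    "write_layers",
    "PipelineConfig",
    "run_report",
]

LAYER_COLUMNS = (
    "site_id", "layer_index", "top_depth_cm", "bottom_depth_cm",
    "dry_bulk_density_g_cm3", "pb210_total_bq_kg",
)
LAYER_OPTIONAL = ("pb210_err_bq_kg", "pb210_supported_bq_kg", "cs137_bq_kg",
                  "habitat_class")


class SchemaError(DomainError):
    """Input table violates the declared schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _opt(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def read_layers(path) -> list[Core]:
    """Read layers.csv into one :class:`Core` per site.

    Layers arriving out of depth order are stably re-sorted by top depth
    with a warning; validation failures raise with layer context.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, LAYER_COLUMNS, path)
    for col in ("top_depth_cm", "bottom_depth_cm", "dry_bulk_density_g_cm3",
                "pb210_total_bq_kg"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))][0]
            raise SchemaError(f"{path}:{bad + 2}: unparseable value in {col}")
    cores = []
    for site, g in df.groupby("site_id", sort=False):
        if not g["top_depth_cm"].is_monotonic_increasing:
            warnings.warn(f"{path}: site {site}: layers out of depth order; re-sorting")
            g = g.sort_values("top_depth_cm", kind="stable")
        habitat = "non_seepage"
        if "habitat_class" in g.columns and g["habitat_class"].notna().any():
            habitat = str(g["habitat_class"].dropna().iloc[0])
            if habitat not in HABITAT_CLASSES:
                raise SchemaError(
                    f"{path}: site {site}: habitat_class {habitat!r} "
                    f"not in {HABITAT_CLASSES}"
                )
        layers = [
            SedimentLayer(
                layer_index=int(r.layer_index),
                top_depth=float(r.top_depth_cm),
                bottom_depth=float(r.bottom_depth_cm),
                dry_bulk_density=float(r.dry_bulk_density_g_cm3),
                pb210_total=float(r.pb210_total_bq_kg),
                pb210_total_err=_opt(getattr(r, "pb210_err_bq_kg", None)),
                pb210_supported=_opt(getattr(r, "pb210_supported_bq_kg", None)),
                cs137=_opt(getattr(r, "cs137_bq_kg", None)),
            )
            for r in g.itertuples(index=False)
        ]
        cores.append(validate_core(Core(site_id=str(site), layers=layers,
                                        habitat_class=habitat)))
    return cores


def read_inventory(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, INVENTORY_COLUMNS, path)
    bad = ~df["polymer"].isin(POLYMERS)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"{path}:{row + 2}: unknown polymer code "
            f"{df.loc[df.index[bad][0], 'polymer']!r}"
        )
    return validate_inventory(df)


def read_particles(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PARTICLE_COLUMNS, path)
    badm = ~df["morphology"].isin(MORPHOLOGIES)
    if badm.any():
        row = int(df.index[badm][0])
        raise SchemaError(
            f"{path}:{row + 2}: unknown morphology "
            f"{df.loc[df.index[badm][0], 'morphology']!r}"
        )
    if df["colored"].dtype == object:
        df["colored"] = df["colored"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    return validate_particles(df)


def write_layers(cores: list[Core], path) -> None:
    frames = []
    for core in cores:
        f = core.to_frame()
        f["habitat_class"] = core.habitat_class
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run (round-trips through YAML)."""

    coring_year: float = 2021.0
    lambda_pb: float = float(np.log(2) / 22.3)
    dating_horizon_yr: float = 150.0
    cs137_peak_year: float = 1963.0
    cs137_tolerance_yr: float = 5.0
    cs137_correct: bool = False
    bin_edges: list = field(default_factory=lambda: list(range(1900, 2030, 10)))
    size_thresholds_um: list = field(default_factory=lambda: [50.0, 250.0])
    hazard_policy: str = "exclude"        # pipeline default; phi() alone is strict
    pli_mode: str = "sqrt"
    c0: float | None = None               # None → lowest detected abundance
    cs_number: float = 373.0
    cs_mass: float = 3465.0
    risk_basis: str = "number"
    seed: int = 0
    out_dir: str = "seepcore_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# End-to-end report

def run_report(
    config: PipelineConfig,
    layers_path,
    inventory_path,
    particles_path=None,
) -> dict:
    """Run dating → burial → fragmentation → risk and write all outputs.

    Writes ``agemodel.csv``, ``burial.csv``, ``frag.csv``, ``risk.json``,
    ``summary.json`` and the resolved config into ``config.out_dir``.  Any
    stage failure aborts with the stage name; outputs of completed stages
    are preserved.
    """
    from .chronology import CRSAgeModel
    from .deposition import bin_by_period, burial_series, growth_fit
    from .fragmentation import fragmentation_profile
    from .risk import HazardTable, risk_report

    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    summary: dict = {"seepcore_version": __version__, "stages": {},
                     "seed": config.seed}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e

    cores = _stage("read", lambda: read_layers(layers_path))
    inventory = _stage("read", lambda: read_inventory(inventory_path))
    particles = (
        _stage("read", lambda: read_particles(particles_path))
        if particles_path is not None else None
    )

    # dating
    def _date():
        models = {}
        frames = []
        for core in cores:
            m = CRSAgeModel(
                lambda_pb=config.lambda_pb,
                dating_horizon_yr=config.dating_horizon_yr,
            ).fit(core, config.coring_year)
            v = m.validate_cs137(
                config.cs137_peak_year, config.cs137_tolerance_yr,
                correct=config.cs137_correct,
            )
            models[core.site_id] = m
            frames.append(m.to_frame())
            summary["stages"].setdefault("date", {})[core.site_id] = dict(
                total_inventory_bq_cm2=m.total_inventory_,
                supported_bq_kg=m.supported_,
                cs137=dataclasses.asdict(v),
            )
        pd.concat(frames, ignore_index=True).to_csv(out / "agemodel.csv", index=False)
        return models

    models = _stage("date", _date)

    # burial
    def _burial():
        frames = []
        for site, m in models.items():
            inv = inventory[inventory["site_id"] == site]
            if inv.empty:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = burial_series(m, inv)
            s = s.copy()
            frames.append(s)
            edges = list(config.bin_edges) + [max(config.bin_edges) + 10]
            binned = bin_by_period(s, sorted(set(edges)))
            info = dict(
                n_dated_layers=int(len(s)),
                mean_2001_2020=_period_stats(s, 2001, 2021),
            )
            try:
                g = growth_fit(s, start_year=1950.0)
                info["growth_k_per_yr"] = g.k_hat
                info["growth_r2"] = g.r_squared
            except DomainError:
                info["growth_k_per_yr"] = None
            summary["stages"].setdefault("burial", {})[site] = info
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(out / "burial.csv", index=False)
        return frames

    _stage("burial", _burial)

    # fragmentation
    def _frag():
        prof = fragmentation_profile(
            inventory, particles, thresholds_um=config.size_thresholds_um
        )
        prof.to_csv(out / "frag.csv", index=False)
        summary["stages"]["frag"] = dict(
            n_rows=int(len(prof)),
            particles_available=particles is not None,
        )
        return prof

    _stage("frag", _frag)

    # risk
    def _risk():
        inventories = {
            site: g for site, g in inventory.groupby("site_id", sort=False)
        }
        hz = HazardTable(policy=config.hazard_policy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = risk_report(
                inventories, hazard=hz, c0=config.c0, basis=config.risk_basis,
                cs_number=config.cs_number, cs_mass=config.cs_mass,
                pli_mode=config.pli_mode,
            )
        (out / "risk.json").write_text(json.dumps(rep.to_dict(), indent=2,
                                                  default=_json_default))
        summary["stages"]["risk"] = rep.parameters
        return rep

    _stage("risk", _risk)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
    )
    return summary


def _period_stats(series: pd.DataFrame, lo: float, hi: float):
    sel = (series["age_ce"] >= lo) & (series["age_ce"] < hi)
    v = series.loc[sel, "burial_mass_mg_m2_yr"]
    if v.empty:
        return None
    return dict(mean_mg_m2_yr=float(v.mean()),
                sd_mg_m2_yr=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                n=int(len(v)))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
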