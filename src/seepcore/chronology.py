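"""Constant-rate-of-supply (CRS) excess-²¹⁰Pb age-depth modelling.

The CRS model assumes a constant atmospheric supply of unsupported ²¹⁰Pb to
the sediment surface.  With I(z) the excess-²¹⁰Pb inventory (Bq cm⁻²) below
depth z and I₀ the total inventory, the age of the boundary at z is

    t(z) = (1/λ) · ln(I₀ / I(z)),        λ = ln2 / 22.3 yr⁻¹

and the mass accumulation rate at a horizon is the CRS rate identity

    r(z) = λ · I(z) / A_ex(z)            (g cm⁻² yr⁻¹).

Slices are measured as mass-weighted averages, so inventories are summed
layerwise (piecewise-constant activity within a slice).  For the rate
identity, I within a layer is taken as the logarithmic mean of the bounding
boundary inventories — the layer average of a log-linearly interpolated
I(z) — which makes ``r`` exact on noise-free constant-rate profiles and
makes burial-flux conservation an algebraic identity downstream.

A ¹³⁷Cs fallout-peak cross-check (global maximum 1963) validates, and can
uniformly rescale, the CRS chronology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Core, DomainError, LAMBDA_PB210, validate_core

__all__ = [
    "CRSAgeModel",
    "Cs137Peak",
    "Cs137Validation",
    "PlateauNotFoundError",
    "SupportedEstimate",
    "estimate_supported",
    "excess_activity",
    "cumulative_inventory",
    "crs_ages",
    "crs_mar",
    "cs137_peak",
    "validate_chronology",
]

DEFAULT_DATING_HORIZON_YR = 150.0     # effective range of ²¹⁰Pb dating
DEFAULT_EXCESS_FLOOR = 1e-3           # Bq kg⁻¹, clip floor for A_ex <= 0


class PlateauNotFoundError(DomainError):
    """Deep ²¹⁰Pb profile still decaying: supply ``supported`` explicitly."""


@dataclass(frozen=True)
class SupportedEstimate:
    value: float                 # Bq kg⁻¹
    layer_indices: tuple[int, ...]
    bypassed: bool               # True when taken from the input table


def estimate_supported(
    core: Core,
    n_deep_layers: int = 4,
    rel_tol: float = 0.05,
    alpha: float = 0.05,
) -> SupportedEstimate:
    """Supported ²¹⁰Pb from the deep asymptote of the total-activity profile.

    If every layer carries ``pb210_supported`` the mean of those values is
    returned unchanged.  Otherwise the ``n_deep_layers`` deepest layers are
    required to form a plateau: the fitted log-linear decline across the
    window must be both practically small (< ``rel_tol`` of the mean) or
    statistically indistinguishable from flat (one-sided ``alpha``).
    """
    given = [l.pb210_supported for l in core.layers]
    if all(v is not None for v in given) and given:
        return SupportedEstimate(
            float(np.mean(given)),
            tuple(l.layer_index for l in core.layers),
            bypassed=True,
        )
    if len(core) < n_deep_layers:
        raise DomainError(
            f"core has {len(core)} layers < n_deep_layers={n_deep_layers}"
        )
    deep = core.layers[-n_deep_layers:]
    tot = np.array([l.pb210_total for l in deep], dtype=float)
    if np.any(tot <= 0):
        raise PlateauNotFoundError(
            "non-positive total activity in the deep window"
        )
    x = np.array([l.midpoint for l in deep])
    y = np.log(tot)
    res = stats.linregress(x, y)
    decline_rel = -res.slope * (x[-1] - x[0])    # fractional drop across window
    p_one_sided = res.pvalue / 2.0 if res.slope < 0 else 1.0
    plateaued = (decline_rel < rel_tol) or (p_one_sided >= alpha)
    if not plateaued:
        raise PlateauNotFoundError(
            "deep ²¹⁰Pb profile has no plateau (log-activity still declining "
            f"by {decline_rel:.1%} across the {n_deep_layers} deepest layers); "
            "supply the supported activity explicitly"
        )
    return SupportedEstimate(
        float(tot.mean()), tuple(l.layer_index for l in deep), bypassed=False
    )


def excess_activity(
    core: Core,
    supported: float,
    floor: float = DEFAULT_EXCESS_FLOOR,
    totals: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-layer A_ex = total − supported (Bq kg⁻¹).

    Values ≤ 0 are clipped to ``floor`` and flagged; clipping is the
    degenerate-input policy, not an error.  ``totals`` overrides the cores'
    measured totals (used for error-model debiasing upstream).
    """
    if supported < 0:
        raise DomainError("supported activity must be >= 0")
    tot = core.pb210_total if totals is None else np.asarray(totals, float)
    a_ex = tot - supported
    clipped = a_ex <= 0
    a_ex = np.where(clipped, floor, a_ex)
    return a_ex, clipped


def _tail_profile_fit(
    m_bounds: np.ndarray,
    a_ex_g: np.ndarray,
    dm: np.ndarray,
    usable: np.ndarray,
    errors_g: np.ndarray | None = None,
) -> tuple[float, float] | None:
    """Fit the excess point profile A(m) = A₀·e^(−βm); returns (A₀, β) in
    Bq g⁻¹ and g⁻¹ cm².

    The slice-average model A₀·(e^(−βm_top) − e^(−βm_bot))/(βΔm) is fitted
    by weighted least squares in *linear* activity space over every layer —
    including layers whose raw excess is negative.  Excluding
    near-equilibrium layers, or fitting in log space, conditions on upward
    noise fluctuations and systematically flattens the profile (β biased
    low, tail inventory high); the unconditional linear-space fit has no
    such selection bias and is exact on noise-free profiles.
    """
    from scipy.optimize import curve_fit

    idx = np.arange(len(a_ex_g))
    pos = usable & (a_ex_g > 0)
    if pos.sum() < 2:
        return None
    # starting values from a log fit on the clearly positive section
    mids = 0.5 * (m_bounds[:-1] + m_bounds[1:])
    sl, ic = np.polyfit(mids[pos], np.log(a_ex_g[pos]), 1)
    beta0 = -sl if -sl > 0 else 1e-3
    a0 = math.exp(ic)

    def model(i, a0, beta):
        i = np.asarray(i, dtype=int)
        beta = abs(beta)
        return a0 * (
            np.exp(-beta * m_bounds[i]) - np.exp(-beta * m_bounds[i + 1])
        ) / (beta * dm[i])

    sigma = None
    if errors_g is not None:
        sigma = np.where(
            np.isfinite(errors_g) & (errors_g > 0), errors_g,
            np.nanmax(errors_g[np.isfinite(errors_g)]) if np.isfinite(errors_g).any() else 1.0,
        )
    try:
        popt, _ = curve_fit(
            model, idx.astype(float), a_ex_g,
            p0=[a0, beta0], sigma=sigma, absolute_sigma=True, maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return (a0, beta0) if beta0 > 0 else None
    a0_fit, beta_fit = float(popt[0]), float(abs(popt[1]))
    if not (a0_fit > 0 and beta_fit > 0):
        return (a0, beta0) if beta0 > 0 else None
    return a0_fit, beta_fit


def cumulative_inventory(
    core: Core,
    a_ex: np.ndarray,
    tail_correction: bool = True,
    clipped: np.ndarray | None = None,
    errors: np.ndarray | None = None,
    sigma_cut: float = 2.0,
    a_ex_raw: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int]:
    """Excess-²¹⁰Pb inventory (Bq cm⁻²) at the n+1 layer boundaries.

    Layer inventory is A_ex (Bq g⁻¹) × ρ (g cm⁻³) × thickness (cm); the
    boundary inventory is the sum over all deeper layers plus, when
    ``tail_correction``, the inventory below assuming exponential
    continuation at the locally estimated decay rate.

    When per-layer activity ``errors`` (1σ, Bq kg⁻¹) are supplied, the
    profile is truncated at the equilibrium depth: the deepest layer whose
    *fitted* excess (from an unconditional exponential profile fit) still
    exceeds ``sigma_cut`` × its error.  Summing layers whose true excess is
    indistinguishable from zero only accumulates subtraction noise — and
    any rule that keeps a layer based on its own measurement selects upward
    fluctuations, which (with one-sided clipping) inflates deep inventories
    and compresses deep ages.  The fit-based rule is deterministic given
    the profile, so no such selection occurs; the inventory below the
    cutoff is carried by the exponential tail and boundaries below it are
    undatable (NaN).

    Returns ``(I_boundaries, tail, cutoff_index, fitted_excess)``; ``I[0]``
    is I₀, ``cutoff_index`` the deepest layer contributing measured excess
    and ``fitted_excess`` the per-layer slice means of the fitted profile
    (Bq kg⁻¹; None when no profile fit was possible).
    """
    n = len(core)
    dz = core.thicknesses
    if np.any(dz <= 0):
        raise DomainError("non-positive layer thickness")
    a_ex = np.asarray(a_ex, dtype=float)
    a_g = a_ex / 1000.0                      # Bq kg⁻¹ → Bq g⁻¹
    dm = core.densities * dz
    inv = a_g * dm
    clip = clipped if clipped is not None else np.zeros(n, bool)
    m_bounds = core.mass_depths

    measured_ok = (a_g > 0) & ~clip
    if not measured_ok.any():
        raise DomainError("no layer has positive excess 210Pb")

    fit = None
    if tail_correction or errors is not None:
        raw_g = a_g if a_ex_raw is None else np.asarray(a_ex_raw, float) / 1000.0
        fit = _tail_profile_fit(
            m_bounds, raw_g, dm, measured_ok,
            errors_g=None if errors is None else np.asarray(errors, float) / 1000.0,
        )

    fitted_mean = None
    if fit is not None:
        a0_fit, beta = fit
        fitted_mean = a0_fit * (
            np.exp(-beta * m_bounds[:-1]) - np.exp(-beta * m_bounds[1:])
        ) / (beta * dm) * 1000.0            # back to Bq kg⁻¹
    if errors is not None and fitted_mean is not None:
        err = np.asarray(errors, dtype=float)
        with np.errstate(invalid="ignore"):
            distinct = fitted_mean > sigma_cut * np.where(np.isfinite(err), err, 0.0)
        if not distinct.any():
            raise DomainError(
                "no layer has excess 210Pb distinguishable from zero"
            )
        cut = int(np.nonzero(distinct)[0][-1])
    else:
        cut = int(np.nonzero(measured_ok)[0][-1])

    tail = 0.0
    if tail_correction and fit is not None:
        # continuation below the cutoff boundary: ∫ A₀e^(−βm) dm = A(m)/β
        a0_fit, beta = fit
        tail = float(a0_fit * math.exp(-beta * m_bounds[cut + 1]) / beta)
    inv_eff = inv[: cut + 1]
    above = np.concatenate([np.cumsum(inv_eff[::-1])[::-1], [0.0]]) + tail
    I = np.full(n + 1, np.nan)
    I[: cut + 2] = above
    return I, tail, cut, fitted_mean


def crs_ages(
    I: np.ndarray,
    I0: float | None = None,
    lambda_pb: float = LAMBDA_PB210,
) -> np.ndarray:
    """CRS boundary ages t = (1/λ)·ln(I₀/I), yr before coring.

    ``I`` ≤ 0 yields +inf (undatable); ``I`` > I₀ is an inconsistency error.
    """
    I = np.asarray(I, dtype=float)
    if not lambda_pb > 0:
        raise DomainError("lambda must be > 0")
    if I0 is None:
        I0 = float(I[0])
    with np.errstate(invalid="ignore"):
        if np.any(I > I0 * (1.0 + 1e-9)):
            raise DomainError("inventory exceeds total inventory I0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ages = np.where(I > 0, np.log(I0 / np.maximum(np.nan_to_num(I, nan=1.0), 1e-300)) / lambda_pb, np.inf)
    return ages


def crs_mar(I, a_ex, lambda_pb: float = LAMBDA_PB210):
    """CRS rate identity r = λ·I/A_ex (g cm⁻² yr⁻¹), A_ex in Bq g⁻¹."""
    I = np.asarray(I, dtype=float)
    a = np.asarray(a_ex, dtype=float)
    if np.any(a <= 0):
        raise DomainError("A_ex must be > 0 for the rate identity")
    out = lambda_pb * I / a
    return float(out) if out.ndim == 0 else out


def _log_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Logarithmic mean, elementwise; equals a where a == b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    out = np.full(np.broadcast(a, b).shape, np.nan)
    ok = (a > 0) & (b > 0)
    close = ok & np.isclose(a, b, rtol=1e-12)
    diff = ok & ~close
    out[close] = np.broadcast_to(a, out.shape)[close]
    with np.errstate(divide="ignore", invalid="ignore"):
        out[diff] = (a - b)[diff] / (np.log(a) - np.log(b))[diff]
    return out


# ---------------------------------------------------------------------------
# ¹³⁷Cs peak

@dataclass(frozen=True)
class Cs137Peak:
    found: bool
    layer_index: int | None = None
    depth_cm: float | None = None          # midpoint of the peak layer
    refined_depth_cm: float | None = None  # log-parabolic sub-layer estimate
    activity: float | None = None

    @property
    def best_depth_cm(self) -> float | None:
        return self.refined_depth_cm if self.refined_depth_cm is not None else self.depth_cm


def cs137_peak(
    core: Core,
    detection_floor: float = 0.0,
    refine: bool = True,
    rel_window: float = 0.2,
) -> Cs137Peak:
    """Locate the ¹³⁷Cs activity maximum.

    The coarse peak is the midpoint of the maximum-activity layer, ties
    broken toward the deeper layer (main fallout precedes coring).  The
    refined depth is the vertex of a quadratic fitted to ln(activity) over
    the contiguous run of layers around the maximum whose activity exceeds
    ``rel_window`` × the peak — exact for a Gaussian pulse sampled at layer
    midpoints, and with multiplicative measurement noise (homoscedastic in
    log space) the unweighted fit is also the natural estimator.
    """
    cs = core.cs137
    valid = np.isfinite(cs) & (cs > detection_floor)
    if not valid.any():
        return Cs137Peak(found=False)
    csv = np.where(valid, cs, -np.inf)
    # deeper of tied maxima
    idx = len(csv) - 1 - int(np.argmax(csv[::-1]))
    mids = core.midpoints
    refined = None
    if refine:
        thr = cs[idx] * rel_window
        lo = idx
        while lo > 0 and np.isfinite(cs[lo - 1]) and cs[lo - 1] > thr:
            lo -= 1
        hi = idx
        while hi < len(cs) - 1 and np.isfinite(cs[hi + 1]) and cs[hi + 1] > thr:
            hi += 1
        if hi - lo < 2:
            # narrow pulse: fall back to the three layers around the maximum
            lo2, hi2 = max(idx - 1, 0), min(idx + 1, len(cs) - 1)
            if hi2 - lo2 == 2 and np.all(np.nan_to_num(cs[lo2: hi2 + 1]) > 0):
                lo, hi = lo2, hi2
        if hi - lo >= 2:
            z = mids[lo: hi + 1]
            y = np.log(cs[lo: hi + 1])
            a, b, _ = np.polyfit(z, y, 2)
            if a < 0:
                vertex = -b / (2.0 * a)
                if z[0] <= vertex <= z[-1]:
                    refined = float(vertex)
    return Cs137Peak(
        found=True,
        layer_index=core.layers[idx].layer_index,
        depth_cm=float(mids[idx]),
        refined_depth_cm=refined,
        activity=float(cs[idx]),
    )


@dataclass(frozen=True)
class Cs137Validation:
    performed: bool
    passed: bool | None = None
    discrepancy_yr: float | None = None
    crs_age_at_peak: float | None = None
    expected_age: float | None = None
    rescale_factor: float | None = None
    reason: str | None = None


# ---------------------------------------------------------------------------
# The fitted model

class CRSAgeModel:
    """CRS age-depth model for one core.

    Parameters
    ----------
    lambda_pb : float
        ²¹⁰Pb decay constant, yr⁻¹ (default ln2/22.3).
    dating_horizon_yr : float
        Ages beyond this are reported capped and flagged ``extrapolated``
        (²¹⁰Pb resolves roughly the last 100–150 yr).
    excess_floor : float
        Clip floor for non-positive excess activities, Bq kg⁻¹.
    tail_correction : bool
        Add the below-core inventory assuming exponential continuation.
    supported : float, optional
        Site-level supported ²¹⁰Pb; estimated from the deep plateau when
        absent from both this argument and the layer table.

    Attributes (after :meth:`fit`)
    ------------------------------
    supported_ : float                    Bq kg⁻¹
    excess_ : ndarray                     per-layer A_ex, Bq kg⁻¹
    excess_clipped_ : ndarray of bool
    boundary_inventory_ : ndarray         n+1 boundary inventories, Bq cm⁻²
    total_inventory_ : float              I₀, Bq cm⁻²
    boundary_ages_ : ndarray              n+1 raw CRS ages, yr before coring
    ages_ : ndarray                       per-layer midpoint ages (capped), yr
    age_ce_ : ndarray                     per-layer midpoint calendar years
    mar_ : ndarray                        per-layer MAR, g cm⁻² yr⁻¹
    extrapolated_ : ndarray of bool       beyond the dating horizon
    mar_unreliable_ : ndarray of bool     MAR from clipped excess
    cs_peak_ : Cs137Peak
    """

    def __init__(
        self,
        lambda_pb: float = LAMBDA_PB210,
        dating_horizon_yr: float = DEFAULT_DATING_HORIZON_YR,
        excess_floor: float = DEFAULT_EXCESS_FLOOR,
        tail_correction: bool = True,
        n_deep_layers: int = 4,
        supported: float | None = None,
        sigma_cut: float = 2.0,
        error_model: str = "lognormal",
    ):
        self.lambda_pb = lambda_pb
        self.dating_horizon_yr = dating_horizon_yr
        self.excess_floor = excess_floor
        self.tail_correction = tail_correction
        self.n_deep_layers = n_deep_layers
        self.supported = supported
        self.sigma_cut = sigma_cut
        if error_model not in ("lognormal", "gaussian"):
            raise DomainError("error_model must be 'lognormal' or 'gaussian'")
        self.error_model = error_model

    def fit(self, core: Core, coring_year: float = 2021.0) -> "CRSAgeModel":
        validate_core(core)
        self.core_ = core
        self.coring_year_ = float(coring_year)

        if self.supported is not None:
            self.supported_info_ = SupportedEstimate(
                float(self.supported), (), bypassed=True
            )
        else:
            self.supported_info_ = estimate_supported(core, self.n_deep_layers)
        self.supported_ = self.supported_info_.value

        errs = core._arr("pb210_total_err")
        totals = core.pb210_total
        if self.error_model == "lognormal" and np.isfinite(errs).any():
            # a lognormal measurement with median A and dispersion cv has
            # mean A·√(1+cv²); divide it out so inventories are unbiased
            cv = np.where(
                np.isfinite(errs) & (totals > 0), errs / np.maximum(totals, 1e-300), 0.0
            )
            totals = totals / np.sqrt(1.0 + cv**2)
        self.excess_, self.excess_clipped_ = excess_activity(
            core, self.supported_, self.excess_floor, totals=totals
        )
        have_errs = bool(np.isfinite(errs).any())
        (self.boundary_inventory_, self.tail_inventory_, self.cutoff_index_,
         self.fitted_excess_) = cumulative_inventory(
            core, self.excess_, self.tail_correction,
            clipped=self.excess_clipped_,
            errors=errs if have_errs else None,
            sigma_cut=self.sigma_cut,
            a_ex_raw=totals - self.supported_,
        )
        self.total_inventory_ = float(self.boundary_inventory_[0])
        self.boundary_ages_ = crs_ages(
            self.boundary_inventory_, self.total_inventory_, self.lambda_pb
        )

        with np.errstate(invalid="ignore"):
            raw_mid = 0.5 * (self.boundary_ages_[:-1] + self.boundary_ages_[1:])
        self.undatable_ = ~np.isfinite(raw_mid)
        self.extrapolated_ = self.undatable_ | (raw_mid > self.dating_horizon_yr)
        self.raw_ages_ = raw_mid
        self.ages_ = np.minimum(raw_mid, self.dating_horizon_yr)
        self.age_ce_ = self.coring_year_ - raw_mid

        I_mid = _log_mean(
            self.boundary_inventory_[:-1], self.boundary_inventory_[1:]
        )
        a_g = self.excess_ / 1000.0
        with np.errstate(invalid="ignore"):
            self.mar_ = self.lambda_pb * I_mid / a_g
        if (self.error_model == "lognormal" and have_errs
                and self.fitted_excess_ is not None):
            # mar ∝ 1/Δln(I) is convex in the layer's excess noise, giving a
            # (1 + cv²) multiplicative bias; cv taken from the fitted profile
            # (not the layer's own measurement) so the factor is deterministic
            with np.errstate(divide="ignore", invalid="ignore"):
                cv2 = (errs / self.fitted_excess_) ** 2
            cv2 = np.where(np.isfinite(cv2), cv2, 0.0)
            self.mar_ = self.mar_ / (1.0 + cv2)
        self.mar_unreliable_ = self.excess_clipped_ | ~np.isfinite(self.mar_)
        self.layer_duration_yr_ = np.diff(self.boundary_ages_)

        self.cs_peak_ = cs137_peak(core)
        self.cs_validation_: Cs137Validation | None = None
        self.age_rescale_factor_ = 1.0
        return self

    # -- ¹³⁷Cs validation --------------------------------------------
    def age_at_depth(self, depth_cm: float) -> float:
        """CRS age interpolated (linearly in depth) between boundaries."""
        self._check_fitted()
        bounds = np.concatenate(
            [[self.core_.layers[0].top_depth], self.core_.bottom_depths]
        )
        finite = np.isfinite(self.boundary_ages_)
        return float(np.interp(depth_cm, bounds[finite], self.boundary_ages_[finite]))

    def validate_cs137(
        self,
        peak_year: float = 1963.0,
        tolerance_yr: float = 5.0,
        correct: bool = False,
    ) -> Cs137Validation:
        """Compare the CRS age at the ¹³⁷Cs peak with the fallout age.

        With ``correct=True`` all CRS ages are uniformly rescaled so the
        peak depth dates exactly to ``peak_year``.
        """
        self._check_fitted()
        peak = self.cs_peak_
        if not peak.found:
            v = Cs137Validation(performed=False, reason="cs137 peak not found")
            self.cs_validation_ = v
            return v
        crs_age = self.age_at_depth(peak.best_depth_cm)
        if not np.isfinite(crs_age) or crs_age > self.dating_horizon_yr:
            v = Cs137Validation(
                performed=False, reason="cs137 peak below the dating horizon"
            )
            warnings.warn(v.reason)
            self.cs_validation_ = v
            return v
        expected = self.coring_year_ - peak_year
        disc = abs(crs_age - expected)
        factor = None
        if correct and crs_age > 0:
            factor = expected / crs_age
            self._rescale_ages(factor)
        v = Cs137Validation(
            performed=True,
            passed=bool(disc <= tolerance_yr),
            discrepancy_yr=float(disc),
            crs_age_at_peak=float(crs_age),
            expected_age=float(expected),
            rescale_factor=factor,
        )
        self.cs_validation_ = v
        return v

    def _rescale_ages(self, factor: float) -> None:
        self.age_rescale_factor_ *= factor
        self.boundary_ages_ = self.boundary_ages_ * factor
        self.raw_ages_ = self.raw_ages_ * factor
        self.ages_ = np.minimum(self.raw_ages_, self.dating_horizon_yr)
        self.age_ce_ = self.coring_year_ - self.raw_ages_
        self.extrapolated_ = self.undatable_ | (self.raw_ages_ > self.dating_horizon_yr)
        self.layer_duration_yr_ = np.diff(self.boundary_ages_)
        self.mar_ = self.mar_ / factor

    # -- export ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        self._check_fitted()
        core = self.core_
        return pd.DataFrame(
            dict(
                site_id=core.site_id,
                layer_index=[l.layer_index for l in core.layers],
                midpoint_depth_cm=core.midpoints,
                age_yr=self.raw_ages_,
                age_ce=self.age_ce_,
                mar_g_cm2_yr=self.mar_,
                layer_duration_yr=self.layer_duration_yr_,
                inventory_below_top_bq_cm2=self.boundary_inventory_[:-1],
                excess_bq_kg=self.excess_,
                excess_clipped=self.excess_clipped_,
                extrapolated=self.extrapolated_,
                mar_unreliable=self.mar_unreliable_,
            )
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "core_"):
            raise RuntimeError("CRSAgeModel is not fitted; call fit(core) first")

    def get_params(self) -> dict:
        return dict(
            lambda_pb=self.lambda_pb,
            dating_horizon_yr=self.dating_horizon_yr,
            excess_floor=self.excess_floor,
            tail_correction=self.tail_correction,
            n_deep_layers=self.n_deep_layers,
            supported=self.supported,
        )


def validate_chronology(
    model: CRSAgeModel,
    peak_year: float = 1963.0,
    coring_year: float | None = None,
    tolerance_yr: float = 5.0,
    correct: bool = False,
) -> Cs137Validation:
    """Functional wrapper over :meth:`CRSAgeModel.validate_cs137`."""
    if coring_year is not None and coring_year != model.coring_year_:
        raise DomainError("coring_year differs from the fitted model's")
    return model.validate_cs137(peak_year, tolerance_yr, correct)
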