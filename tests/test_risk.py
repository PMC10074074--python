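import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seepcore.core import DomainError
from seepcore.risk import (
    DEFAULT_HAZARD_SCORES,
    HazardTable,
    classify_npi,
    classify_phi,
    classify_pli,
    classify_pri,
    composition_from_inventory,
    contamination_factor,
    npi,
    npi_from_inventory,
    phi,
    pli,
    pri,
    risk_report,
)

# ---------------------------------------------------------------------------
# Independent naive re-implementations used as oracles


def naive_pli(cf):
    vals = [math.sqrt(c) for c in cf]
    prod = 1.0
    for v in vals:
        prod *= v
    return vals, prod ** (1.0 / len(vals))


def naive_phi(comp, scores):
    return sum(p * scores[poly] for poly, p in comp.items())


def naive_pri(comp, cf, scores):
    return sum(p * cf * scores[poly] for poly, p in comp.items())


def naive_npi(ps):
    mean = sum(ps) / len(ps)
    return math.sqrt((mean**2 + max(ps) ** 2) / 2.0)


class TestContaminationFactor:
    @pytest.mark.parametrize("ci, c0, expected", [(5, 5, 1), (20, 5, 4), (0, 5, 0)])
    def test_ratio(self, ci, c0, expected):
        assert contamination_factor(ci, c0) == expected

    def test_nonpositive_background_rejected(self):
        with pytest.raises(DomainError):
            contamination_factor(1.0, 0.0)


class TestPli:
    def test_unit_factors(self):
        pli_i, pli_r, level = pli([1.0, 1.0, 1.0])
        assert np.allclose(pli_i, 1.0) and pli_r == 1.0 and level == "low"

    def test_sqrt_form_and_geometric_mean(self):
        pli_i, pli_r, _ = pli([1.0, 16.0])
        assert np.allclose(pli_i, [1.0, 4.0])
        assert pli_r == pytest.approx(2.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        cf = rng.uniform(0.1, 50, 8)
        _, a, _ = pli(cf)
        _, b, _ = pli(rng.permutation(cf))
        assert a == pytest.approx(b)

    def test_geometric_mean_equals_exp_mean_log(self):
        cf = [0.5, 2.0, 9.0, 100.0]
        _, pli_r, _ = pli(cf)
        assert pli_r == pytest.approx(
            math.exp(np.mean(np.log(np.sqrt(cf)))), rel=1e-12
        )

    def test_literal_mode(self):
        pli_i, _, _ = pli([4.0], mode="literal")
        assert pli_i[0] == 4.0

    def test_nonpositive_cf_rejected(self):
        with pytest.raises(DomainError):
            pli([1.0, 0.0])


class TestPhi:
    @pytest.mark.parametrize(
        "polymer, score, level",
        [("PVC", 10001, "V"), ("AC", 10599, "V"), ("PC", 1177, "V"),
         ("PP", 1, "II")],
    )
    def test_single_polymer_reproduces_hazard_score(self, polymer, score, level):
        value, lev = phi({polymer: 1.0})
        assert value == score and lev == level

    def test_mixture(self):
        value, level = phi({"PE": 0.5, "PP": 0.5})
        assert value == pytest.approx(6.0) and level == "II"

    def test_unscored_polymer_strict_policy_names_it(self):
        with pytest.raises(DomainError, match="PTFE"):
            phi({"PTFE": 1.0})

    def test_exclude_policy_renormalises(self):
        value, _ = phi({"PTFE": 0.5, "PP": 0.5},
                       HazardTable(policy="exclude"))
        assert value == 1.0

    def test_bad_composition_rejected(self):
        with pytest.raises(DomainError):
            phi({"PE": 0.5})           # does not sum to 1

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_linearity_in_composition(self, alpha):
        p, q = {"PE": 1.0}, {"PVC": 1.0}
        mix = {"PE": alpha, "PVC": 1.0 - alpha}
        assert phi(mix)[0] == pytest.approx(
            alpha * phi(p)[0] + (1 - alpha) * phi(q)[0]
        )

    def test_monotone_shift_toward_higher_score(self):
        low = phi({"PP": 0.8, "PVC": 0.2})[0]
        high = phi({"PP": 0.6, "PVC": 0.4})[0]
        assert high > low


class TestPri:
    def test_collapses_to_hazard_score_at_unit_enrichment(self):
        value, _ = pri({"PA": 1.0}, cf=1.0)
        assert value == 50.0

    def test_printed_threshold_level(self):
        value, level = pri({"PA": 1.0}, cf=4.0)     # 200
        assert value == 200.0 and level == "II"

    def test_zero_enrichment(self):
        value, level = pri({"PVC": 1.0}, cf=0.0)
        assert value == 0.0 and level == "I"

    def test_per_polymer_enrichment(self):
        value, _ = pri({"PE": 0.5, "PP": 0.5}, cf={"PE": 2.0, "PP": 4.0})
        assert value == pytest.approx(0.5 * 2 * 11 + 0.5 * 4 * 1)


class TestNpi:
    def test_uniform_unit_ratios(self):
        value, level = npi([1.0, 1.0, 1.0])
        assert value == 1.0 and level == "II"

    def test_mean_one_max_three(self):
        value, level = npi([0.0, 0.0, 3.0])
        assert value == pytest.approx(math.sqrt(5.0)) and level == "IV"

    def test_single_zero_point(self):
        value, level = npi([0.0])
        assert value == 0.0 and level == "I"

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1,
                    max_size=12))
    def test_bounds(self, ps):
        value, _ = npi(ps)
        assert value >= np.mean(ps) - 1e-12
        assert value >= max(ps) / math.sqrt(2) - 1e-12

    def test_equal_ratios_collapse_to_mean(self):
        value, _ = npi([2.5] * 6)
        assert value == pytest.approx(2.5)

    def test_homogeneity_of_inventory_form(self, tiny_inventory):
        v1, _ = npi_from_inventory(tiny_inventory, "number", reference=373.0)
        doubled = tiny_inventory.assign(
            number_items_kg=2 * tiny_inventory["number_items_kg"]
        )
        v2, _ = npi_from_inventory(doubled, "number", reference=373.0)
        assert v2 == pytest.approx(2 * v1)

    def test_reference_abundance_gives_unit_index(self):
        inv = pd.DataFrame(
            dict(site_id=["S"] * 2, layer_index=[0, 1],
                 polymer=["PE", "PE"],
                 number_items_kg=[373.0, 373.0], mass_mg_kg=[10.0, 10.0])
        )
        value, level = npi_from_inventory(inv, "number")
        assert value == pytest.approx(1.0) and level == "II"

    def test_empty_inventory_rejected(self):
        empty = pd.DataFrame(
            columns=["site_id", "layer_index", "polymer",
                     "number_items_kg", "mass_mg_kg"]
        )
        with pytest.raises(DomainError):
            npi_from_inventory(empty, "number")


class TestClassificationBoundaries:
    """Every printed level boundary maps to its documented side."""

    @pytest.mark.parametrize(
        "value, level",
        [(0, "low"), (9.999, "low"), (10, "medium"), (19.999, "medium"),
         (20, "high"), (29.999, "high"), (30, "extremely high")],
    )
    def test_pli(self, value, level):
        assert classify_pli(value) == level

    @pytest.mark.parametrize(
        "value, level",
        [(0, "I"), (0.999, "I"), (1, "II"), (9.999, "II"), (10, "III"),
         (99.99, "III"), (100, "IV"), (999.9, "IV"), (1000, "V")],
    )
    def test_phi(self, value, level):
        assert classify_phi(value) == level

    @pytest.mark.parametrize(
        "value, level",
        [(0, "I"), (149.9, "I"), (150, "II"), (299.9, "II"), (300, "III"),
         (599.9, "III"), (600, "IV"), (1199.9, "IV"), (1200, "V")],
    )
    def test_pri(self, value, level):
        assert classify_pri(value) == level

    @pytest.mark.parametrize(
        "value, level",
        [(0, "I"), (0.7, "I"), (0.70001, "II"), (1.0, "II"), (1.00001, "III"),
         (2.0, "III"), (2.00001, "IV"), (3.0, "IV"), (3.00001, "V")],
    )
    def test_npi(self, value, level):
        assert classify_npi(value) == level

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0, max_value=1e5))
    def test_classifiers_total_on_nonnegative_reals(self, x):
        assert classify_pli(x) in {"low", "medium", "high", "extremely high"}
        for f in (classify_phi, classify_pri, classify_npi):
            assert f(x) in {"I", "II", "III", "IV", "V"}


class TestNaiveOracleEquivalence:
    def test_indices_match_naive_reimplementation(self):
        """1000 random small inputs agree with an independent naive
        re-implementation to 1e-12 relative."""
        rng = np.random.default_rng(12345)
        polymers = list(DEFAULT_HAZARD_SCORES)
        for _ in range(1000):
            n = rng.integers(1, 7)
            cf = rng.uniform(0.01, 40, n)
            _, pli_r, _ = pli(cf)
            assert pli_r == pytest.approx(naive_pli(cf)[1], rel=1e-12)

            k = rng.integers(1, 6)
            chosen = rng.choice(polymers, size=k, replace=False)
            w = rng.dirichlet(np.ones(k))
            comp = dict(zip(chosen, w))
            assert phi(comp)[0] == pytest.approx(
                naive_phi(comp, DEFAULT_HAZARD_SCORES), rel=1e-12
            )
            c = float(rng.uniform(0, 10))
            assert pri(comp, c)[0] == pytest.approx(
                naive_pri(comp, c, DEFAULT_HAZARD_SCORES), rel=1e-12
            )
            ps = rng.uniform(0, 5, n)
            assert npi(ps)[0] == pytest.approx(naive_npi(ps), rel=1e-12)


class TestRiskReport:
    def make_site(self, scale):
        return pd.DataFrame(
            dict(
                site_id=[f"S{scale}"] * 4,
                layer_index=[0, 0, 1, 1],
                polymer=["PE", "PVC", "PP", "PA"],
                number_items_kg=np.array([100.0, 50, 80, 20]) * scale,
                mass_mg_kg=np.array([50.0, 25, 40, 10]) * scale,
            )
        )

    def test_two_sites_min_max_normalised(self):
        rep = risk_report({"A": self.make_site(1), "B": self.make_site(3)})
        assert rep.normalized is not None
        for col in ("pli_r", "npi_n", "npi_m"):
            assert set(np.round(rep.normalized[col], 12)) == {0.0, 1.0}

    def test_identical_sites_skip_normalisation(self):
        with pytest.warns(UserWarning):
            rep = risk_report({"A": self.make_site(1), "B": self.make_site(1)})
        assert rep.normalized is None

    def test_parameters_echoed(self):
        rep = risk_report({"A": self.make_site(1), "B": self.make_site(2)})
        p = rep.parameters
        assert p["cs_number"] == 373.0 and p["cs_mass"] == 3465.0
        assert "hazard_table_digest" in p and p["c0"] > 0

    def test_background_defaults_to_lowest_abundance(self):
        rep = risk_report({"A": self.make_site(1), "B": self.make_site(2)})
        # lowest positive layer total (number basis) across sites
        assert rep.parameters["c0"] == pytest.approx(100.0)

    def test_composition_from_inventory(self, tiny_inventory):
        comp = composition_from_inventory(tiny_inventory, basis="number")
        assert sum(comp.values()) == pytest.approx(1.0)
        assert comp["PE"] == pytest.approx(180.0 / 250.0)
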