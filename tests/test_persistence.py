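import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from conftest import random_history
from occgaps.persistence import (
    ModelConfig,
    classify_persistence,
    estimate_detection_rate,
    estimate_effort,
    persistence_oracle,
    persistence_probability,
    persistence_table,
)


class TestEstimateEffort:
    def cell_rows(self, pairs):
        return pd.DataFrame(pairs, columns=["species_id", "best_year"])

    def test_counts_per_year(self):
        rows = self.cell_rows([("A", 1970)] * 3 + [("B", 1990)])
        e = estimate_effort(rows, 1969, 1991)
        assert e[1970 - 1969] == 3 and e[1990 - 1969] == 1 and e.sum() == 4

    def test_empty_span_all_zero(self):
        e = estimate_effort(self.cell_rows([]), 1970, 1980)
        assert e.shape == (11,) and not e.any()

    def test_other_species_mode_excludes_focal(self):
        rows = self.cell_rows([("A", 1970), ("A", 1971)])
        e = estimate_effort(rows, 1970, 1971, focal_species="A")
        assert not e.any()

    def test_undated_records_do_not_contribute(self):
        rows = pd.DataFrame({"species_id": ["A", "A"], "best_year": [1970, None]})
        assert estimate_effort(rows, 1970, 1970).sum() == 1


class TestDetectionRate:
    @pytest.mark.parametrize(
        "n,e,expected",
        [
            ([1, 1], [1, 1], 1.0),
            ([2, 0, 1], [1, 1, 2], 0.75),
            ([5], [10], 0.5),
            ([1, 2, 0, 0], [2, 2, 5, 5], 0.75),  # post-last-sighting years ignored
        ],
    )
    def test_closed_form(self, n, e, expected):
        assert estimate_detection_rate(np.array(n), np.array(e)) == pytest.approx(expected)

    def test_matches_numerical_poisson_mle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n, e = random_history(rng, max_years=25)
            i_last = np.nonzero(n)[0][-1]

            def nll(r):
                lam = r * e[: i_last + 1]
                return float(np.sum(lam) - np.sum(n[: i_last + 1] * np.log(np.maximum(lam, 1e-300))))

            res = minimize_scalar(nll, bounds=(1e-9, 50), method="bounded")
            assert estimate_detection_rate(n, e) == pytest.approx(res.x, abs=1e-5)

    def test_no_sightings_rejected(self):
        with pytest.raises(ValueError):
            estimate_detection_rate(np.zeros(3), np.ones(3))

    def test_zero_effort_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_detection_rate(np.array([1.0]), np.array([0.0]))


class TestPersistenceProbability:
    def test_worked_three_year_example(self):
        # one sighting then two surveyed-but-empty years at r = 1
        p = persistence_probability(np.array([1, 0, 0]), np.array([1, 1, 1]), 1.0, 0.5)
        assert p == pytest.approx(0.165, abs=5e-4)
        assert p == pytest.approx(
            persistence_oracle(np.array([1, 0, 0]), np.array([1, 1, 1]), 1.0, 0.5),
            abs=1e-12,
        )

    def test_zero_post_effort_returns_prior_exactly(self):
        p = persistence_probability(
            np.array([2, 1, 0, 0, 0]), np.array([1, 2, 0, 0, 0]), 1.5, 0.5
        )
        assert p == 0.5

    def test_final_year_sighting_is_certain_persistence(self):
        p = persistence_probability(np.array([1, 0, 1]), np.array([1, 1, 1]), 1.0)
        assert p == 1.0

    def test_single_year_history(self):
        assert persistence_oracle(np.array([1.0]), np.array([1.0]), 1.0) == 1.0
        assert persistence_probability(np.array([1.0]), np.array([1.0]), 1.0) == 1.0

    def test_oracle_equivalence_seeded(self):
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(20):
            n, e = random_history(rng)
            r = estimate_detection_rate(n, e)
            worst = max(
                worst,
                abs(persistence_probability(n, e, r) - persistence_oracle(n, e, r)),
            )
        assert worst < 1e-10

    def test_monotone_in_post_effort(self):
        # adding effort to any post-last-sighting year cannot raise p
        rng = np.random.default_rng(9)
        for _ in range(20):
            n, e = random_history(rng)
            i_last = np.nonzero(n)[0][-1]
            if i_last == n.size - 1:
                continue
            r = estimate_detection_rate(n, e)
            p0 = persistence_probability(n, e, r)
            j = int(rng.integers(i_last + 1, n.size))
            e2 = e.copy()
            e2[j] += rng.uniform(0.5, 3.0)
            assert persistence_probability(n, e2, r) <= p0 + 1e-12

    def test_limit_heavy_effort_drives_p_to_zero(self):
        n = np.array([1.0, 0, 0, 0])
        e = np.array([1.0, 100, 100, 100])
        assert persistence_probability(n, e, 1.0) < 1e-10

    @settings(max_examples=100, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        prior=st.floats(0.05, 0.95),
    )
    def test_posterior_is_probability_and_matches_oracle(self, seed, prior):
        rng = np.random.default_rng(seed)
        n, e = random_history(rng, max_years=20)
        r = estimate_detection_rate(n, e)
        p = persistence_probability(n, e, r, prior)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(persistence_oracle(n, e, r, prior), abs=1e-10)


class TestClassifyPersistence:
    @pytest.mark.parametrize("p,expected", [(0.5, True), (0.49, False), (1.0, True)])
    def test_threshold_with_tie_extant(self, p, expected):
        assert classify_persistence(p, 0.5) is expected

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            classify_persistence(1.5)


class TestPersistenceTable:
    def test_covers_exactly_pre_only_pairs(self, gridded, persistence_tab):
        pairs = gridded.groupby(["species_id", "ix", "iy"])["period"].agg(
            lambda s: set(s)
        )
        pre_only = {k for k, v in pairs.items() if v == {"pre"}}
        got = set(map(tuple, persistence_tab[["species_id", "ix", "iy"]].values))
        assert got == pre_only

    def test_probabilities_valid_and_calls_consistent(self, persistence_tab):
        p = persistence_tab["p_extant"]
        assert ((p >= 0) & (p <= 1)).all()
        assert (persistence_tab["extant_call"] == (p >= 0.5)).all()

    def test_never_revisited_cell_sits_at_the_prior(self):
        # a cell last surveyed the year of the species' last sighting: the
        # posterior cannot move off the prior, and the tie rule keeps it
        gridded = pd.DataFrame(
            {
                "species_id": ["A", "A", "B"],
                "ix": [0, 0, 0],
                "iy": [0, 0, 0],
                "period": ["pre", "pre", "pre"],
                "best_year": [1970, 1975, 1975],
            }
        )
        tab = persistence_table(gridded, ModelConfig())
        tab = tab.set_index("species_id")
        assert tab.loc["A", "p_extant"] == 0.5
        assert bool(tab.loc["A", "extant_call"]) is True

    def test_effort_mode_other_species(self, gridded):
        cfg = ModelConfig(effort_mode="other_species")
        tab = persistence_table(gridded.head(2000), cfg)
        assert ((tab["p_extant"] >= 0) & (tab["p_extant"] <= 1)).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(threshold=0.0)
        with pytest.raises(ValueError):
            ModelConfig(effort_mode="nope")
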