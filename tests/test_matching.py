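import math

import numpy as np
import pytest
from scipy.special import expit

from crisischat.matching import (
    MatchRecord,
    PerfectSeparationError,
    fit_propensity,
    fit_propensity_coefficients,
    logit,
    match_pairs,
    standardized_mean_diff,
)


def _records_from_logits(treated_logits, control_logits):
    recs, props = [], {}
    for i, lg in enumerate(treated_logits):
        rid = f"t{i}"
        recs.append(MatchRecord(rid, True, 5.0, "a"))
        props[rid] = float(expit(lg))
    for i, lg in enumerate(control_logits):
        rid = f"c{i}"
        recs.append(MatchRecord(rid, False, 5.0, "a"))
        props[rid] = float(expit(lg))
    return recs, props


class TestLogit:
    def test_half_maps_to_zero(self):
        assert logit(0.5) == 0.0

    def test_closed_form_value(self):
        assert logit(0.75) == pytest.approx(math.log(3.0))

    def test_antisymmetry(self):
        assert logit(1 - 0.3) == pytest.approx(-logit(0.3))

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_outside_open_interval_raises(self, p):
        with pytest.raises(ValueError):
            logit(p)


class TestPropensityFit:
    def test_null_model_limit_gives_marginal_fraction(self):
        rng = np.random.default_rng(0)
        recs = [
            MatchRecord(f"r{i}", bool(i < 400), float(rng.uniform(1, 10)), "a")
            for i in range(1000)
        ]
        props = fit_propensity(recs)
        assert np.allclose(list(props.values()), 0.4, atol=0.12)
        assert np.mean(list(props.values())) == pytest.approx(0.4, abs=1e-6)

    def test_known_intensity_coefficient_recovered(self):
        rng = np.random.default_rng(42)
        n = 10_000
        x = rng.uniform(1, 10, size=n)
        topics = rng.choice(["a", "b"], size=n)
        eta = -4.5 + 0.8 * x + 0.3 * (topics == "b")
        y = rng.random(n) < expit(eta)
        recs = [
            MatchRecord(f"r{i}", bool(y[i]), float(x[i]), str(topics[i])) for i in range(n)
        ]
        beta, names = fit_propensity_coefficients(recs)
        j = names.index("intensity")
        # SE for the 3-SE band from an independent statsmodels fit
        import statsmodels.api as sm

        X = np.column_stack([np.ones(n), x, (topics == "b").astype(float)])
        fit = sm.Logit(y.astype(float), X).fit(disp=0)
        assert abs(beta[j] - 0.8) < 3 * fit.bse[1]
        assert abs(beta[j] - fit.params[1]) < 1e-6

    def test_coefficients_match_independent_optimizer(self):
        recs = [
            MatchRecord("a", True, 7.0, "x"),
            MatchRecord("b", True, 5.0, "x"),
            MatchRecord("c", False, 4.0, "x"),
            MatchRecord("d", False, 6.0, "x"),
            MatchRecord("e", False, 3.0, "x"),
            MatchRecord("f", True, 8.0, "x"),
        ]
        beta, names = fit_propensity_coefficients(recs)
        import statsmodels.api as sm

        X = np.column_stack([np.ones(6), [7, 5, 4, 6, 3, 8]])
        y = np.array([1, 1, 0, 0, 0, 1], dtype=float)
        ref = sm.Logit(y, X).fit(disp=0, method="newton")
        assert np.allclose(beta, ref.params, atol=1e-6)

    def test_perfect_separation_raises_with_ridge_advice(self):
        recs = [MatchRecord(f"t{i}", True, 9.0 + i * 0.1, "x") for i in range(5)] + [
            MatchRecord(f"c{i}", False, 1.0 + i * 0.1, "x") for i in range(5)
        ]
        with pytest.raises(PerfectSeparationError, match="ridge"):
            fit_propensity(recs)
        props = fit_propensity(recs, ridge=1e-6)  # penalized fit succeeds
        assert all(0.0 < p < 1.0 for p in props.values())

    def test_needs_both_groups(self):
        with pytest.raises(ValueError):
            fit_propensity([MatchRecord("a", True, 5.0, "x")])


class TestMatchPairs:
    def test_identical_propensities_all_match_at_distance_zero(self):
        recs, props = _records_from_logits([0.3] * 4, [0.3] * 6)
        res = match_pairs(recs, props, caliper=0.01, rng=0)
        assert res.n_pairs == 4
        assert all(d == 0.0 for _, _, d in res.pairs)

    def test_caliper_excludes_distant_treated_unit(self):
        recs, props = _records_from_logits([0.00, 0.05], [0.004, 0.30])
        res = match_pairs(recs, props, caliper=0.01, rng=1)
        assert res.pairs == [("t0", "c0", pytest.approx(0.004, abs=1e-9))]
        assert res.excluded == ["t1"]

    def test_infinite_caliper_on_equal_groups_matches_everything(self):
        rng = np.random.default_rng(5)
        recs, props = _records_from_logits(rng.normal(size=8), rng.normal(size=8))
        res = match_pairs(recs, props, caliper=np.inf, rng=2)
        assert res.n_pairs == 8

    def test_no_controls_excludes_all_treated(self):
        recs, props = _records_from_logits([0.1, 0.2], [])
        res = match_pairs(recs, props, caliper=0.01, rng=0)
        assert res.n_pairs == 0 and sorted(res.excluded) == ["t0", "t1"]

    def test_missing_propensity_raises(self):
        recs, props = _records_from_logits([0.1], [0.1])
        del props["c0"]
        with pytest.raises(KeyError):
            match_pairs(recs, props)

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_matches_brute_force_oracle_on_small_instances(self, seed):
        """On 10-unit instances the implementation equals a pure-Python
        greedy oracle that scans every remaining control per treated unit
        (same seeded processing order, ties to lowest id)."""
        rng = np.random.default_rng(1000 + seed)
        t_logits = rng.normal(size=5) * 0.05
        c_logits = rng.normal(size=5) * 0.05
        recs, props = _records_from_logits(t_logits, c_logits)
        caliper = 0.03
        res = match_pairs(recs, props, caliper=caliper, rng=seed)

        treated = sorted(r.id for r in recs if r.treated)
        controls = sorted(r.id for r in recs if not r.treated)
        lg = {rid: math.log(props[rid] / (1 - props[rid])) for rid in props}
        order = np.random.default_rng(seed).permutation(len(treated))
        remaining = set(controls)
        expected_pairs, expected_excluded = [], []
        for idx in order:
            t = treated[idx]
            best, best_d = None, None
            for c in sorted(remaining):
                d = abs(lg[t] - lg[c])
                if best_d is None or d < best_d - 1e-15:
                    best, best_d = c, d
            if best is None or best_d > caliper:
                expected_excluded.append(t)
                continue
            remaining.discard(best)
            expected_pairs.append((t, best))
        assert sorted((t, c) for t, c, _ in res.pairs) == sorted(expected_pairs)
        assert sorted(res.excluded) == sorted(expected_excluded)

    @pytest.mark.parametrize("seed", range(4))
    def test_without_replacement_and_caliper_invariants(self, seed):
        rng = np.random.default_rng(seed)
        recs, props = _records_from_logits(rng.normal(size=30) * 0.1, rng.normal(size=20) * 0.1)
        res = match_pairs(recs, props, caliper=0.05, rng=seed)
        controls_used = [c for _, c, _ in res.pairs]
        assert len(controls_used) == len(set(controls_used))
        assert res.n_pairs <= 20
        assert all(d <= 0.05 for _, _, d in res.pairs)
        assert res.n_pairs + len(res.excluded) == 30


class TestBalance:
    def test_identical_matched_groups_have_zero_smd(self):
        recs, props = _records_from_logits([0.2, 0.4], [0.2, 0.4])
        for r in recs:
            object.__setattr__(r, "initial_intensity", 6.0)
        res = match_pairs(recs, props, caliper=1.0, rng=0)
        rows = standardized_mean_diff(recs, res)
        by_name = {r.covariate: r for r in rows}
        assert by_name["intensity"].smd_after == 0.0

    def test_two_pair_example_matches_hand_arithmetic(self):
        recs = [
            MatchRecord("t0", True, 8.0, "a"),
            MatchRecord("t1", True, 6.0, "a"),
            MatchRecord("c0", False, 7.0, "a"),
            MatchRecord("c1", False, 5.0, "a"),
        ]
        props = {"t0": 0.6, "t1": 0.6, "c0": 0.6, "c1": 0.6}
        res = match_pairs(recs, props, caliper=1.0, rng=0)
        rows = {r.covariate: r for r in standardized_mean_diff(recs, res)}
        # pooled SD = sqrt(var_T/2 + var_C/2) = sqrt(1 + 1) with var = 2
        expected = (7.0 - 6.0) / math.sqrt(2.0)
        assert rows["intensity"].smd_before == pytest.approx(expected)

    def test_matching_on_true_propensities_reduces_confounding(self):
        """Simulated confounded data: treatment probability rises with
        intensity, so SMD before matching is large; matching on the fitted
        propensities shrinks it."""
        rng = np.random.default_rng(77)
        n = 5_000
        x = rng.uniform(1, 10, size=n)
        treated = rng.random(n) < expit(-3.0 + 0.5 * x)
        recs = [
            MatchRecord(f"r{i}", bool(treated[i]), float(x[i]), "a") for i in range(n)
        ]
        props = fit_propensity(recs)
        res = match_pairs(recs, props, caliper=0.1, rng=7)
        rows = {r.covariate: r for r in standardized_mean_diff(recs, res)}
        assert abs(rows["intensity"].smd_after) < abs(rows["intensity"].smd_before)
        assert abs(rows["intensity"].smd_after) < 0.1
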