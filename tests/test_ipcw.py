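"""Censoring Kaplan–Meier, IPCW weights and the IPCW concordance index."""

import numpy as np
import pytest

import iabrisk as ir
from iabrisk.ipcw import ConcordanceUndefinedError, fit_censoring_km


@pytest.fixture()
def hand_km():
    """The worked 4-subject example: X = 1(ev), 2(cens), 3(ev), 4(cens)."""
    return fit_censoring_km([1, 2, 3, 4], [True, False, True, False])


class TestCensoringKM:
    def test_hand_product_limit_values(self, hand_km):
        # at t=2 the risk set {2,3,4} gives factor 2/3; at t=4 risk set {4} gives 0
        assert np.allclose(hand_km.jump_times, [2, 4])
        assert np.allclose(hand_km.survival_values, [2 / 3, 0.0])
        assert hand_km.evaluate(1.9) == 1.0
        assert hand_km.evaluate(2.0) == pytest.approx(2 / 3)
        assert hand_km.evaluate_left(2.0) == 1.0
        assert hand_km.evaluate(3.9) == pytest.approx(2 / 3)
        assert hand_km.evaluate(4.0) == 0.0

    def test_no_censoring_gives_unit_survival(self):
        G = fit_censoring_km([1, 2, 3], [True, True, True])
        assert G.jump_times.size == 0
        assert np.all(G.evaluate([0, 5, 100]) == 1.0)

    def test_all_censored_at_common_time(self):
        G = fit_censoring_km([2.5] * 4, [False] * 4)
        assert G.evaluate(2.4) == 1.0
        assert G.evaluate(2.5) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_censoring_km([], [])

    def test_matches_lifelines_on_random_data(self):
        """Cross-check against the standard product-limit implementation."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 10, 200).round(1)  # rounding forces ties
        delta = rng.random(200) < 0.5
        G = fit_censoring_km(x, delta)
        km = KaplanMeierFitter().fit(x, event_observed=~delta)
        for t in np.linspace(0, 11, 45):
            assert G.evaluate(t) == pytest.approx(
                float(km.predict(t)), abs=1e-12
            )

    def test_tie_rule_censor_first(self):
        # one event and one censoring at t=2: censor-first removes the event
        # from the risk set of the censoring
        x, d = [2, 2, 3], [True, False, False]
        default = fit_censoring_km(x, d)
        alt = fit_censoring_km(x, d, ties="censor_first")
        assert default.evaluate(2) == pytest.approx(1 - 1 / 3)
        assert alt.evaluate(2) == pytest.approx(1 - 1 / 2)

    def test_json_round_trip(self, hand_km):
        clone = ir.CensoringModel.from_json(hand_km.to_json())
        assert np.array_equal(clone.jump_times, hand_km.jump_times)
        assert np.array_equal(clone.survival_values, hand_km.survival_values)
        assert clone.n_fitted == hand_km.n_fitted


class TestWeights:
    def test_no_censoring_means_unit_weights(self):
        G = fit_censoring_km([1, 2, 3], [True] * 3)
        w = ir.ipcw_weights([0.5, 2.0, 11.0], [1.0, 1.0, 0.0], G, tau=10)
        assert np.allclose(w, 1.0)

    def test_event_weight_uses_left_limit(self, hand_km):
        # event at X=3: Ĝ(3⁻) = 2/3 so the weight is 1.5
        w = ir.ipcw_weights([3.0], [1.0], hand_km, tau=5)
        assert w[0] == pytest.approx(1.5)

    def test_censored_rows_get_zero_weight(self, hand_km):
        w = ir.ipcw_weights([2.0], [np.nan], hand_km, tau=5)
        assert w[0] == 0.0

    def test_zero_survival_hits_the_cap(self, hand_km):
        w = ir.ipcw_weights([4.5], [1.0], hand_km, tau=5, w_max=20.0)
        assert w[0] == 20.0

    def test_weight_sum_estimates_cohort_size(self):
        """Σw within 10% of n under ~30% independent censoring."""
        rng = np.random.default_rng(11)
        n = 2000
        tau = 5.0
        event_time = rng.exponential(6.0, n)
        cens_time = np.minimum(rng.exponential(12.0, n), tau + 2)
        x = np.minimum(event_time, cens_time)
        delta = event_time <= cens_time
        label = np.where(
            delta & (x <= tau), 1.0, np.where(x > tau, 0.0, np.nan)
        )
        G = fit_censoring_km(x, delta)
        w = ir.ipcw_weights(x, label, G, tau=tau)
        assert 0.3 > np.isnan(label).mean() > 0.1  # sanity: real censoring present
        assert abs(w.sum() - n) / n < 0.10


def _c_index_oracle(scores, x, delta, G, tau, w_max=20.0):
    """Exhaustive double-loop pair sum, written independently of the module."""
    num = den = 0.0
    for i in range(len(x)):
        if not delta[i] or x[i] >= tau:
            continue
        g = G.evaluate_left(x[i])
        wi = min(1.0 / g, w_max) ** 2 if g > 0 else w_max**2
        for j in range(len(x)):
            if x[j] > x[i]:
                den += wi
                if scores[i] > scores[j]:
                    num += wi
                elif scores[i] == scores[j]:
                    num += 0.5 * wi
    if den == 0:
        return None
    return num / den


class TestCIndex:
    def test_single_correctly_ordered_pair(self):
        G = fit_censoring_km([1, 5], [True, True])
        assert ir.ipcw_c_index([0.9, 0.1], [1, 5], [True, False], G, tau=10) == 1.0

    def test_single_wrongly_ordered_pair(self):
        G = fit_censoring_km([1, 5], [True, True])
        assert ir.ipcw_c_index([0.1, 0.9], [1, 5], [True, False], G, tau=10) == 0.0

    def test_all_ties_give_half(self):
        G = fit_censoring_km([1, 2, 5], [True] * 3)
        assert ir.ipcw_c_index([0.3] * 3, [1, 2, 5], [True, True, False], G, tau=10) == 0.5

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            n = int(rng.integers(3, 10))
            x = rng.uniform(0.1, 10, n)
            delta = rng.random(n) < 0.6
            scores = rng.choice([0.1, 0.4, 0.4, 0.9], n)  # ties likely
            tau = float(rng.uniform(2, 12))
            G = fit_censoring_km(x, delta)
            expected = _c_index_oracle(scores, x, delta, G, tau)
            if expected is None:
                with pytest.raises(ConcordanceUndefinedError):
                    ir.ipcw_c_index(scores, x, delta, G, tau=tau)
            else:
                got = ir.ipcw_c_index(scores, x, delta, G, tau=tau)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_equals_classical_concordance_without_censoring(self):
        """With no censoring and τ beyond all times, reduces to plain AUC."""
        rng = np.random.default_rng(29)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x = rng.uniform(0.1, 10, n)
            delta = np.ones(n, dtype=bool)
            scores = rng.normal(size=n)
            G = fit_censoring_km(x, delta)
            got = ir.ipcw_c_index(scores, x, delta, G, tau=x.max() + 1)
            naive_num = naive_den = 0.0
            for i in range(n):
                for j in range(n):
                    if x[i] < x[j]:
                        naive_den += 1
                        naive_num += (
                            1.0 if scores[i] > scores[j] else 0.5 if scores[i] == scores[j] else 0.0
                        )
            assert got == pytest.approx(naive_num / naive_den, abs=1e-12)

    def test_matches_scikit_survival_estimator(self):
        """Dual route: agrees with sksurv's Uno estimator on censored data."""
        from sksurv.metrics import concordance_index_ipcw
        from sksurv.util import Surv

        rng = np.random.default_rng(5)
        n = 80
        x = rng.uniform(0.5, 12, n)
        delta = rng.random(n) < 0.6
        scores = rng.normal(size=n)
        y = Surv.from_arrays(event=delta, time=x)
        G = fit_censoring_km(x, delta)
        mine = ir.ipcw_c_index(scores, x, delta, G, tau=8.0, w_max=1e12)
        theirs = concordance_index_ipcw(y, y, scores, tau=8.0)[0]
        assert mine == pytest.approx(theirs, abs=1e-10)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0.1, 10, 60)
        delta = rng.random(60) < 0.6
        scores = rng.normal(size=60)
        G = fit_censoring_km(x, delta)
        base = ir.ipcw_c_index(scores, x, delta, G, tau=8)
        for transform in (np.exp, lambda s: 3 * s - 7, np.cbrt):
            assert ir.ipcw_c_index(transform(scores), x, delta, G, tau=8) == pytest.approx(
                base, abs=1e-12
            )

    def test_no_comparable_pairs_is_signalled(self):
        G = fit_censoring_km([5, 6], [False, False])
        with pytest.raises(ConcordanceUndefinedError):
            ir.ipcw_c_index([0.1, 0.2], [5, 6], [False, False], G, tau=10)
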