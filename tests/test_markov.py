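"""Eight-state rate model: mapping, estimation, cycles, entropy."""

import numpy as np
import pytest

from ratchetsim.markov import (
    STATES, STATE_ID, EDGE_CLASS, CLASS_EDGES, coarse_state, coarse_series,
    EightStateModel, estimate_rates, cycle_ratio, r_approx, RateResults,
    resolve_pathways, entropy_production_rate, markov_entropy_rate,
    build_generator, stationary_distribution, fc1_cycle, max_coupling_fc1,
    fundamental_cycles, RATE_NAMES)
from ratchetsim.fixtures import make_ctmc_trajectory, make_event_stream


def _rates(**kw):
    base = {"attach_close": 0.05, "cleave_close": 0.05, "attach_far": 0.05,
            "cleave_far": 0.05, "cw": 0.05, "ccw": 0.05, "sym": 0.05}
    base.update(kw)
    return base


def _results(rates, p_ss=None):
    return RateResults(rates=rates, stderr={k: None for k in rates},
                       p_ss=np.full(8, 0.125) if p_ss is None else p_ss,
                       N=np.zeros((8, 8), dtype=np.int64), t_obs=1.0)


class TestStateMapping:
    def test_mapping_is_a_bijection(self):
        assert sorted(STATES) == list(range(1, 9))
        assert len({v for v in STATES.values()}) == 8

    def test_far_cleavage_transitions_fix_the_numbering(self):
        """The pooled far-cleavage formula names exactly 2->1, 3->4, 5->6, 8->7."""
        assert CLASS_EDGES["cleave_far"] == [(2, 1), (3, 4), (5, 6), (8, 7)]

    def test_graph_has_eleven_edges_and_four_cycles(self):
        und = {tuple(sorted(e)) for e in EDGE_CLASS}
        assert len(und) == 11
        assert len(fundamental_cycles()) == 4

    def test_both_blocked_ring_moves_disconnected(self):
        assert (3, 8) not in EDGE_CLASS and (8, 3) not in EDGE_CLASS

    @pytest.mark.parametrize("idx,b1,b2,expect", [
        (0, False, False, STATE_ID[(1, 0, 0)]),
        (15, True, True, STATE_ID[(2, 1, 1)]),
        (7, False, False, STATE_ID[(1, 0, 0)]),
        (8, False, False, STATE_ID[(2, 0, 0)]),
        (23, False, False, STATE_ID[(1, 0, 0)]),
        (22, False, False, STATE_ID[(2, 0, 0)]),
    ])
    def test_coarse_state_convention(self, idx, b1, b2, expect):
        assert coarse_state(idx, b1, b2) == expect

    def test_vectorised_series_matches_scalar(self, rng):
        idx = rng.integers(0, 30, 200)
        blk = rng.integers(0, 2, (200, 2)).astype(np.uint8)
        vec = coarse_series(idx, blk)
        ref = [coarse_state(i, b[0], b[1]) for i, b in zip(idx, blk)]
        assert np.array_equal(vec, ref)


class TestEstimator:
    def test_counting_formula_toy_example(self):
        """p_ss = 0.5 each for states 1 and 6, 10 transitions each way over
        t_obs = 100 -> pooled k_sym = 20 / (100 * 1) = 0.2."""
        block = [1] * 50 + [6] * 50
        series = np.array(block * 10)        # 10 up-switches, 9 down-switches
        dt = 100.0 / len(series)
        fit = estimate_rates(series, dt)
        assert fit.rates["sym"] == pytest.approx(19 / 100.0, rel=1e-9)
        assert fit.p_ss[0] == pytest.approx(0.5)
        assert fit.p_ss[5] == pytest.approx(0.5)

    def test_rate_recovery_from_gillespie_oracle(self, rng):
        truth = _rates(attach_close=0.02, attach_far=0.08, cw=0.1, ccw=0.03,
                       cleave_close=0.06, cleave_far=0.04, sym=0.05)
        series = [make_ctmc_trajectory(truth, t_obs=20_000, dt=0.05, rng=rng)[0]
                  for _ in range(4)]
        fit = EightStateModel(series, 0.05).fit()
        for name in RATE_NAMES:
            se = fit.stderr[name] or 0.0
            tol = max(3 * se, 0.12 * truth[name])
            assert abs(fit.rates[name] - truth[name]) < tol, name

    def test_time_reversal_swaps_conjugate_fluxes(self, rng):
        """Reversing the series swaps attach<->cleave and CW<->CCW transition
        fluxes exactly: k_class(rev) * p_src(class) = k_conj(fwd) * p_src(conj),
        since the reversed numerator counts are the conjugate edges' counts."""
        truth = _rates(attach_close=0.08, cleave_close=0.02, cw=0.09, ccw=0.02)
        series, _ = make_ctmc_trajectory(truth, t_obs=5000, dt=0.05, rng=rng)
        fwd = estimate_rates(series, 0.05)
        rev = estimate_rates(series[::-1], 0.05)
        assert np.array_equal(rev.p_ss, fwd.p_ss)

        def flux(fit, name):
            return sum(fit.N[a - 1, b - 1] for a, b in CLASS_EDGES[name])

        for a_cls, b_cls in (("attach_close", "cleave_close"),
                             ("attach_far", "cleave_far"), ("cw", "ccw")):
            assert flux(rev, a_cls) == flux(fwd, b_cls)
            assert flux(rev, b_cls) == flux(fwd, a_cls)

    def test_missing_rate_reported_not_zero_divided(self):
        series = np.ones(100, dtype=np.int64)      # never leaves state 1
        fit = estimate_rates(series, 0.05)
        assert fit.rates["cleave_far"] is None     # no dwell in states 2,3,5,8

    def test_disconnected_transitions_counted_and_dropped(self):
        series = np.array([3, 8, 3, 8, 3])          # both-blocked ring hops
        fit = estimate_rates(series, 1.0)
        assert fit.n_disconnected == 4
        assert fit.N.sum() == 4


class TestCycleAnalysis:
    def test_equal_rates_give_unit_ratio(self):
        rep = cycle_ratio(_results(_rates()))
        assert rep.R == pytest.approx(1.0) and rep.affinity == pytest.approx(0.0)

    def test_detailed_balance_gives_unit_ratio_within_noise(self, rng):
        # attach/cleave tuned so the one-blocked cycles obey detailed balance
        truth = _rates(attach_close=0.08, attach_far=0.04, cleave_close=0.03,
                       cleave_far=0.06, cw=0.1, ccw=0.025)
        R_true = (0.04 / 0.08) * (0.03 / 0.06) * (0.1 / 0.025)
        assert R_true == pytest.approx(1.0)
        series = [make_ctmc_trajectory(truth, 15_000, 0.05, rng)[0]
                  for _ in range(4)]
        fit = EightStateModel(series, 0.05).fit()
        rep = fit.cycle_report()
        assert abs(rep.affinity) < 0.25

    def test_driven_generator_recovers_affinity_and_current_sign(self, rng):
        truth = _rates(attach_far=0.1, attach_close=0.05)     # R = 2
        series = [make_ctmc_trajectory(truth, 15_000, 0.05, rng)[0]
                  for _ in range(4)]
        fit = EightStateModel(series, 0.05).fit()
        rep = fit.cycle_report()
        assert abs(rep.affinity - np.log(2)) < 0.3
        # net current on the CW ring edges shares the sign of the affinity
        net = sum(fit.N[a - 1, b - 1] for a, b in CLASS_EDGES["cw"]) \
            - sum(fit.N[a - 1, b - 1] for a, b in CLASS_EDGES["ccw"])
        assert np.sign(net) == np.sign(rep.affinity)

    def test_r_approx_identities(self):
        est0 = _results(_rates())
        assert r_approx(est0, est0) == pytest.approx(1.0)
        estN = _results(_rates(attach_far=0.1))     # far doubled, close fixed
        assert r_approx(estN, est0) == pytest.approx(2.0)
        # attachment-only perturbations: R_approx equals the full ratio exactly
        estN2 = _results(_rates(attach_far=0.12, attach_close=0.02))
        R_full = cycle_ratio(estN2).R / cycle_ratio(est0).R
        assert r_approx(estN2, est0) == pytest.approx(R_full)

    def test_fc1_is_the_fully_ratcheted_six_cycle(self):
        cyc = fc1_cycle()
        assert len(cyc) == 6
        assert set(cyc) == {1, 2, 7, 6, 5, 4}
        assert max_coupling_fc1() == pytest.approx(0.5)


class TestPathways:
    def test_pure_c_pathway(self):
        events, _ = make_event_stream(0.05, 0.0, 2000.0,
                                      np.random.default_rng(0))
        pw = resolve_pathways(events, threshold=1.0, k_attach=0.05)
        assert pw.n_attach_TC == 0
        assert pw.k_attach_TC == 0.0

    def test_partition_identity(self, rng):
        events, _ = make_event_stream(0.05, 0.02, 2000.0, rng)
        pw = resolve_pathways(events, threshold=1.0, k_attach=0.07)
        assert pw.k_attach_C + pw.k_attach_TC == pytest.approx(pw.k_attach)

    def test_mixture_fractions_recovered(self, rng):
        events, truth = make_event_stream(0.03, 0.07, 20_000.0, rng,
                                          mode_C=5.0, mode_TC=0.8, spread=0.05)
        pw = resolve_pathways(events, threshold=1.0)
        n = pw.n_attach_C + pw.n_attach_TC
        frac = pw.n_attach_TC / n
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) < 4 * se

    def test_empty_stream_no_crash(self):
        pw = resolve_pathways([], threshold=1.0)
        assert pw.attach_fraction_TC() is None


class TestEntropyProduction:
    def test_detailed_balance_produces_nothing(self):
        sigma = markov_entropy_rate(_rates())
        assert abs(sigma) < 1e-10

    def test_three_state_ring_closed_form(self):
        a, b = 2.0, 0.5
        edges = [(1, 2, a, b), (2, 3, a, b), (3, 1, a, b)]
        sigma = entropy_production_rate(edges)
        # uniform ring: J = (a - b)/3 per edge, A = 3 log(a/b)
        assert sigma == pytest.approx((a - b) * np.log(a / b), rel=1e-9)

    def test_one_way_edge_is_divergent(self):
        assert entropy_production_rate([(1, 2, 1.0, 0.0), (2, 1, 0.0, 1.0)],
                                       p=[0.5, 0.5]) == np.inf

    def test_pathway_refinement_raises_entropy(self):
        """Splitting a pooled edge into two opposing channels reveals hidden
        dissipation (data-processing inequality, checked numerically)."""
        p = [0.5, 0.5]
        pooled = entropy_production_rate([(1, 2, 2.5, 2.5)], p=p)
        split = entropy_production_rate([(1, 2, 2.0, 0.5), (1, 2, 0.5, 2.0)],
                                        p=p)
        assert split >= pooled
        assert pooled == pytest.approx(0.0)
        assert split > 0.5

    def test_driven_generator_entropy_positive(self):
        sigma = markov_entropy_rate(_rates(attach_far=0.2))
        assert sigma > 0


class TestSummary:
    def test_summary_renders(self, rng):
        series, _ = make_ctmc_trajectory(_rates(), 2000, 0.05, rng)
        txt = EightStateModel(series, 0.05).fit().summary()
        assert "attach_far" in txt and "p_ss" in txt
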