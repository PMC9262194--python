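"""Likelihood, gradients, masking and the multi-round training loop."""

import numpy as np
import pytest

from hicbg import (
    BinStats,
    ModelParameters,
    TrainingConfig,
    fit_one_round,
    negative_log_likelihood,
    recompute_bin_totals,
    simulate_background,
    train,
)
from hicbg.model import nb_log_pmf
from hicbg.trainer import (
    _Design,
    _nll_and_grad,
    _pack,
    initial_parameters,
    raw_bin_totals,
)


class TestNegativeLogLikelihood:
    def test_hand_summed_oracle(self, toy_map, simple_params):
        s = raw_bin_totals(toy_map)
        stats_ = BinStats.from_totals(s, simple_params)
        got = negative_log_likelihood(toy_map, simple_params, stats_)
        # oracle: sum the NB log pmf terms pair by pair
        from hicbg.model import bias_factor, distance_expectation, soft_maximum

        total = 0.0
        mid = toy_map.bins.midpoint()
        ii, jj = toy_map.idx()
        for n in range(len(toy_map)):
            vi = float(bias_factor(s[ii[n]], simple_params))
            vj = float(bias_factor(s[jj[n]], simple_params))
            if toy_map.bins.chrom[ii[n]] == toy_map.bins.chrom[jj[n]]:
                f = float(distance_expectation(abs(float(mid[jj[n]] - mid[ii[n]])), simple_params))
            else:
                f = simple_params.f_c
            mu = float(soft_maximum(vi * vj * f, simple_params.base_e, simple_params.k))
            total -= float(nb_log_pmf(toy_map.count[n], mu, simple_params.r))
        assert got == pytest.approx(total, rel=1e-12)

    def test_single_term(self, toy_bins, simple_params):
        from hicbg import ContactMap

        cmap = ContactMap(bins=toy_bins, i=[1], j=[2], count=[4], bin_size=10_000)
        s = raw_bin_totals(cmap)
        one = negative_log_likelihood(cmap, simple_params, BinStats.from_totals(s, simple_params))
        assert np.isfinite(one) and one > 0

    def test_additivity_under_duplication(self, toy_bins, simple_params):
        # a second chromosome pair with identical covariates doubles the NLL
        from hicbg import BinTable, ContactMap

        bins = BinTable(
            chrom=np.array(["chr1", "chr1", "chr2", "chr2"], dtype=object),
            start=[0, 10_000, 0, 10_000],
            end=[10_000, 20_000, 10_000, 20_000],
            bin_id=[1, 2, 3, 4],
        )
        single = ContactMap(bins=bins, i=[1], j=[2], count=[4], bin_size=10_000)
        double = ContactMap(bins=bins, i=[1, 3], j=[2, 4], count=[4, 4], bin_size=10_000)
        stats_s = BinStats.from_totals(raw_bin_totals(single), simple_params)
        stats_d = BinStats.from_totals(raw_bin_totals(double), simple_params)
        # use the duplicated map's totals for both so covariates match
        nll_1 = negative_log_likelihood(single, simple_params, stats_d)
        nll_2 = negative_log_likelihood(double, simple_params, stats_d)
        assert nll_2 == pytest.approx(2 * nll_1, rel=1e-12)

    def test_masking_excludes_terms(self, toy_map, simple_params):
        stats_ = BinStats.from_totals(raw_bin_totals(toy_map), simple_params)
        full = negative_log_likelihood(toy_map, simple_params, stats_)
        part = negative_log_likelihood(toy_map, simple_params, stats_, masked={(1, 2)})
        assert part < full


class TestGradients:
    @pytest.mark.parametrize("zero_truncation", [False, True])
    def test_matches_finite_differences(self, background_sim, zero_truncation):
        cmap, _ = background_sim
        design = _Design(cmap)
        s = raw_bin_totals(cmap)
        cfg = TrainingConfig()
        theta = _pack(initial_parameters(design, s, cfg), design)
        _, grad = _nll_and_grad(theta, design, s, cfg.k, cfg.base_e,
                                zero_truncation=zero_truncation)
        eps = 1e-6
        for m in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[m] += eps
            tm[m] -= eps
            hi = _nll_and_grad(tp, design, s, cfg.k, cfg.base_e, zero_truncation=zero_truncation)[0]
            lo = _nll_and_grad(tm, design, s, cfg.k, cfg.base_e, zero_truncation=zero_truncation)[0]
            num = (hi - lo) / (2 * eps)
            assert grad[m] == pytest.approx(num, rel=1e-4, abs=1e-4)


class TestFitOneRound:
    def test_max_iters_zero_returns_input(self, background_sim):
        cmap, _ = background_sim
        p0 = ModelParameters(b=0.9, b_m=-3.0, v_base=0.02, a0=10.0, a1=-0.8, f_c=0.4, r=3.0)
        params, trace, converged = fit_one_round(
            cmap, p0, None, TrainingConfig(max_iters=0)
        )
        assert not converged and len(trace) == 0
        for name in ("b", "b_m", "v_base", "a0", "a1", "a2", "a3", "f_c", "r"):
            assert getattr(params, name) == pytest.approx(getattr(p0, name), rel=1e-9, abs=1e-12)

    def test_refit_from_optimum_is_fixed_point(self, background_sim):
        cmap, _ = background_sim
        cfg = TrainingConfig(seed=0)
        fit = train(cmap, TrainingConfig(rounds=1, seed=0))
        params2, trace, converged = fit_one_round(cmap, fit.params, None, cfg)
        assert converged and len(trace) <= 200
        assert params2.b == pytest.approx(fit.params.b, abs=0.02)
        assert np.log(params2.r) == pytest.approx(np.log(fit.params.r), abs=0.02)

    def test_nll_trace_non_increasing_near_convergence(self, background_sim):
        # ADAM oscillates by a sliver around the optimum; the objective must
        # still be flat-or-falling over the last recorded iterations
        cmap, _ = background_sim
        fit = train(cmap, TrainingConfig(rounds=2, seed=0))
        for trace, conv in zip(fit.loglik_trace, fit.converged):
            nll = -np.asarray(trace)
            last = nll[-10:]
            assert np.all(np.diff(last) <= 1e-5 * np.abs(last[:-1]))
            # and the round made net progress
            assert nll[-1] <= nll[0]


class TestRecomputeBinTotals:
    def test_no_mask_equals_raw_marginals(self, toy_map, simple_params):
        stats_ = BinStats.from_totals(raw_bin_totals(toy_map), simple_params)
        out = recompute_bin_totals(toy_map, None, simple_params, stats_)
        assert np.allclose(out.s, raw_bin_totals(toy_map))

    def test_masked_pair_replaced_by_expectation(self, toy_map, simple_params):
        s0 = raw_bin_totals(toy_map)
        stats_ = BinStats.from_totals(s0, simple_params)
        out = recompute_bin_totals(toy_map, {(1, 2)}, simple_params, stats_)
        # pair (1,2) has x=5; bins 0 and 1 lose 5 and gain mu
        from hicbg.trainer import _Design, _mu_only

        design = _Design(toy_map)
        mu = _mu_only(simple_params, design, s0)
        pos = [n for n in range(len(toy_map)) if (toy_map.i[n], toy_map.j[n]) == (1, 2)][0]
        delta = toy_map.count[pos] - mu[pos]
        assert out.s[0] == pytest.approx(s0[0] - delta)
        assert out.s[1] == pytest.approx(s0[1] - delta)
        assert np.allclose(out.s[2:], s0[2:])

    def test_all_masked_equals_expectation_marginals(self, toy_map, simple_params):
        s0 = raw_bin_totals(toy_map)
        stats_ = BinStats.from_totals(s0, simple_params)
        mask = np.ones(len(toy_map), dtype=bool)
        out = recompute_bin_totals(toy_map, mask, simple_params, stats_)
        from hicbg.trainer import _Design, _mu_only

        design = _Design(toy_map)
        mu = _mu_only(simple_params, design, s0)
        ii, jj = toy_map.idx()
        want = np.zeros(len(toy_map.bins))
        for n in range(len(toy_map)):
            want[ii[n]] += mu[n]
            want[jj[n]] += mu[n]
        assert np.allclose(out.s, want)


class TestTrain:
    def test_rounds_one_equals_single_fit(self, background_sim):
        cmap, _ = background_sim
        cfg = TrainingConfig(rounds=1, seed=0)
        fit = train(cmap, cfg)
        params, trace, converged = fit_one_round(cmap, initial_parameters(
            _Design(cmap), raw_bin_totals(cmap), cfg), None, cfg)
        assert fit.params.b == params.b
        assert fit.params.r == params.r
        assert fit.converged == [converged]

    def test_empty_map_fatal(self, toy_bins):
        from hicbg import ContactMap

        empty = ContactMap(bins=toy_bins, i=[], j=[], count=[], bin_size=10_000)
        with pytest.raises(ValueError):
            train(empty, TrainingConfig())

    def test_masking_monotone_under_spiked_signal(self, background_sim):
        from hicbg import sample_loop_pairs, spike_loops

        cmap, truth = background_sim
        fit_bg = train(cmap, TrainingConfig(seed=0))
        loops = sample_loop_pairs(truth, 10, fold=12.0, min_mu=1.0, seed=7)
        spiked = spike_loops(cmap, loops, truth, seed=8)
        fit_sp = train(spiked, TrainingConfig(seed=0))
        assert int(fit_sp.masked.sum()) >= int(fit_bg.masked.sum())

    def test_parameter_recovery_smoke(self, background_sim):
        # coarse bounds at small n; the full-scale recovery experiment is
        # exercised by the acceptance suite
        cmap, truth = background_sim
        fit = train(cmap, TrainingConfig(rounds=1, seed=0))
        assert fit.params.b == pytest.approx(truth.params.b, abs=0.15)
        assert np.log(fit.params.r) == pytest.approx(np.log(truth.params.r), abs=0.35)

    def test_minibatch_mode_runs(self, background_sim):
        cmap, _ = background_sim
        cfg = TrainingConfig(rounds=1, seed=3, batch_size=1000, max_iters=150)
        fit = train(cmap, cfg)
        assert np.isfinite(fit.params.r) and fit.params.r > 0
        assert np.all(np.isfinite(fit.pvalues))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(rounds=0)
        with pytest.raises(ValueError):
            TrainingConfig(sig_threshold=1.5)
        with pytest.raises(ValueError):
            TrainingConfig(tol=0.0)
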