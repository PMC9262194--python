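"""Validation experiments run by the test suite and the acceptance script.

Each function builds its own inputs with the simulator (or closed-form
grids), runs the package's public machinery and returns plain numbers, so
the same experiment backs both a pytest assertion and a reported metric.
"""

from __future__ import annotations

import numpy as np

from .enrichment import fisher_pvalue
from .model import distance_expectation, nb_log_pmf, pvalue, soft_maximum
from .simulate import sample_loop_pairs, simulate_background, spike_loops
from .trainer import TrainingConfig, train

__all__ = [
    "nb_tail_oracle_error",
    "soft_maximum_bound_excess",
    "null_calibration",
    "parameter_recovery",
    "spiked_loop_detection",
    "capture_degeneracy",
    "fisher_oracle_error",
]


def nb_tail_oracle_error(max_x: int = 200) -> float:
    """Max |survival - brute-force pmf summation| over a 3x3x200 grid."""
    xs = np.arange(1, max_x + 1)
    worst = 0.0
    for mu in (0.1, 1.0, 10.0):
        for r in (0.5, 2.0, 50.0):
            grid = np.arange(0, 5000)
            pmf = np.exp(nb_log_pmf(grid, mu, r))
            tail = pmf[::-1].cumsum()[::-1]
            got = pvalue(xs, mu, r)
            worst = max(worst, float(np.max(np.abs(got - tail[xs]))))
    return worst


def soft_maximum_bound_excess() -> tuple[float, float]:
    """(max bound violation, max error at alpha == beta) over a grid.

    The bound: |softmax(a, b, k) - max(a, b)| <= |a - b| e^{-k|a-b|}.
    """
    alphas = np.linspace(-20, 20, 81)
    betas = np.linspace(-20, 20, 79)
    worst = 0.0
    for k in (0.5, 1.0, 10.0, 100.0):
        a = alphas[:, None]
        b = betas[None, :]
        tau = soft_maximum(a, b, k)
        gap = np.abs(a - b)
        excess = np.abs(tau - np.maximum(a, b)) - gap * np.exp(-k * gap)
        worst = max(worst, float(excess.max()))
    eq = float(np.max(np.abs(soft_maximum(alphas, alphas, 10.0) - alphas)))
    return worst, eq


def null_calibration(seed: int = 1, n_bins: int = 500, bin_size: int = 10_000,
                     threshold: float = 0.001):
    """Fraction of pairs called at p < threshold on pure background.

    Returns (fraction, n_pairs, three-binomial-SE half width).
    """
    cmap, _ = simulate_background(n_bins=n_bins, bin_size=bin_size, seed=seed)
    fit = train(cmap, TrainingConfig(rounds=4, sig_threshold=threshold, seed=0))
    n = len(cmap)
    frac = float(fit.masked.mean())
    half = 3.0 * float(np.sqrt(threshold * (1 - threshold) / n))
    return frac, n, half


def parameter_recovery(seeds=range(1, 11), n_bins: int = 625, bin_size: int = 16_000):
    """Single-round fit on self-consistent backgrounds across seeds.

    Returns a dict of per-seed absolute errors of the bias exponent, the
    log dispersion, and the worst relative error of the recovered decay
    curve (expected-count scale at the median bias) over 20 kb - 10 Mb,
    plus the total number of simulated pairs per replicate.
    """
    b_errs, lnr_errs, dec_errs, n_pairs = [], [], [], 0
    for seed in seeds:
        cmap, truth = simulate_background(n_bins=n_bins, bin_size=bin_size, seed=seed)
        fit = train(cmap, TrainingConfig(rounds=1, seed=0))
        p, tp = fit.params, truth.params
        b_errs.append(abs(p.b - tp.b))
        lnr_errs.append(abs(float(np.log(p.r / tp.r))))
        d_hi = (n_bins - 1) * bin_size
        d = np.geomspace(2e4, d_hi, 30)
        med_t = float(np.median(truth.v))
        med_h = float(np.median(fit.bin_stats.v))
        mu_t = soft_maximum(med_t**2 * distance_expectation(d, tp), tp.base_e, tp.k)
        mu_h = soft_maximum(med_h**2 * distance_expectation(d, p), p.base_e, p.k)
        dec_errs.append(float(np.max(np.abs(mu_h / mu_t - 1.0))))
        n_pairs = n_bins * (n_bins - 1) // 2
    return {
        "b_errors": b_errs,
        "ln_r_errors": lnr_errs,
        "decay_errors": dec_errs,
        "n_pairs": n_pairs,
    }


def spiked_loop_detection(seed: int = 1, n_loops: int = 50, fold: float = 10.0,
                          threshold: float = 0.001, min_mu: float = 10.0):
    """Sensitivity and specificity for loops spiked at fold x background.

    Loops are placed on cis pairs whose background mean is at least
    ``min_mu`` reads (default 10; detection power at weaker sites is
    limited by counting noise, not by the model). Returns (sensitivity,
    fraction of non-loop pairs called, n_loops, n_nonloop).
    """
    cmap, truth = simulate_background(n_bins=500, bin_size=10_000, seed=seed)
    loops = sample_loop_pairs(truth, n_loops, fold=fold, min_mu=min_mu, seed=seed + 1000)
    spiked = spike_loops(cmap, loops, truth, seed=seed + 2000)
    fit = train(spiked, TrainingConfig(rounds=4, sig_threshold=threshold, seed=0))
    loop_set = {(a, b) for a, b, _ in loops}
    is_loop = np.fromiter(
        ((int(a), int(b)) in loop_set for a, b in zip(spiked.i, spiked.j)),
        dtype=bool, count=len(spiked),
    )
    called = fit.pvalues < threshold
    sens = float(called[is_loop].sum()) / n_loops
    nonloop_frac = float(called[~is_loop].mean())
    return sens, nonloop_frac, n_loops, int((~is_loop).sum())


def capture_degeneracy(seed: int = 42, n_bins: int = 120):
    """All-bait capture vs the general model: max |p difference|.

    Also verifies the TT-conversion is the identity on TT pairs and linear
    in the count; returns (max abs p-value difference, max conversion
    deviation, n_pairs).
    """
    import pandas as pd

    from .capture import convert_count_to_TT, train_capture

    cmap, _ = simulate_background(n_bins=n_bins, bin_size=10_000, seed=seed)
    baits = pd.DataFrame(
        [(c, 0, int(cmap.bins.end.max())) for c in np.unique(cmap.bins.chrom.astype(str))],
        columns=["chrom", "start", "end"],
    )
    cfg = TrainingConfig(rounds=2, seed=0)
    general = train(cmap, cfg)
    capture = train_capture(cmap, baits, cfg)
    p_diff = float(np.max(np.abs(capture.pvalues - general.pvalues)))

    conv_dev = 0.0
    for n in range(0, len(cmap), max(1, len(cmap) // 20)):
        x = int(cmap.count[n])
        one = convert_count_to_TT(x, cmap.i[n], cmap.j[n], capture, cmap.bins)
        conv_dev = max(conv_dev, abs(one - x))  # identity on TT
        five = convert_count_to_TT(5 * x, cmap.i[n], cmap.j[n], capture, cmap.bins)
        conv_dev = max(conv_dev, abs(five - 5 * one))  # linear in x
    return p_diff, conv_dev, len(cmap)


def fisher_oracle_error(max_total: int = 50) -> float:
    """Max |Fisher P - exact hypergeometric enumeration| over all 2x2
    tables with total <= max_total.

    The oracle enumerates the hypergeometric pmf directly through
    log-gamma arithmetic (not through the same code path as the test
    statistic) and sums the outcomes no more probable than the observed
    table.
    """
    from scipy.special import gammaln

    lg = gammaln(np.arange(0, max_total + 2) + 1.0)  # ln k!

    def log_choose(n, k):
        return lg[n] - lg[k] - lg[n - k]

    def canonical(a, b, c, d):
        # row swap, column swap and transpose leave the two-sided P unchanged
        forms = [
            (a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
            (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
        ]
        return min(forms)

    worst = 0.0
    seen: set = set()
    for total in range(1, max_total + 1):
        for a in range(total + 1):
            for b in range(total + 1 - a):
                for c in range(total + 1 - a - b):
                    d = total - a - b - c
                    key = canonical(a, b, c, d)
                    if key in seen:
                        continue
                    seen.add(key)
                    row1, col1 = a + b, a + c
                    lo = max(0, row1 + col1 - total)
                    hi = min(row1, col1)
                    ks = np.arange(lo, hi + 1)
                    log_pmf = (
                        log_choose(col1, ks)
                        + log_choose(total - col1, row1 - ks)
                        - log_choose(total, row1)
                    )
                    pmf = np.exp(log_pmf)
                    p_obs = pmf[a - lo]
                    oracle = float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())
                    got = fisher_pvalue((a, b, c, d))
                    worst = max(worst, abs(got - min(oracle, 1.0)))
    return worst
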