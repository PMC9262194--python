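"""Maximum-likelihood fitting of the background model.

The negative log-likelihood of all stored (unmasked) pairs under the NB
background is minimised with ADAM using analytic gradients (digamma terms
for the dispersion). All strictly positive parameters (v_base, f_c, r) are
optimised on the log scale so positivity is structural. Training proceeds
in rounds: fit, score every pair, mask pairs below the significance
threshold, and replace the masked pairs' observed counts by their model
expectations when recomputing per-bin totals — so putative real
interactions stop inflating the background for the next round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .contact_io import ContactMap
from .model import BinStats, ModelParameters, _EXP_CLIP, bias_factor

__all__ = [
    "TrainingConfig",
    "FitResult",
    "FitDivergenceError",
    "negative_log_likelihood",
    "fit_one_round",
    "recompute_bin_totals",
    "train",
]

logger = logging.getLogger(__name__)

# optimisation order of the free parameters (log scale where positive)
_PARAM_NAMES = ("b", "b_m", "ln_v_base", "a0", "a1", "a2", "a3", "ln_f_c", "ln_r")


class FitDivergenceError(RuntimeError):
    """Raised when the NLL increases for many consecutive iterations."""


@dataclass
class TrainingConfig:
    rounds: int = 4
    sig_threshold: float = 0.001
    tol: float = 1e-4
    max_iters: int = 1000
    learning_rate: float = 1e-2
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    device_cores: int = 1
    # model hyperparameters (fixed, not fitted)
    k: float = 10.0
    base_e: float = 0.5
    # switches
    freeze_v_base: bool = False
    use_trans: bool = True
    batch_size: int | None = None  # None = full-batch (deterministic)
    inclusive_pvalue: bool = True
    # condition the likelihood and P-values on a pair being observed
    # (x >= 1): the triplet store never contains zero-count pairs, and the
    # unconditional NB fitted to zero-truncated counts is inconsistent
    zero_truncation: bool = True

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0 < self.sig_threshold < 1:
            raise ValueError("sig_threshold must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FitResult:
    params: ModelParameters
    bin_stats: BinStats
    masked: np.ndarray  # bool per stored pair, final round's mask
    loglik_trace: list  # one array of per-iteration log-likelihoods per round
    converged: list  # bool per round
    mu: np.ndarray | None = None  # final expected counts per stored pair
    pvalues: np.ndarray | None = None  # final tail probabilities per stored pair

    @property
    def masked_pairs(self) -> set:
        return set(map(tuple, self._pair_ids[self.masked])) if len(self.masked) else set()

    _pair_ids: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# design: cached per-map arrays
# ---------------------------------------------------------------------------

class _Design:
    """Precomputed per-pair arrays for one contact map.

    The decay cubic is optimised on a centred and scaled log-distance
    variable t = (ln d - d_center) / d_scale; the raw powers of ln d are
    nearly collinear over a genomic distance range and would cripple a
    diagonal optimiser. Public parameters stay in the plain ln d basis.
    """

    def __init__(self, cmap: ContactMap, use_trans: bool = True):
        ii, jj = cmap.idx()
        d = cmap.distances()
        trans = ~np.isfinite(d)
        keep = np.ones(len(d), dtype=bool)
        if not use_trans:
            keep = ~trans
        self.sel = keep  # selection into the map's triplet store
        self.ii = ii[keep]
        self.jj = jj[keep]
        self.x = cmap.count[keep].astype(float)
        self.trans = trans[keep]
        self.cis = ~self.trans
        self.n_bins = len(cmap.bins)
        ln_d = np.zeros(len(self.x))
        ln_d[self.cis] = np.log(d[keep][self.cis])
        self.ln_d = ln_d
        if self.cis.sum() >= 2:
            self.d_center = float(np.mean(ln_d[self.cis]))
            self.d_scale = float(max(np.std(ln_d[self.cis]), 1e-6))
        else:
            self.d_center, self.d_scale = 0.0, 1.0
        self.t = np.where(self.cis, (ln_d - self.d_center) / self.d_scale, 0.0)
        # unique observed counts: lgamma/digamma are evaluated on the unique
        # values only, which makes the per-iteration cost independent of N
        self.xu, self.x_inv = np.unique(self.x, return_inverse=True)
        self.gl_x1 = special.gammaln(self.xu + 1.0)

    def subset(self, mask: np.ndarray) -> "_DesignView":
        return _DesignView(self, mask)


class _DesignView:
    """A design restricted to the pairs where ``mask`` is True."""

    def __init__(self, design: _Design, mask: np.ndarray):
        self.ii = design.ii[mask]
        self.jj = design.jj[mask]
        self.x = design.x[mask]
        self.trans = design.trans[mask]
        self.cis = ~self.trans
        self.ln_d = design.ln_d[mask]
        self.d_center = design.d_center
        self.d_scale = design.d_scale
        self.t = design.t[mask]
        self.n_bins = design.n_bins
        self.xu, self.x_inv = np.unique(self.x, return_inverse=True)
        self.gl_x1 = special.gammaln(self.xu + 1.0)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _binom(n: int, k: int) -> float:
    from math import comb

    return float(comb(n, k))


def _a_to_scaled(a: np.ndarray, center: float, scale: float) -> np.ndarray:
    """Coefficients of the cubic in t = (L - center)/scale given those in L."""
    c = np.zeros(4)
    for k in range(4):
        for n in range(k, 4):
            c[k] += a[n] * _binom(n, k) * center ** (n - k) * scale**k
    return c


def _scaled_to_a(c: np.ndarray, center: float, scale: float) -> np.ndarray:
    """Inverse of :func:`_a_to_scaled`."""
    a = np.zeros(4)
    for k in range(4):
        for n in range(k, 4):
            a[k] += c[n] * scale ** (-n) * _binom(n, k) * (-center) ** (n - k)
    return a


def _pack(params: ModelParameters, design=None, s_center: float = 0.0) -> np.ndarray:
    center = getattr(design, "d_center", 0.0)
    scale = getattr(design, "d_scale", 1.0)
    c = _a_to_scaled(params.a, center, scale)
    return np.array(
        [
            params.b,
            params.b_m + params.b * s_center,
            np.log(params.v_base),
            c[0],
            c[1],
            c[2],
            c[3],
            np.log(params.f_c),
            np.log(params.r),
        ]
    )


def _unpack(theta: np.ndarray, template: ModelParameters, design=None,
            s_center: float = 0.0) -> ModelParameters:
    center = getattr(design, "d_center", 0.0)
    scale = getattr(design, "d_scale", 1.0)
    a = _scaled_to_a(theta[3:7], center, scale)
    return template.copy(
        b=float(theta[0]),
        b_m=float(theta[1] - theta[0] * s_center),
        v_base=float(np.exp(theta[2])),
        a0=float(a[0]),
        a1=float(a[1]),
        a2=float(a[2]),
        a3=float(a[3]),
        f_c=float(np.exp(theta[7])),
        r=float(np.exp(theta[8])),
    )


# ---------------------------------------------------------------------------
# likelihood and analytic gradient
# ---------------------------------------------------------------------------

def _bias_terms(theta: np.ndarray, s: np.ndarray, s_center: float = 0.0):
    """Per-bin bias v plus the pieces needed for its gradient.

    ``s_center`` shifts ln s so the exponent and offset are decorrelated
    during optimisation; theta[1] is the offset in the centred basis.
    """
    b, b_m = theta[0], theta[1]
    v_base = np.exp(theta[2])
    pos = s > 0
    ln_s = np.where(pos, np.log(np.where(pos, s, 1.0)) - s_center, 0.0)
    expo = np.clip(b * ln_s + b_m, -_EXP_CLIP, _EXP_CLIP)
    u = np.where(pos, np.exp(expo), 0.0)
    v = np.maximum(u, v_base)
    active = u > v_base  # floor inactive: gradient flows through the power law
    return v, u, ln_s, active, v_base


def _mu_terms(theta: np.ndarray, design, s: np.ndarray, k: float, base_e: float,
              s_center: float = 0.0):
    """Expected counts plus every intermediate the gradient needs."""
    c0, c1, c2, c3 = theta[3], theta[4], theta[5], theta[6]
    f_c = np.exp(theta[7])
    v, u, ln_s, active, v_base = _bias_terms(theta, s, s_center)
    vi = v[design.ii]
    vj = v[design.jj]

    L = design.t  # centred/scaled log distance
    poly = ((c3 * L + c2) * L + c1) * L + c0
    clipped = np.abs(poly) >= _EXP_CLIP
    f_v = np.exp(np.clip(poly, -_EXP_CLIP, _EXP_CLIP))

    diff = k * (f_v - f_c)
    w_fv = special.expit(diff)
    w_fc = 1.0 - w_fv
    gap = f_v - f_c
    f = np.where(design.cis, w_fv * f_v + w_fc * f_c, f_c)
    df_dfv = np.where(design.cis & ~clipped, w_fv * (1.0 + k * w_fc * gap), 0.0)
    df_dfc = np.where(design.cis, w_fc * (1.0 - k * w_fv * gap), 1.0)

    z = vi * vj * f
    zdiff = k * (z - base_e)
    w_z = special.expit(zdiff)
    w_b = 1.0 - w_z
    mu = w_z * z + w_b * base_e
    dmu_dz = w_z * (1.0 + k * w_b * (z - base_e))
    return {
        "mu": mu, "z": z, "dmu_dz": dmu_dz, "f": f, "f_v": f_v,
        "df_dfv": df_dfv, "df_dfc": df_dfc, "f_c": f_c,
        "v": v, "vi": vi, "vj": vj, "u": u, "ln_s": ln_s,
        "active": active, "v_base": v_base, "L": L,
    }


def _nll_and_grad(theta: np.ndarray, design, s: np.ndarray, k: float, base_e: float,
                  zero_truncation: bool = False, s_center: float = 0.0):
    t = _mu_terms(theta, design, s, k, base_e, s_center)
    mu = t["mu"]
    x = design.x
    r = np.exp(theta[8])
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        bad = int(np.flatnonzero(~np.isfinite(mu) | (mu <= 0))[0])
        raise FloatingPointError(
            f"non-finite expected count for pair ({design.ii[bad]}, {design.jj[bad]})"
        )

    log_rm = np.log(r + mu)
    gl_xr = special.gammaln(design.xu + r)[design.x_inv]
    ll = (
        gl_xr
        - special.gammaln(r)
        - design.gl_x1[design.x_inv]
        + r * (np.log(r) - log_rm)
        + x * (np.log(mu) - log_rm)
    )
    nll = -float(np.sum(ll))
    if not np.isfinite(nll):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(
            f"non-finite likelihood term for pair ({design.ii[bad]}, {design.jj[bad]})"
        )

    # dl/dmu, chained through the soft maximum
    dl_dmu = x / mu - (x + r) / (r + mu)
    trunc_r = 0.0
    if zero_truncation:
        # condition on x >= 1: l -= log(1 - P0), P0 = (r/(r+mu))^r
        p0 = np.minimum(np.exp(r * (np.log(r) - log_rm)), 1.0 - 1e-12)
        log1m = np.log1p(-p0)
        nll += float(np.sum(log1m))
        dl_dmu = dl_dmu - p0 * r / ((r + mu) * (1.0 - p0))
        g_r = np.log(r) - log_rm + mu / (r + mu)  # d ln P0 / dr
        trunc_r = r * p0 * g_r / (1.0 - p0)
    g = dl_dmu * t["dmu_dz"]  # dl/dz per pair

    grad = np.zeros(len(theta))
    # decay coefficients (cis pairs only; clipped exponents contribute 0)
    base = g * t["vi"] * t["vj"] * t["df_dfv"] * t["f_v"]
    L = t["L"]
    grad[3] = np.sum(base)
    grad[4] = np.sum(base * L)
    grad[5] = np.sum(base * L * L)
    grad[6] = np.sum(base * L * L * L)
    # ln f_c (cis via soft max weight, trans directly)
    grad[7] = np.sum(g * t["vi"] * t["vj"] * t["df_dfc"]) * t["f_c"]
    # bias parameters: accumulate dl/dv per bin then chain through v(s)
    c_i = g * t["f"] * t["vj"]
    c_j = g * t["f"] * t["vi"]
    G = np.bincount(design.ii, weights=c_i, minlength=design.n_bins) + np.bincount(
        design.jj, weights=c_j, minlength=design.n_bins
    )
    act = t["active"]
    grad[0] = np.sum(G[act] * t["u"][act] * t["ln_s"][act])
    grad[1] = np.sum(G[act] * t["u"][act])
    grad[2] = np.sum(G[~act]) * t["v_base"]
    # ln r
    dg_xr = special.digamma(design.xu + r)[design.x_inv]
    dl_dlnr = r * (
        dg_xr - special.digamma(r) + np.log(r) + 1.0 - log_rm - (x + r) / (r + mu)
    ) + trunc_r
    grad[8] = np.sum(dl_dlnr)

    return nll, -grad


def _mu_only(params: ModelParameters, design, s: np.ndarray) -> np.ndarray:
    t = _mu_terms(_pack(params, design), design, s, params.k, params.base_e)
    return t["mu"]


def _pvalues_for(params: ModelParameters, design, s: np.ndarray, inclusive: bool = True,
                 zero_truncation: bool = False):
    mu = _mu_only(params, design, s)
    p = params.r / (params.r + mu)
    shift = 1.0 if inclusive else 0.0
    pv = stats.nbinom.sf(design.x - shift, params.r, p)
    if zero_truncation:
        # tail of the count conditional on the pair being observed
        pv = pv / np.maximum(1.0 - p**params.r, 1e-300)
    return np.clip(pv, np.finfo(float).tiny, 1.0), mu


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _as_mask(cmap: ContactMap, masked) -> np.ndarray:
    """Accept a boolean per-triplet array or a set of (i, j) bin-id pairs."""
    if masked is None:
        return np.zeros(len(cmap), dtype=bool)
    is_pair_collection = isinstance(masked, (set, frozenset, list)) and (
        len(masked) == 0 or isinstance(next(iter(masked)), tuple)
    )
    if not is_pair_collection:
        arr = np.asarray(masked, dtype=bool)
        if arr.shape != (len(cmap),):
            raise ValueError("boolean mask must align with the triplet store")
        return arr
    pairs = {(min(a, b), max(a, b)) for a, b in masked}
    return np.fromiter(
        ((int(a), int(b)) in pairs for a, b in zip(cmap.i, cmap.j)),
        dtype=bool,
        count=len(cmap),
    )


def negative_log_likelihood(
    cmap: ContactMap,
    params: ModelParameters,
    bin_stats: BinStats,
    masked=None,
    use_trans: bool = True,
    zero_truncation: bool = False,
) -> float:
    """-sum of NB log pmf over unmasked stored pairs (trans pairs use f_c).

    With ``zero_truncation`` each term is conditioned on the pair being
    observed (x >= 1), the form the trainer uses by default.
    """
    design = _Design(cmap, use_trans=use_trans)
    mask = _as_mask(cmap, masked)[design.sel]
    view = design.subset(~mask)
    nll, _ = _nll_and_grad(
        _pack(params, view), view, bin_stats.s, params.k, params.base_e,
        zero_truncation=zero_truncation,
    )
    return nll


def fit_one_round(
    cmap_or_design,
    params0: ModelParameters,
    masked,
    config: TrainingConfig,
    bin_totals: np.ndarray | None = None,
):
    """One ADAM fit of all free parameters on the unmasked pairs.

    Stops when every parameter's absolute change (on its optimisation
    scale) since the previous iteration is below ``config.tol``, or at
    ``config.max_iters`` to handle oscillation around the optimum. Raises
    :class:`FitDivergenceError` if the NLL increases 50 iterations in a row.
    """
    if isinstance(cmap_or_design, ContactMap):
        design = _Design(cmap_or_design, use_trans=config.use_trans)
        mask = _as_mask(cmap_or_design, masked)[design.sel]
        if bin_totals is None:
            bin_totals = raw_bin_totals(cmap_or_design)
    else:
        design = cmap_or_design
        mask = np.zeros(len(design.x), dtype=bool) if masked is None else np.asarray(masked, bool)
        if bin_totals is None:
            raise ValueError("bin_totals required when passing a design")
    view = design.subset(~mask) if mask.any() else design

    pos = bin_totals > 0
    s_center = float(np.mean(np.log(bin_totals[pos]))) if pos.any() else 0.0
    theta = _pack(params0, view, s_center)
    free = np.ones(len(theta), dtype=bool)
    if config.freeze_v_base:
        free[2] = False

    rng = np.random.default_rng(config.seed)
    m = np.zeros_like(theta)
    vmom = np.zeros_like(theta)
    trace = []
    converged = False
    rising = 0
    last_nll = np.inf
    n_total = len(view.x)

    for it in range(1, config.max_iters + 1):
        if config.batch_size is not None and config.batch_size < n_total:
            idx = rng.choice(n_total, size=config.batch_size, replace=False)
            batch = _DesignView(view, np.isin(np.arange(n_total), idx))
            nll, grad = _nll_and_grad(
                theta, batch, bin_totals, config.k, config.base_e,
                zero_truncation=config.zero_truncation, s_center=s_center,
            )
            nll *= n_total / config.batch_size
            grad *= n_total / config.batch_size
        else:
            nll, grad = _nll_and_grad(
                theta, view, bin_totals, config.k, config.base_e,
                zero_truncation=config.zero_truncation, s_center=s_center,
            )
        trace.append(nll)
        if nll > last_nll + 1e-9:
            rising += 1
            if rising >= 50:
                raise FitDivergenceError(
                    f"NLL increased for 50 consecutive iterations (iter {it}, NLL {nll:.6g})"
                )
        else:
            rising = 0
        last_nll = nll

        grad = np.where(free, grad, 0.0)
        m = config.adam_beta1 * m + (1 - config.adam_beta1) * grad
        vmom = config.adam_beta2 * vmom + (1 - config.adam_beta2) * grad * grad
        m_hat = m / (1 - config.adam_beta1**it)
        v_hat = vmom / (1 - config.adam_beta2**it)
        step = config.learning_rate * m_hat / (np.sqrt(v_hat) + config.adam_eps)
        theta = theta - np.where(free, step, 0.0)
        if np.max(np.abs(np.where(free, step, 0.0))) < config.tol:
            converged = True
            break

    return _unpack(theta, params0, view, s_center), np.array(trace), converged


def raw_bin_totals(cmap: ContactMap) -> np.ndarray:
    """Marginal read count per bin (both ends of every stored pair)."""
    ii, jj = cmap.idx()
    n = len(cmap.bins)
    return np.bincount(ii, weights=cmap.count, minlength=n) + np.bincount(
        jj, weights=cmap.count, minlength=n
    )


def recompute_bin_totals(
    cmap: ContactMap,
    masked,
    params: ModelParameters,
    bin_stats: BinStats,
    use_trans: bool = True,
) -> BinStats:
    """Effective totals with masked pairs replaced by their expectations.

    s_i = sum of observed counts over unmasked pairs touching i plus the
    model-expected counts over masked pairs touching i — the read count the
    bin would have shown had its significant interactions been background.
    """
    design = _Design(cmap, use_trans=use_trans)
    mask = _as_mask(cmap, masked)[design.sel]
    mu = _mu_only(params, design, bin_stats.s)
    contrib = np.where(mask, mu, design.x)
    n = design.n_bins
    s = np.bincount(design.ii, weights=contrib, minlength=n) + np.bincount(
        design.jj, weights=contrib, minlength=n
    )
    if not use_trans:
        # trans reads still count toward raw coverage when excluded from the fit
        trans_sel = ~design.sel
        ii, jj = cmap.idx()
        s += np.bincount(ii[trans_sel], weights=cmap.count[trans_sel], minlength=n)
        s += np.bincount(jj[trans_sel], weights=cmap.count[trans_sel], minlength=n)
    return BinStats.from_totals(s, params)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def _distance_strata(ln_d: np.ndarray, n_strata: int = 30):
    lo, hi = ln_d.min(), ln_d.max()
    if hi <= lo:
        return np.zeros(len(ln_d), dtype=int), np.array([lo])
    edges = np.linspace(lo, hi, n_strata + 1)
    which = np.clip(np.searchsorted(edges, ln_d, side="right") - 1, 0, n_strata - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return which, centers


def initial_parameters(design: _Design, s: np.ndarray, config: TrainingConfig) -> ModelParameters:
    """Data-driven starting point for the optimiser.

    b starts at 1 with b_m centring the median bias at 1; the decay cubic
    comes from OLS on distance-stratified mean normalised counts; f_c from
    the trans mean (or the farthest cis decile without trans); r from
    method-of-moments on distance-stratified variances.
    """
    pos = s > 0
    ln_s = np.log(s[pos])
    b = 1.0
    b_m = -float(np.median(ln_s))
    u = np.exp(np.log(np.where(pos, s, 1.0)) * b + b_m)
    v_base = max(float(np.percentile(u[pos], 1)), 1e-8)

    v = np.maximum(np.where(pos, u, 0.0), v_base)
    vi = v[design.ii]
    vj = v[design.jj]
    norm = design.x / (vi * vj)

    cis = design.cis
    a = np.array([0.0, 0.0, 0.0, 0.0])
    if cis.sum() >= 10:
        which, centers = _distance_strata(design.ln_d[cis])
        sums = np.bincount(which, weights=norm[cis], minlength=len(centers))
        cnts = np.bincount(which, minlength=len(centers))
        ok = cnts > 0
        means = np.where(ok, sums / np.maximum(cnts, 1), np.nan)
        good = ok & (means > 0)
        if good.sum() >= 4:
            coef = np.polyfit(centers[good], np.log(means[good]), 3)
            a = coef[::-1]  # polyfit is highest power first
        else:
            a = np.array([float(np.log(max(norm[cis].mean(), 1e-6))), 0.0, 0.0, 0.0])

    if design.trans.any():
        f_c = float(np.mean(norm[design.trans]))
    elif cis.sum():
        far = design.ln_d >= np.quantile(design.ln_d[cis], 0.9)
        f_c = float(np.mean(norm[cis & far]))
    else:
        f_c = 1.0
    f_c = max(f_c, 1e-4)

    r = 2.0
    if cis.sum() >= 10:
        which, centers = _distance_strata(design.ln_d[cis])
        xs = design.x[cis]
        cnts = np.bincount(which, minlength=len(centers))
        sums = np.bincount(which, weights=xs, minlength=len(centers))
        sq = np.bincount(which, weights=xs * xs, minlength=len(centers))
        ok = cnts > 4
        mean = sums[ok] / cnts[ok]
        var = sq[ok] / cnts[ok] - mean**2
        over = var > mean * 1.001
        if over.any():
            r_hat = mean[over] ** 2 / (var[over] - mean[over])
            r = float(np.clip(np.median(r_hat), 0.05, 1e4))

    return ModelParameters(
        b=b, b_m=b_m, v_base=v_base,
        a0=float(a[0]), a1=float(a[1]), a2=float(a[2]), a3=float(a[3]),
        f_c=f_c, r=r, k=config.k, base_e=config.base_e,
    )


# ---------------------------------------------------------------------------
# multi-round training
# ---------------------------------------------------------------------------

def train(cmap: ContactMap, config: TrainingConfig | None = None) -> FitResult:
    """Fit the background model in rounds with significant-pair masking.

    Each round fits on the currently unmasked pairs, scores every stored
    pair, re-derives the mask from scratch as {p < sig_threshold}, and
    recomputes effective bin totals with masked counts replaced by their
    expectations. The returned model is the last round's parameters together
    with the bin totals that round was fitted on.
    """
    if config is None:
        config = TrainingConfig()
    if len(cmap) == 0:
        raise ValueError("cannot train on an empty contact map")
    design = _Design(cmap, use_trans=config.use_trans)
    s = raw_bin_totals(cmap)
    params = initial_parameters(design, s, config)

    mask = np.zeros(len(design.x), dtype=bool)
    traces: list[np.ndarray] = []
    converged: list[bool] = []
    prev_mask = mask
    s_used = s
    pv = mu = None

    for rnd in range(1, config.rounds + 1):
        s_used = s
        params, trace, conv = fit_one_round(design, params, mask, config, bin_totals=s)
        traces.append(trace)
        converged.append(conv)
        pv, mu = _pvalues_for(
            params, design, s,
            inclusive=config.inclusive_pvalue,
            zero_truncation=config.zero_truncation,
        )
        prev_mask = mask
        mask = pv < config.sig_threshold
        logger.info(
            "round %d: NLL %.6g, %d/%d pairs masked, converged=%s",
            rnd, trace[-1], int(mask.sum()), len(mask), conv,
        )
        logger.debug("round %d parameters: %s", rnd, params.to_dict())
        contrib = np.where(mask, mu, design.x)
        s = np.bincount(design.ii, weights=contrib, minlength=design.n_bins) + np.bincount(
            design.jj, weights=contrib, minlength=design.n_bins
        )

    changed = int(np.sum(mask != prev_mask))
    if len(mask) and changed > 0.01 * len(mask):
        logger.warning(
            "masked set still changing between the last two rounds (%d pairs, %.2f%%); "
            "consider more rounds", changed, 100 * changed / len(mask),
        )

    full_mask = np.zeros(len(cmap), dtype=bool)
    full_mask[design.sel] = mask
    full_pv = np.full(len(cmap), np.nan)
    full_pv[design.sel] = pv
    full_mu = np.full(len(cmap), np.nan)
    full_mu[design.sel] = mu
    result = FitResult(
        params=params,
        bin_stats=BinStats.from_totals(s_used, params),
        masked=full_mask,
        loglik_trace=[-t for t in traces],
        converged=converged,
        mu=full_mu,
        pvalues=full_pv,
    )
    result._pair_ids = np.column_stack([cmap.i, cmap.j])
    return result
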