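"""Closed-form pieces of the negative-binomial background model.

The read count of a bin pair (i, j) is modelled as

    x_ij ~ NB(mu_ij, r)        (mean mu, variance mu + mu^2/r)

with

    mu_ij = softmax(v_i * v_j * f(d_ij), base_e)

where ``v_i`` is a per-bin bias factor, ``f(d)`` is the expected read count
of a random background ligation at genomic distance ``d`` and ``softmax`` is
a smooth surrogate for the two-argument maximum so the expectation stays
differentiable for gradient-based fitting.

The bias factor is a power law in the bin's effective total read count
``s_i`` with a hard floor::

    v_i = maximum(s_i**b * exp(b_m), v_base)

and the distance term is a cubic in log distance with a constant
background-ligation floor ``f_c``::

    f(d) = softmax(exp(a3*ln(d)^3 + a2*ln(d)^2 + a1*ln(d) + a0), f_c)

Trans pairs have no genomic distance; their expectation uses ``f_c``
directly, the same constant observed for distant cis pairs.

Everything in this module is a pure, vectorised function of its arguments;
the trainer owns parameter estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

__all__ = [
    "ModelParameters",
    "BinStats",
    "InteractionRecord",
    "soft_maximum",
    "soft_maximum_grad",
    "bias_factor",
    "distance_expectation",
    "expected_count",
    "nb_log_pmf",
    "pvalue",
]

# exponent clip keeps exp() finite while the optimizer explores; the bound
# (e^40 ~ 2.4e17 reads) is far outside any physical count scale
_EXP_CLIP = 40.0


@dataclass
class ModelParameters:
    """All scalars of the background model.

    ``b``, ``b_m`` and ``v_base`` shape the bias factor; ``a0..a3`` are the
    cubic log-distance decay coefficients; ``f_c`` is the constant
    background-ligation expectation (reads); ``r`` the shared NB dispersion.
    ``k`` (soft-maximum sharpness) and ``base_e`` (expected-count floor,
    reads) are fixed smoothing hyperparameters, not fitted.
    """

    b: float = 1.0
    b_m: float = 0.0
    v_base: float = 1e-2
    a0: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    f_c: float = 0.5
    r: float = 2.0
    k: float = 10.0
    base_e: float = 0.5

    def __post_init__(self) -> None:
        for name in ("v_base", "f_c", "r", "k", "base_e"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def a(self) -> np.ndarray:
        """Decay coefficients ordered (a0, a1, a2, a3)."""
        return np.array([self.a0, self.a1, self.a2, self.a3])

    def copy(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            k: float(getattr(self, k))
            for k in ("b", "b_m", "v_base", "a0", "a1", "a2", "a3", "f_c", "r", "k", "base_e")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class BinStats:
    """Per-bin effective totals ``s_i`` and derived bias factors ``v_i``.

    ``s`` and ``v`` are aligned with the bin index (position in the bin
    table, not the bin id). Invariant: ``v == bias_factor(s, params)`` under
    the parameters they were computed with.
    """

    s: np.ndarray
    v: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def from_totals(cls, s: np.ndarray, params: ModelParameters) -> "BinStats":
        s = np.asarray(s, dtype=float)
        return cls(s=s, v=bias_factor(s, params))


@dataclass
class InteractionRecord:
    """One scored bin pair."""

    i: int
    j: int
    d: float  # bp for cis; nan for trans
    x: int
    mu: float
    pvalue: float
    cls: str = "cis"  # "cis"/"trans" plus capture class suffix where relevant
    capture_cls: str = "NA"  # TT / TO / OO / NA

    @property
    def is_trans(self) -> bool:
        return not np.isfinite(self.d)


# ---------------------------------------------------------------------------
# soft maximum
# ---------------------------------------------------------------------------

def soft_maximum(alpha, beta, k: float):
    """Smooth two-argument maximum.

    softmax(a, b) = w_a * a + w_b * b with w_a = e^{k a} / (e^{k a} + e^{k b}).
    Bounded between min and max of its arguments and converging to the hard
    maximum as ``k`` grows. Computed with the larger exponent subtracted so
    it is total for all finite inputs.
    """
    tau, _, _ = soft_maximum_grad(alpha, beta, k)
    return tau


def soft_maximum_grad(alpha, beta, k: float):
    """Soft maximum together with its partial derivatives.

    Returns ``(tau, dtau/dalpha, dtau/dbeta)``; used by the trainer's
    analytic gradients. dtau/dalpha = w_a * (1 + k * w_b * (alpha - beta)).
    """
    if k <= 0:
        raise ValueError("sharpness k must be positive")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    diff = k * (alpha - beta)
    # w_a = 1 / (1 + e^{-k(a-b)}): logistic form is already overflow-safe
    w_a = special.expit(diff)
    w_b = 1.0 - w_a
    tau = w_a * alpha + w_b * beta
    gap = alpha - beta
    d_alpha = w_a * (1.0 + k * w_b * gap)
    d_beta = w_b * (1.0 - k * w_a * gap)
    return tau, d_alpha, d_beta


# ---------------------------------------------------------------------------
# bias factor
# ---------------------------------------------------------------------------

def bias_factor(s, params: ModelParameters):
    """Per-bin bias factor v = maximum(s**b * e^{b_m}, v_base).

    A hard maximum: the floor exists to keep nearly-unseen bins from
    producing abnormally small expectations. ``0**b`` is taken as 0 for any
    ``b`` so empty bins land exactly on the floor.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("bin totals must be non-negative")
    with np.errstate(divide="ignore"):
        ln_s = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), -np.inf)
    expo = np.clip(params.b * ln_s + params.b_m, -_EXP_CLIP, _EXP_CLIP)
    u = np.where(s > 0, np.exp(expo), 0.0)
    return np.maximum(u, params.v_base)


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

def _decay_poly(ln_d: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Value of the cubic decay polynomial at log distance."""
    return ((params.a3 * ln_d + params.a2) * ln_d + params.a1) * ln_d + params.a0


def distance_expectation(d, params: ModelParameters):
    """Expected background read count f(d) for cis pairs.

    f(d) = softmax(f_v(d), f_c) with f_v a cubic in ln(d) on the log scale.
    Self pairs must already be removed, so d <= 0 is an error; trans pairs
    never reach this function (callers use ``params.f_c`` directly).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("genomic distance must be positive for cis pairs")
    ln_d = np.log(d)
    f_v = np.exp(np.clip(_decay_poly(ln_d, params), -_EXP_CLIP, _EXP_CLIP))
    return soft_maximum(f_v, params.f_c, params.k)


# ---------------------------------------------------------------------------
# expected count
# ---------------------------------------------------------------------------

def expected_count(v_i, v_j, f_d, params: ModelParameters):
    """mu_ij = softmax(v_i * v_j * f(d_ij), base_e).

    The floor ``base_e`` keeps the many 1-read pairs between barely covered
    bins from dragging the fitted parameters down.
    """
    z = np.asarray(v_i, dtype=float) * np.asarray(v_j, dtype=float) * np.asarray(f_d, dtype=float)
    return soft_maximum(z, params.base_e, params.k)


# ---------------------------------------------------------------------------
# negative binomial likelihood and tail
# ---------------------------------------------------------------------------

def _check_counts(x) -> np.ndarray:
    x = np.asarray(x)
    if not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("observed counts must be integers")
    x = x.astype(float)
    if np.any(x < 0):
        raise ValueError("observed counts must be non-negative")
    return x

def nb_log_pmf(x, mu, r):
    """Log pmf of NB with mean ``mu`` and dispersion ``r``.

    pmf(x) = Gamma(x+r) / (Gamma(r) x!) * (r/(r+mu))^r * (mu/(r+mu))^x;
    evaluated through log-gamma so large counts stay exact.
    """
    x = _check_counts(x)
    mu = np.asarray(mu, dtype=float)
    r = float(r)
    if np.any(mu <= 0) or r <= 0:
        raise ValueError("mu and r must be strictly positive")
    log_rm = np.log(r + mu)
    return (
        special.gammaln(x + r)
        - special.gammaln(r)
        - special.gammaln(x + 1.0)
        + r * (np.log(r) - log_rm)
        + x * (np.log(mu) - log_rm)
    )


def pvalue(x, mu, r, inclusive: bool = True):
    """Upper-tail probability of the observed count under the background.

    With ``inclusive`` (default) this is P(X >= x) = 1 - CDF(x-1), the
    conservative convention for a discrete test; ``inclusive=False`` gives
    the strict tail P(X > x). Always in (0, 1]; computed with the survival
    function so small tails do not lose precision to 1-p cancellation.
    """
    x = _check_counts(x)
    mu = np.asarray(mu, dtype=float)
    r = float(r)
    if np.any(mu <= 0) or r <= 0:
        raise ValueError("mu and r must be strictly positive")
    p = r / (r + mu)
    shift = 1.0 if inclusive else 0.0
    out = stats.nbinom.sf(x - shift, r, p)
    # survival can round to exactly 0 for extreme counts; keep p in (0, 1]
    return np.clip(out, np.finfo(float).tiny, 1.0)
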