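"""Capture Hi-C extension of the background model.

Capture (bait-enriched) libraries sequence target regions at much higher
depth, so pairs fall into three classes — target-target (TT), target-other
(TO) and other-other (OO) — with different background levels. Each class
gets its own full parameter set, fitted only on its own pairs; the
smoothing hyperparameters (soft-maximum sharpness, expected-count floor)
are shared. Because a bin's raw total mixes reads from all three classes,
counts are converted to their TT-equivalents before bin totals are formed:

    x_TT_equiv = x * mu_TT / mu_own

where both expectations use the pair's own covariates under the two
parameter sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_io import BinTable, ContactMap, read_bed
from .model import BinStats, InteractionRecord, ModelParameters
from .trainer import (
    TrainingConfig,
    _Design,
    _mu_only,
    _pvalues_for,
    fit_one_round,
    initial_parameters,
    raw_bin_totals,
)

__all__ = [
    "CaptureModel",
    "flag_targets",
    "interaction_class",
    "convert_count_to_TT",
    "train_capture",
    "score_capture",
]

logger = logging.getLogger(__name__)

CLASSES = ("OO", "TO", "TT")
# a class too small to fit borrows parameters from its neighbour in
# enrichment order (TT <-> TO <-> OO)
_NEAREST = {"TT": ("TO", "OO"), "TO": ("TT", "OO"), "OO": ("TO", "TT")}
MIN_CLASS_PAIRS = 1000


@dataclass
class CaptureModel:
    """Per-class parameters plus shared (TT-equivalent scale) bin stats."""

    params_by_class: dict
    target_flags: np.ndarray
    bin_stats: BinStats
    classes: np.ndarray  # "TT"/"TO"/"OO" per stored pair
    masked: np.ndarray  # bool per stored pair
    mu: np.ndarray  # own-class expectation per stored pair
    pvalues: np.ndarray
    loglik_trace: dict = field(default_factory=dict)
    converged: dict = field(default_factory=dict)


def flag_targets(bins: BinTable, baits) -> np.ndarray:
    """Mark bins overlapping at least one bait interval by >= 1 bp.

    ``baits`` is a BED path or a DataFrame with chrom/start/end columns
    (0-based half-open). Zero flagged bins is fatal: capture mode without
    targets is a configuration error.
    """
    if not isinstance(baits, pd.DataFrame):
        baits = read_bed(baits)
    flags = np.zeros(len(bins), dtype=bool)
    for chrom, grp in baits.groupby("chrom"):
        sel = np.flatnonzero(bins.chrom.astype(str) == str(chrom))
        if len(sel) == 0:
            continue
        starts = np.asarray(grp["start"], dtype=np.int64)
        ends = np.asarray(grp["end"], dtype=np.int64)
        for s, e in zip(starts, ends):
            hit = (bins.start[sel] < e) & (bins.end[sel] > s)
            flags[sel[hit]] = True
    if not flags.any():
        raise ValueError("capture mode with no targets: no bin overlaps any bait")
    return flags


def interaction_class(i, j, target_flags: np.ndarray, bins: BinTable | None = None) -> str:
    """TT / TO / OO for one pair; symmetric in (i, j).

    ``i``/``j`` are bin indices into ``target_flags``, or bin ids when a
    bin table is supplied.
    """
    if bins is not None:
        i = int(bins.index_of([i])[0])
        j = int(bins.index_of([j])[0])
    return CLASSES[int(target_flags[i]) + int(target_flags[j])]


def _pair_classes(design: _Design, flags: np.ndarray) -> np.ndarray:
    code = flags[design.ii].astype(int) + flags[design.jj].astype(int)
    return np.array(CLASSES, dtype=object)[code]


def convert_count_to_TT(x, i, j, model: CaptureModel, bins: BinTable) -> float:
    """A pair's read count rescaled to the target-target class.

    Identity on TT pairs; linear in x.
    """
    ai = int(bins.index_of([i])[0])
    aj = int(bins.index_of([j])[0])
    cls = CLASSES[int(model.target_flags[ai]) + int(model.target_flags[aj])]
    if cls == "TT":
        return float(x)
    mid = bins.midpoint()
    s = model.bin_stats.s

    def mu_under(params: ModelParameters) -> float:
        from .model import bias_factor, distance_expectation, soft_maximum

        v = bias_factor(np.array([s[ai], s[aj]]), params)
        if bins.chrom[ai] == bins.chrom[aj]:
            f = float(distance_expectation(np.array([abs(float(mid[aj] - mid[ai]))]), params)[0])
        else:
            f = params.f_c
        return float(soft_maximum(v[0] * v[1] * f, params.base_e, params.k))

    mu_own = mu_under(model.params_by_class[cls])
    mu_tt = mu_under(model.params_by_class["TT"])
    return float(x) * mu_tt / mu_own


def train_capture(cmap: ContactMap, baits, config: TrainingConfig | None = None) -> CaptureModel:
    """Multi-round fit with one parameter set per interaction class.

    Per round: each class is fitted on its own unmasked pairs against the
    shared TT-equivalent bin totals; every pair is scored with its own
    class's parameters; the mask is re-derived; totals are recomputed from
    TT-converted counts (masked pairs contribute their TT expectation).
    Classes with fewer than ``MIN_CLASS_PAIRS`` pairs borrow the nearest
    fitted class's parameters (logged).
    """
    if config is None:
        config = TrainingConfig()
    if len(cmap) == 0:
        raise ValueError("cannot train on an empty contact map")
    flags = flag_targets(cmap.bins, baits)
    design = _Design(cmap, use_trans=config.use_trans)
    classes = _pair_classes(design, flags)
    class_masks = {cls: classes == cls for cls in CLASSES}
    counts = {cls: int(m.sum()) for cls, m in class_masks.items()}
    fit_order = [cls for cls in ("TT", "TO", "OO") if counts[cls] >= MIN_CLASS_PAIRS]
    if not fit_order:
        raise ValueError(
            f"no interaction class has at least {MIN_CLASS_PAIRS} pairs: {counts}"
        )
    for cls in CLASSES:
        if 0 < counts[cls] < MIN_CLASS_PAIRS:
            logger.warning(
                "class %s has only %d pairs; sharing parameters with the nearest class",
                cls, counts[cls],
            )

    s = raw_bin_totals(cmap)
    params0 = initial_parameters(design, s, config)
    params = {cls: params0 for cls in CLASSES}

    traces: dict = {cls: [] for cls in CLASSES}
    converged: dict = {cls: [] for cls in CLASSES}
    mask = np.zeros(len(design.x), dtype=bool)
    s_used = s
    pv = np.ones(len(design.x))
    mu_own = np.ones(len(design.x))

    for rnd in range(1, config.rounds + 1):
        s_used = s
        for cls in fit_order:
            exclude = mask | ~class_masks[cls]
            p_new, trace, conv = fit_one_round(design, params[cls], exclude, config, bin_totals=s)
            params[cls] = p_new
            traces[cls].append(trace)
            converged[cls].append(conv)
        for cls in CLASSES:
            if cls not in fit_order:
                donor = next(d for d in _NEAREST[cls] if d in fit_order)
                params[cls] = params[donor]
        # score each pair under its own class parameters
        for cls in CLASSES:
            sel = class_masks[cls]
            if not sel.any():
                continue
            sub = design.subset(sel)
            pv_c, mu_c = _pvalues_for(
                params[cls], sub, s,
                inclusive=config.inclusive_pvalue,
                zero_truncation=config.zero_truncation,
            )
            pv[sel] = pv_c
            mu_own[sel] = mu_c
        mask = pv < config.sig_threshold
        # TT-equivalent totals
        mu_tt = _mu_only(params["TT"], design, s)
        converted = np.where(mask, mu_tt, design.x * (mu_tt / mu_own))
        s = np.bincount(design.ii, weights=converted, minlength=design.n_bins) + np.bincount(
            design.jj, weights=converted, minlength=design.n_bins
        )
        logger.info(
            "capture round %d: %d/%d pairs masked", rnd, int(mask.sum()), len(mask)
        )

    full = lambda arr, fill: _expand(arr, design.sel, len(cmap), fill)  # noqa: E731
    return CaptureModel(
        params_by_class=params,
        target_flags=flags,
        bin_stats=BinStats.from_totals(s_used, params["TT"]),
        classes=full(classes, "NA"),
        masked=full(mask, False),
        mu=full(mu_own, np.nan),
        pvalues=full(pv, np.nan),
        loglik_trace={cls: [-t for t in traces[cls]] for cls in CLASSES},
        converged=converged,
    )


def _expand(arr: np.ndarray, sel: np.ndarray, n: int, fill) -> np.ndarray:
    if arr.dtype == object:
        out = np.full(n, fill, dtype=object)
    else:
        out = np.full(n, fill, dtype=arr.dtype if arr.dtype != bool else bool)
    out[sel] = arr
    return out


def score_capture(cmap: ContactMap, model: CaptureModel) -> list[InteractionRecord]:
    """One record per stored pair, scored with its own class's parameters."""
    d = cmap.distances()
    records = []
    for n in range(len(cmap)):
        records.append(
            InteractionRecord(
                i=int(cmap.i[n]),
                j=int(cmap.j[n]),
                d=float(d[n]),
                x=int(cmap.count[n]),
                mu=float(model.mu[n]),
                pvalue=float(model.pvalues[n]),
                cls="trans" if not np.isfinite(d[n]) else "cis",
                capture_cls=str(model.classes[n]),
            )
        )
    return records
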