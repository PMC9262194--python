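"""Scoring stored pairs under a trained background model."""

from __future__ import annotations

import numpy as np

from .contact_io import ContactMap
from .model import InteractionRecord, ModelParameters
from .trainer import FitResult, _Design, _pvalues_for

__all__ = ["score_all", "call_significant", "top_k", "benjamini_hochberg"]


def score_all(
    cmap: ContactMap,
    fit: FitResult,
    inclusive: bool = True,
    zero_truncation: bool = True,
    capture_classes=None,
) -> list[InteractionRecord]:
    """One scored record per stored triplet.

    Cis pairs use the distance-decay expectation, trans pairs the constant
    background-ligation term; each record carries the observed count, the
    model expectation and the NB tail probability (conditioned on the pair
    being observed unless ``zero_truncation`` is off, mirroring training).
    """
    if len(cmap) == 0:
        return []
    design = _Design(cmap, use_trans=True)
    pv, mu = _pvalues_for(fit.params, design, fit.bin_stats.s, inclusive=inclusive,
                          zero_truncation=zero_truncation)
    d = cmap.distances()
    records = []
    for n in range(len(cmap)):
        cap = "NA" if capture_classes is None else capture_classes[n]
        records.append(
            InteractionRecord(
                i=int(cmap.i[n]),
                j=int(cmap.j[n]),
                d=float(d[n]),
                x=int(cmap.count[n]),
                mu=float(mu[n]),
                pvalue=float(pv[n]),
                cls="trans" if not np.isfinite(d[n]) else "cis",
                capture_cls=cap,
            )
        )
    return records


def _sort_key(records: list[InteractionRecord], cmap_bins) -> np.ndarray:
    """Deterministic order: ascending p, ties by coordinates."""
    if not records:
        return np.array([], dtype=int)
    ai = cmap_bins.index_of([rec.i for rec in records])
    aj = cmap_bins.index_of([rec.j for rec in records])
    import pandas as pd

    df = pd.DataFrame(
        {
            "p": [rec.pvalue for rec in records],
            "c1": cmap_bins.chrom[ai].astype(str),
            "s1": cmap_bins.start[ai],
            "c2": cmap_bins.chrom[aj].astype(str),
            "s2": cmap_bins.start[aj],
        }
    )
    return df.sort_values(["p", "c1", "s1", "c2", "s2"], kind="mergesort").index.to_numpy()


def call_significant(
    records: list[InteractionRecord], threshold: float, bins=None
) -> list[InteractionRecord]:
    """Records with p below the threshold, sorted ascending by p.

    Ties are broken by genomic coordinates when a bin table is supplied,
    otherwise by (i, j) bin ids — both deterministic.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    hits = [rec for rec in records if rec.pvalue < threshold or threshold == 1.0]
    if threshold == 1.0:
        hits = list(records)
    if bins is not None:
        order = _sort_key(hits, bins)
        return [hits[int(n)] for n in order]
    return sorted(hits, key=lambda rec: (rec.pvalue, rec.i, rec.j))


def top_k(records: list[InteractionRecord], k: int, bins=None) -> list[InteractionRecord]:
    """The k best-P-value records with the same deterministic tie-break."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if bins is not None:
        order = _sort_key(records, bins)
        ordered = [records[int(n)] for n in order]
    else:
        ordered = sorted(records, key=lambda rec: (rec.pvalue, rec.i, rec.j))
    return ordered[:k]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH q-values, emitted for users; never used for the primary calls."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
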