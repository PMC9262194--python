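"""Feature-enrichment statistics for interaction calls.

Region-based enrichment compares the fraction of significant calls with at
least one end overlapping a feature against the same fraction over all
stored pairs; pair-based enrichment requires both ends to overlap (one
feature each, order-free). Capture libraries use a permutation scheme
instead, drawing random non-target-interacting bins as the null. SNP and
eQTL analyses are special cases with point intervals and promoter windows.

Overlap is >= 1 bp intersection on 0-based half-open intervals; strand is
ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contact_io import BinTable
from .model import InteractionRecord

__all__ = [
    "EnrichmentResult",
    "region_enrichment",
    "pair_enrichment",
    "capture_permutation_enrichment",
    "eqtl_pair_overlap",
    "fisher_pvalue",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    enrichment: float  # nan when undefined
    pvalue: float
    sig_fraction: float
    all_fraction: float
    table: tuple  # (sig overlap, sig non, all overlap, all non)

    def to_row(self) -> dict:
        return {
            "enrichment": self.enrichment,
            "pvalue": self.pvalue,
            "sig_fraction": self.sig_fraction,
            "all_fraction": self.all_fraction,
            "sig_overlap": self.table[0],
            "sig_nonoverlap": self.table[1],
            "all_overlap": self.table[2],
            "all_nonoverlap": self.table[3],
        }


# ---------------------------------------------------------------------------
# interval machinery
# ---------------------------------------------------------------------------

def _merge_intervals(feature: pd.DataFrame) -> dict:
    """Per-chromosome merged, sorted, disjoint intervals."""
    out = {}
    for chrom, grp in feature.groupby("chrom"):
        arr = grp[["start", "end"]].sort_values("start").to_numpy(dtype=np.int64)
        merged = []
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        m = np.array(merged, dtype=np.int64)
        out[str(chrom)] = (m[:, 0], m[:, 1])
    return out


def _overlaps(chroms, starts, ends, merged: dict) -> np.ndarray:
    """Half-open >= 1 bp overlap of query intervals with merged features."""
    chroms = np.asarray(chroms).astype(str)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    hit = np.zeros(len(chroms), dtype=bool)
    for chrom in np.unique(chroms):
        if chrom not in merged:
            continue
        f_start, f_end = merged[chrom]
        sel = chroms == chrom
        # candidate: last feature starting before the query end
        pos = np.searchsorted(f_start, ends[sel], side="left") - 1
        ok = pos >= 0
        cand_end = np.where(ok, f_end[np.clip(pos, 0, None)], 0)
        hit[np.flatnonzero(sel)] = ok & (cand_end > starts[sel])
    return hit


def _record_ends(records: list[InteractionRecord], bins: BinTable):
    ai = bins.index_of([rec.i for rec in records])
    aj = bins.index_of([rec.j for rec in records])
    return (
        (bins.chrom[ai], bins.start[ai], bins.end[ai]),
        (bins.chrom[aj], bins.start[aj], bins.end[aj]),
    )


def _as_feature(feature) -> pd.DataFrame:
    if isinstance(feature, pd.DataFrame):
        return feature
    from .contact_io import read_bed

    return read_bed(feature)


def fisher_pvalue(table, alternative: str = "two-sided") -> float:
    """Fisher's exact P for the 2x2 scheme used throughout: the counts are
    (sig overlap, sig non-overlap) against (all overlap, all non-overlap)."""
    a, b, c, d = (int(v) for v in table)
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def _enrich(sig_hit: np.ndarray, all_hit: np.ndarray) -> EnrichmentResult:
    n_sig, n_all = len(sig_hit), len(all_hit)
    k_sig, k_all = int(sig_hit.sum()), int(all_hit.sum())
    sig_frac = k_sig / n_sig if n_sig else np.nan
    all_frac = k_all / n_all if n_all else np.nan
    table = (k_sig, n_sig - k_sig, k_all, n_all - k_all)
    if not n_sig or not n_all or all_frac == 0:
        logger.warning("enrichment undefined (no overlap in the reference set)")
        return EnrichmentResult(np.nan, np.nan, sig_frac, all_frac, table)
    return EnrichmentResult(sig_frac / all_frac, fisher_pvalue(table), sig_frac, all_frac, table)


def region_enrichment(
    sig: list[InteractionRecord],
    all_records: list[InteractionRecord],
    feature,
    bins: BinTable,
) -> EnrichmentResult:
    """Enrichment of calls with >= 1 end overlapping the feature.

    enrichment = (fraction of significant calls overlapping) /
    (fraction of all stored pairs overlapping); P from Fisher's exact test
    on the (sig overlap, sig non, all overlap, all non) table.
    """
    merged = _merge_intervals(_as_feature(feature))

    def any_end(records):
        if not records:
            return np.zeros(0, dtype=bool)
        (c1, s1, e1), (c2, s2, e2) = _record_ends(records, bins)
        return _overlaps(c1, s1, e1, merged) | _overlaps(c2, s2, e2, merged)

    return _enrich(any_end(sig), any_end(all_records))


def pair_enrichment(
    sig: list[InteractionRecord],
    all_records: list[InteractionRecord],
    feature_a,
    feature_b,
    bins: BinTable,
) -> EnrichmentResult:
    """Enrichment of calls with one end in feature A and the other in B.

    Order-free: (end1 in A and end2 in B) or (end1 in B and end2 in A);
    with A == B this is the both-ends version of the region analysis.
    """
    merged_a = _merge_intervals(_as_feature(feature_a))
    merged_b = _merge_intervals(_as_feature(feature_b))

    def both_ends(records):
        if not records:
            return np.zeros(0, dtype=bool)
        (c1, s1, e1), (c2, s2, e2) = _record_ends(records, bins)
        a1 = _overlaps(c1, s1, e1, merged_a)
        a2 = _overlaps(c2, s2, e2, merged_a)
        b1 = _overlaps(c1, s1, e1, merged_b)
        b2 = _overlaps(c2, s2, e2, merged_b)
        return (a1 & b2) | (b1 & a2)

    return _enrich(both_ends(sig), both_ends(all_records))


def capture_permutation_enrichment(
    sig_other_ends: np.ndarray,
    candidate_pool: np.ndarray,
    feature,
    bins: BinTable,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation enrichment for capture libraries.

    ``sig_other_ends`` and ``candidate_pool`` are bin indices: the
    significant target-interacting other ends, and bins with no target
    interaction at all. Each permutation draws ``len(sig_other_ends)``
    pool bins without replacement; enrichment is the observed overlap
    fraction over the mean permuted fraction, with an empirical P-value
    (1 + #permutations >= observed) / (n_perm + 1).
    """
    sig_other_ends = np.asarray(sig_other_ends, dtype=np.int64)
    candidate_pool = np.asarray(candidate_pool, dtype=np.int64)
    if len(candidate_pool) < len(sig_other_ends):
        raise ValueError("candidate pool smaller than the significant set")
    merged = _merge_intervals(_as_feature(feature))
    flags = _overlaps(bins.chrom, bins.start, bins.end, merged)
    obs = float(flags[sig_other_ends].mean()) if len(sig_other_ends) else np.nan
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_perm)
    for t in range(n_perm):
        draw = rng.choice(candidate_pool, size=len(sig_other_ends), replace=False)
        fracs[t] = flags[draw].mean()
    mean_frac = float(fracs.mean())
    enrichment = obs / mean_frac if mean_frac > 0 else np.nan
    pvalue = (1.0 + float(np.sum(fracs >= obs))) / (n_perm + 1.0)
    return enrichment, pvalue


def eqtl_pair_overlap(
    sig: list[InteractionRecord],
    all_records: list[InteractionRecord],
    eqtl: pd.DataFrame,
    bins: BinTable,
    promoter_halfwidth: int = 5000,
) -> tuple[float, float]:
    """Fraction of calls bridging an eQTL SNP to its gene's promoter.

    A record overlaps an eQTL pair when one end contains the SNP position
    and the other end intersects [TSS - halfwidth, TSS + halfwidth]. The
    eqtl frame needs columns snp_chrom, snp_pos, tss_chrom, tss_pos.
    Returns (fraction over significant calls, enrichment over all pairs).
    """

    def hits(records) -> np.ndarray:
        if not records:
            return np.zeros(0, dtype=bool)
        (c1, s1, e1), (c2, s2, e2) = _record_ends(records, bins)
        c1 = c1.astype(str)
        c2 = c2.astype(str)
        out = np.zeros(len(records), dtype=bool)
        for row in eqtl.itertuples(index=False):
            snp_c, snp_p = str(row.snp_chrom), int(row.snp_pos)
            tss_c, tss_p = str(row.tss_chrom), int(row.tss_pos)
            lo, hi = tss_p - promoter_halfwidth, tss_p + promoter_halfwidth
            snp1 = (c1 == snp_c) & (s1 <= snp_p) & (snp_p < e1)
            snp2 = (c2 == snp_c) & (s2 <= snp_p) & (snp_p < e2)
            prom1 = (c1 == tss_c) & (s1 <= hi) & (e1 > lo)
            prom2 = (c2 == tss_c) & (s2 <= hi) & (e2 > lo)
            out |= (snp1 & prom2) | (snp2 & prom1)
        return out

    sig_hit = hits(sig)
    all_hit = hits(all_records)
    sig_frac = float(sig_hit.mean()) if len(sig_hit) else np.nan
    all_frac = float(all_hit.mean()) if len(all_hit) else np.nan
    if not all_frac or np.isnan(all_frac):
        logger.warning("eQTL enrichment undefined (no overlap among all pairs)")
        return sig_frac, np.nan
    return sig_frac, sig_frac / all_frac
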