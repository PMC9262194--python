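"""Reading, writing and binning of sparse contact maps.

Input format is the common triplet dump: a bins file (BED-like, 4+ columns:
chrom, start, end, bin_id) and a matrix file (3 columns: bin_id_i,
bin_id_j, count). Coordinates are 0-based half-open throughout. Triplets
are normalised on load: ``i <= j`` enforced by swapping, duplicate pairs
summed, self pairs and zero counts dropped. Gzip-compressed inputs are
accepted transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .model import InteractionRecord

__all__ = [
    "BinTable",
    "ContactMap",
    "read_hicpro",
    "read_bed",
    "bin_fragment_pairs",
    "write_calls",
]

logger = logging.getLogger(__name__)


def _open_text(path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class BinTable:
    """Fixed-size genomic bins with integer ids.

    ``start``/``end`` are 0-based half-open; bins within a chromosome are
    sorted and non-overlapping and all but the terminal bin of each
    chromosome have length ``bin_size``.
    """

    chrom: np.ndarray  # str per bin
    start: np.ndarray  # int bp
    end: np.ndarray  # int bp
    bin_id: np.ndarray  # unique int key
    is_target: np.ndarray | None = None  # capture mode only

    _id_to_index: dict = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.bin_id = np.asarray(self.bin_id, dtype=np.int64)
        if len(np.unique(self.bin_id)) != len(self.bin_id):
            raise ValueError("bin ids must be unique")
        if np.any(self.end <= self.start):
            raise ValueError("bins must satisfy start < end")
        self._id_to_index = {int(b): idx for idx, b in enumerate(self.bin_id)}

    def __len__(self) -> int:
        return len(self.bin_id)

    def index_of(self, bin_ids) -> np.ndarray:
        """Map bin ids to row positions; fatal if an id is unknown."""
        ids = np.asarray(bin_ids, dtype=np.int64)
        out = np.empty(ids.shape, dtype=np.int64)
        for pos, b in enumerate(ids.ravel()):
            try:
                out.ravel()[pos] = self._id_to_index[int(b)]
            except KeyError:
                raise KeyError(f"bin id {int(b)} referenced in matrix but absent from bins file") from None
        return out

    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end, "bin_id": self.bin_id})
        if self.is_target is not None:
            df["is_target"] = self.is_target
        return df

    @classmethod
    def regular(cls, chrom_sizes: dict[str, int], bin_size: int, first_id: int = 1) -> "BinTable":
        """Tile chromosomes with ``bin_size`` bins, ids consecutive."""
        chroms, starts, ends = [], [], []
        for name, size in chrom_sizes.items():
            edges = np.arange(0, size, bin_size, dtype=np.int64)
            chroms.extend([name] * len(edges))
            starts.append(edges)
            ends.append(np.minimum(edges + bin_size, size))
        starts = np.concatenate(starts)
        ends = np.concatenate(ends)
        ids = np.arange(first_id, first_id + len(starts), dtype=np.int64)
        return cls(chrom=np.array(chroms, dtype=object), start=starts, end=ends, bin_id=ids)


@dataclass
class ContactMap:
    """Sparse upper-triangular contact map for one library at one bin size.

    ``i``/``j`` are bin ids (with i <= j), ``count`` the observed reads;
    only pairs with at least one read are stored and self pairs are removed.
    """

    bins: BinTable
    i: np.ndarray
    j: np.ndarray
    count: np.ndarray
    bin_size: int

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if not (len(self.i) == len(self.j) == len(self.count)):
            raise ValueError("triplet arrays must have equal length")

    def __len__(self) -> int:
        return len(self.count)

    @property
    def n_pairs(self) -> int:
        return len(self.count)

    @classmethod
    def from_triplets(cls, bins: BinTable, i, j, count, bin_size: int,
                      report_dropped: bool = False):
        """Normalise raw triplets into a valid map.

        Swaps to i <= j, sums duplicates, drops self pairs and zero counts.
        Returns the map, plus the dropped self-pair read mass if requested.
        """
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        count = np.asarray(count, dtype=np.int64)
        # referential integrity (raises on unknown ids)
        bins.index_of(i)
        bins.index_of(j)
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        keep = count > 0
        lo, hi, count = lo[keep], hi[keep], count[keep]
        self_mask = lo == hi
        dropped = int(count[self_mask].sum())
        lo, hi, count = lo[~self_mask], hi[~self_mask], count[~self_mask]
        if len(lo):
            key = pd.MultiIndex.from_arrays([lo, hi])
            agg = pd.Series(count).groupby(key).sum()
            lo = np.array([k[0] for k in agg.index], dtype=np.int64)
            hi = np.array([k[1] for k in agg.index], dtype=np.int64)
            count = agg.to_numpy(dtype=np.int64)
        cmap = cls(bins=bins, i=lo, j=hi, count=count, bin_size=bin_size)
        if report_dropped:
            return cmap, dropped
        return cmap

    def idx(self) -> tuple[np.ndarray, np.ndarray]:
        """Row positions of both ends in the bin table."""
        return self.bins.index_of(self.i), self.bins.index_of(self.j)

    def distances(self) -> np.ndarray:
        """Midpoint distance (bp) per pair; nan for trans pairs."""
        ii, jj = self.idx()
        mid = self.bins.midpoint()
        d = np.abs(mid[jj] - mid[ii]).astype(float)
        trans = self.bins.chrom[ii] != self.bins.chrom[jj]
        d[trans] = np.nan
        return d

    def write_hicpro(self, matrix_path, bed_path) -> None:
        """Write the triplet/bins pair back out (uncompressed text)."""
        bed = self.bins.to_frame()[["chrom", "start", "end", "bin_id"]]
        bed.to_csv(bed_path, sep="\t", header=False, index=False)
        pd.DataFrame({"i": self.i, "j": self.j, "count": self.count}).to_csv(
            matrix_path, sep="\t", header=False, index=False
        )


def read_bed(path) -> pd.DataFrame:
    """Read a BED-like interval file (3+ columns, 0-based half-open)."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"BED line has fewer than 3 columns: {line!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _infer_bin_size(start: np.ndarray, end: np.ndarray) -> int:
    widths = end - start
    return int(np.bincount(widths).argmax()) if len(widths) else 0


def read_hicpro(matrix_path, bed_path) -> ContactMap:
    """Read a triplet matrix plus bins BED into a normalised ContactMap.

    The bed file needs 4+ whitespace-delimited columns (chrom, start, end,
    bin_id); the matrix file 3 columns (i, j, count). Counts must be
    integers; unknown bin ids in the matrix are fatal.
    """
    chroms, starts, ends, ids = [], [], [], []
    with _open_text(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{bed_path}:{lineno}: bins file needs 4+ columns")
            chroms.append(parts[0])
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            ids.append(int(parts[3]))
    bins = BinTable(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts), end=np.array(ends), bin_id=np.array(ids),
    )
    ii, jj, cc = [], [], []
    with _open_text(matrix_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{matrix_path}:{lineno}: matrix file needs 3 columns")
            try:
                i_val, j_val = int(parts[0]), int(parts[1])
                c_val = int(parts[2])
            except ValueError:
                raise ValueError(
                    f"{matrix_path}:{lineno}: non-integer entry in matrix row {parts[:3]}"
                ) from None
            ii.append(i_val)
            jj.append(j_val)
            cc.append(c_val)
    bin_size = _infer_bin_size(bins.start, bins.end)
    return ContactMap.from_triplets(bins, ii, jj, cc, bin_size=bin_size)


def bin_fragment_pairs(
    pairs: Iterable[tuple[str, int, int, str, int, int]], bins: BinTable
) -> ContactMap:
    """Assign fragment-level read pairs to bins by fragment midpoint.

    Each end goes to the bin whose [start, end) contains
    floor((start + end) / 2); a midpoint at a bin boundary belongs to the
    bin starting there. Pairs whose two ends land in the same bin are
    self interactions and are removed. Midpoints beyond the last bin of
    their chromosome are clamped to the terminal bin (logged).
    """
    # per-chromosome sorted lookup
    order: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(bins.chrom.astype(str)):
        sel = np.where(bins.chrom.astype(str) == chrom)[0]
        sel = sel[np.argsort(bins.start[sel])]
        order[chrom] = (bins.start[sel], bins.bin_id[sel])

    clamped = 0

    def locate(chrom: str, start: int, end: int) -> int:
        nonlocal clamped
        if start < 0 or end < 0:
            raise ValueError("fragment coordinates must be non-negative")
        if chrom not in order:
            raise KeyError(f"no bins for chromosome {chrom!r}")
        mid = (start + end) // 2
        starts, ids_ = order[chrom]
        pos = int(np.searchsorted(starts, mid, side="right")) - 1
        if pos < 0:
            pos = 0
        if pos >= len(ids_):
            pos = len(ids_) - 1
        # beyond the terminal bin: clamp and count
        idx = bins._id_to_index[int(ids_[pos])]
        if mid >= bins.end[idx] and pos == len(ids_) - 1:
            clamped += 1
        return int(ids_[pos])

    ii, jj = [], []
    for chromA, a0, a1, chromB, b0, b1 in pairs:
        ii.append(locate(chromA, a0, a1))
        jj.append(locate(chromB, b0, b1))
    if clamped:
        logger.warning("%d fragment midpoints beyond the terminal bin were clamped", clamped)
    n = len(ii)
    bin_size = _infer_bin_size(bins.start, bins.end)
    return ContactMap.from_triplets(bins, ii, jj, np.ones(n, dtype=np.int64), bin_size=bin_size)


# ---------------------------------------------------------------------------
# results file
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "distance", "observed", "expected", "neg_log10_pvalue", "class",
]


def _records_frame(records: Sequence[InteractionRecord], bins: BinTable) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=_CALL_COLUMNS)
    ids = np.array([(rec.i, rec.j) for rec in records], dtype=np.int64)
    ai = bins.index_of(ids[:, 0])
    aj = bins.index_of(ids[:, 1])
    d = np.array([rec.d for rec in records], dtype=float)
    p = np.array([rec.pvalue for rec in records], dtype=float)
    cls = []
    for rec in records:
        label = "trans" if rec.is_trans else "cis"
        if rec.capture_cls != "NA":
            label += f":{rec.capture_cls}"
        cls.append(label)
    df = pd.DataFrame(
        {
            "chrom1": bins.chrom[ai],
            "start1": bins.start[ai],
            "end1": bins.end[ai],
            "chrom2": bins.chrom[aj],
            "start2": bins.start[aj],
            "end2": bins.end[aj],
            "distance": d,
            "observed": [rec.x for rec in records],
            "expected": [rec.mu for rec in records],
            "neg_log10_pvalue": -np.log10(p),
            "class": cls,
        }
    )
    return df


def write_calls(records: Sequence[InteractionRecord], path, bins: BinTable) -> None:
    """Write scored records to a tab-delimited file.

    Rows are sorted by P-value ascending, ties broken by coordinates; the
    trans distance is serialized as ``NA``.
    """
    df = _records_frame(records, bins)
    if len(df):
        df = df.sort_values(
            ["neg_log10_pvalue", "chrom1", "start1", "chrom2", "start2"],
            ascending=[False, True, True, True, True],
            kind="mergesort",
        )
        df["distance"] = [
            "NA" if not np.isfinite(v) else str(int(v)) for v in df["distance"]
        ]
        df["expected"] = [str(round(float(v), 6)) for v in df["expected"]]
        df["neg_log10_pvalue"] = [str(round(float(v), 6)) for v in df["neg_log10_pvalue"]]
    df.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    """Round-trip reader for the results file."""
    return pd.read_csv(path, sep="\t", dtype={"distance": str}, keep_default_na=False,
                       na_values=[""])
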