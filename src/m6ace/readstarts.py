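"""UMI handling, PCR-duplicate removal and read-start collation.

The central object is the :class:`ReadStartTable`: per-position,
per-replicate, per-library-type counts of deduplicated fragment 5' ends.
Exonuclease digestion stops at the antibody-protected methylated base, so
in the m6ACE library these 5' ends pile up exactly at modified adenosines,
while the input library (random fragmentation) is flat.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from m6ace.errors import FormatError, M6aceError
from m6ace.io import (ALIGNED_TABLE_COLUMNS, LIBRARY_TYPES, UMI_PATTERN,
                      ReferenceSet, SiteRecord)

UMI_LENGTH = 8

_DEDUP_KEY = ["contig", "strand", "start", "end", "umi", "replicate", "library"]


class AlignedRead(NamedTuple):
    """One deduplicable mapped read pair.

    ``start``/``end`` are the genomic half-open fragment interval
    (start < end); the method's signal, the strand-aware 5' coordinate, is
    ``start`` on + and ``end - 1`` on -.
    """

    contig: str
    strand: str
    start: int
    end: int
    umi: str
    replicate: str
    library: str

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def reads_to_frame(reads: Sequence[AlignedRead]) -> pd.DataFrame:
    return pd.DataFrame(list(reads), columns=ALIGNED_TABLE_COLUMNS)


class UmiResult(NamedTuple):
    umi: str
    remainder: str
    valid: bool


def extract_umi(read1_sequence: str) -> UmiResult:
    """Split off the 8-mer N7B UMI at the 5' end of read 1.

    The UMI occupies the first 8 nucleotides; validity requires bases 1-7 in
    {A,C,G,T} and base 8 in {C,G,T}. Sequences shorter than 9 nt (UMI plus
    at least one insert base) are an error.
    """
    seq = read1_sequence.upper()
    if len(seq) < UMI_LENGTH + 1:
        raise FormatError(
            f"read of length {len(seq)} too short to carry an {UMI_LENGTH}-mer "
            "UMI plus insert")
    umi, rest = seq[:UMI_LENGTH], seq[UMI_LENGTH:]
    return UmiResult(umi, rest, bool(UMI_PATTERN.match(umi)))


def deduplicate(reads: Union[pd.DataFrame, Sequence[AlignedRead]]):
    """Remove PCR duplicates: aligned pairs sharing mapping coordinates
    (contig, strand, start, end) and UMI within a (replicate, library).

    The first occurrence is retained; output is sorted by the duplicate key
    for determinism. Idempotent.
    """
    as_frame = isinstance(reads, pd.DataFrame)
    df = reads if as_frame else reads_to_frame(reads)
    out = (df.drop_duplicates(subset=_DEDUP_KEY, keep="first")
             .sort_values(_DEDUP_KEY, kind="mergesort")
             .reset_index(drop=True))
    if as_frame:
        return out
    return [AlignedRead(*row) for row in out[ALIGNED_TABLE_COLUMNS].itertuples(index=False)]


class ReadStartTable:
    """Read-start counts per (contig, strand, position) x (replicate, library).

    ``counts`` is a DataFrame whose row index is the position triple and
    whose columns are a (replicate, library) MultiIndex. ``library_sizes``
    holds the total deduplicated read count per column; for the full table
    it equals the column sums.
    """

    def __init__(self, counts: pd.DataFrame, library_sizes: pd.Series):
        self.counts = counts
        self.library_sizes = library_sizes
        self._index_cache: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}

    @property
    def replicates(self) -> List[str]:
        return sorted({r for r, _ in self.counts.columns})

    def columns_for(self, library: str) -> List[Tuple[str, str]]:
        return [c for c in self.counts.columns if c[1] == library]

    def rpm(self) -> pd.DataFrame:
        """Counts scaled to reads per million mapped (per column)."""
        sizes = self.library_sizes.reindex(self.counts.columns)
        if (sizes <= 0).any():
            raise M6aceError("rpm undefined for empty libraries")
        return self.counts / sizes * 1e6

    # -- window sums --------------------------------------------------------

    def _group_arrays(self, contig: str, strand: str):
        key = (contig, strand)
        if key not in self._index_cache:
            try:
                sub = self.counts.xs((contig, strand), level=("contig", "strand"),
                                     drop_level=True)
            except KeyError:
                sub = self.counts.iloc[0:0].droplevel(["contig", "strand"])
            positions = sub.index.to_numpy(dtype=np.int64)
            order = np.argsort(positions)
            self._index_cache[key] = (positions[order],
                                      sub.to_numpy()[order])
        return self._index_cache[key]

    def window_sums(self, contig: str, strand: str, position: int,
                    offsets: Tuple[int, int]) -> pd.Series:
        """Sum counts over an inclusive strand-aware offset window.

        Offsets follow transcription: -k is k nt 5' of the site, so on the
        minus strand offset -k is genomic position + k. Positions absent
        from the table (including off-contig) contribute 0. Returns one sum
        per (replicate, library) column.
        """
        a, b = offsets
        if a > b:
            raise ValueError(f"offset range {offsets} must be (low, high)")
        if strand == "+":
            lo, hi = position + a, position + b
        else:
            lo, hi = position - b, position - a
        positions, mat = self._group_arrays(contig, strand)
        i = np.searchsorted(positions, lo, side="left")
        j = np.searchsorted(positions, hi, side="right")
        return pd.Series(mat[i:j].sum(axis=0), index=self.counts.columns)

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready view: contig, strand, position, one count column
        per replicate x library."""
        flat = self.counts.copy()
        flat.columns = [f"{r}.{lib}" for r, lib in flat.columns]
        return flat.reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   library_sizes: Optional[pd.Series] = None) -> "ReadStartTable":
        df = frame.set_index(["contig", "strand", "position"])
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split(".", 1)) for c in df.columns],
            names=["replicate", "library"])
        df.columns = cols
        if library_sizes is None:
            library_sizes = df.sum(axis=0)
        return cls(df, library_sizes)


def window_sum(table: ReadStartTable, site: SiteRecord,
               offsets: Tuple[int, int], replicate: Optional[str] = None,
               library: Optional[str] = None):
    """Windowed read-start count for one site (see
    :meth:`ReadStartTable.window_sums`); with ``replicate`` and ``library``
    given, returns the scalar for that column."""
    sums = table.window_sums(site.contig, site.strand, site.position, offsets)
    if replicate is None and library is None:
        return sums
    if replicate is not None and library is not None:
        return int(sums[(replicate, library)])
    sel = [c for c in sums.index
           if (replicate is None or c[0] == replicate)
           and (library is None or c[1] == library)]
    return sums[sel]


def collate_read_starts(reads: pd.DataFrame, reference: ReferenceSet) -> ReadStartTable:
    """Collate deduplicated reads into the full read-start table.

    Each read increments (contig, strand, 5'-position) in its
    (replicate, library) column. Reads whose 5' position falls outside the
    contig are rejected with a warning. Library sizes are the retained read
    counts per column.
    """
    df = reads.copy()
    df["position"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    lengths = df["contig"].map(lambda c: len(reference.contigs.get(c, "")))
    in_bounds = (df["position"] >= 0) & (df["position"] < lengths)
    n_bad = int((~in_bounds).sum())
    if n_bad:
        warnings.warn(f"rejected {n_bad} reads with 5' ends outside contig bounds")
        df = df[in_bounds]
    grouped = (df.groupby(["contig", "strand", "position", "replicate", "library"],
                          observed=True)
                 .size())
    counts = grouped.unstack(["replicate", "library"], fill_value=0)
    # stable column order: replicate-major, library per LIBRARY_TYPES order
    reps = sorted({r for r, _ in counts.columns})
    libs = [l for l in LIBRARY_TYPES if l in {x for _, x in counts.columns}]
    cols = [(r, l) for r in reps for l in libs if (r, l) in counts.columns]
    counts = counts[cols]
    counts.columns = pd.MultiIndex.from_tuples(cols, names=["replicate", "library"])
    counts = counts.sort_index()
    return ReadStartTable(counts, counts.sum(axis=0))


def candidate_positions(table: ReadStartTable, reference: ReferenceSet,
                        min_mean: float = 1.0) -> pd.DataFrame:
    """Subset of the full table eligible for site testing.

    A position is a candidate when its strand-aware reference base is A and
    its mean m6ACE count across replicates is at least ``min_mean`` (the
    input libraries are not thresholded). Returns the count sub-DataFrame.
    """
    m6_cols = table.columns_for("m6ACE")
    if not m6_cols:
        raise M6aceError("no m6ACE libraries in table")
    mean_ok = table.counts[m6_cols].mean(axis=1) >= min_mean
    sub = table.counts[mean_ok.to_numpy()]
    idx = sub.index
    is_a = np.fromiter(
        (reference.base(c, p, s) == "A"
         for c, s, p in zip(idx.get_level_values("contig"),
                            idx.get_level_values("strand"),
                            idx.get_level_values("position"))),
        dtype=bool, count=len(idx))
    return sub[is_a]
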