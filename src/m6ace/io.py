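"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open, genomic. A "site" is the
single genomic base carrying the modification, so its BED interval is
``[position, position + 1)``. Strand-aware offsets follow transcription:
offset ``-k`` lies k nt 5' of a position, i.e. at genomic ``position - k``
on the plus strand and ``position + k`` on the minus strand. User-facing
tables additionally report 1-based positions.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from m6ace.errors import ConfigurationError, FormatError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Unique molecular identifier layout: seven fully random bases followed by
#: one of C/G/T (pattern "N7B"). The constrained final base marks the
#: ligation junction next to the insert.
UMI_PATTERN = re.compile(r"^[ACGT]{7}[CGT]$")

ALIGNED_TABLE_COLUMNS = ["contig", "strand", "start", "end", "umi",
                         "replicate", "library"]
LIBRARY_TYPES = ("m6ACE", "input")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceSet:
    """Reference sequences plus the designated spike-in contig.

    The spike-in is a synthetic methylated RNA added at fixed mass to every
    library; its methylated site normalises crosslink/IP/exonuclease
    efficiency across samples (the denominator of RML).
    """

    contigs: Dict[str, str]
    spike_in_name: Optional[str] = None

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}
        for name, seq in self.contigs.items():
            if not set(seq) <= set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise FormatError(f"contig {name!r} contains non-ACGTN bases: {bad}")
        if self.spike_in_name is not None and self.spike_in_name not in self.contigs:
            raise ConfigurationError(
                f"spike-in contig {self.spike_in_name!r} not present in reference "
                f"(contigs: {sorted(self.contigs)})"
            )

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def base(self, contig: str, position: int, strand: str = "+") -> str:
        """Strand-aware base at a genomic position; '' when off-contig."""
        seq = self.contigs.get(contig)
        if seq is None or not (0 <= position < len(seq)):
            return ""
        b = seq[position]
        return b if strand == "+" else b.translate(_COMPLEMENT)

    def base_at_offset(self, contig: str, position: int, strand: str,
                       offset: int) -> str:
        """Strand-aware base at a transcription-frame offset from ``position``."""
        g = position + offset if strand == "+" else position - offset
        return self.base(contig, g, strand)


@dataclass
class TranscriptModel:
    """One transcript: sorted non-overlapping exon blocks plus optional CDS.

    ``cds`` is the genomic (start, end) of the coding region (half-open);
    None for non-coding transcripts. The TSS is the strand-aware first
    transcribed base.
    """

    name: str
    contig: str
    strand: str
    exons: List[tuple]
    cds: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise FormatError(f"transcript {self.name!r}: overlapping exons")
        if self.cds is not None:
            self.cds = tuple(self.cds)
            if not (self._in_exons(self.cds[0]) and self._in_exons(self.cds[1] - 1)):
                raise FormatError(
                    f"transcript {self.name!r}: CDS {self.cds} outside exons")

    def _in_exons(self, g: int) -> bool:
        return any(s <= g < e for s, e in self.exons)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic position of the strand-aware first transcribed base."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    def genomic_to_transcript(self, g: int) -> Optional[int]:
        """Transcript coordinate (0 = 5' end) of genomic position g, or None
        if g falls in an intron / outside the transcript."""
        u = 0
        for s, e in self.exons:
            if s <= g < e:
                u += g - s
                return u if self.strand == "+" else self.length - 1 - u
            u += e - s
        return None

    def transcript_to_genomic(self, t: int) -> int:
        if not (0 <= t < self.length):
            raise IndexError(f"transcript coordinate {t} out of range")
        u = t if self.strand == "+" else self.length - 1 - t
        for s, e in self.exons:
            if u < e - s:
                return s + u
            u -= e - s
        raise AssertionError("unreachable")

    def cds_transcript_interval(self) -> Optional[tuple]:
        """CDS as a half-open interval in transcript coordinates."""
        if self.cds is None:
            return None
        a = self.genomic_to_transcript(self.cds[0])
        b = self.genomic_to_transcript(self.cds[1] - 1)
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1

    def rna_sequence(self, reference: ReferenceSet) -> str:
        seq = "".join(reference.contigs[self.contig][s:e] for s, e in self.exons)
        return seq if self.strand == "+" else reverse_complement(seq)


@dataclass
class SiteRecord:
    """A candidate or called modification site: one adenosine base."""

    contig: str
    strand: str
    position: int
    site_id: str = ""
    gene: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if not self.site_id:
            self.site_id = f"{self.contig}:{self.position}:{self.strand}"


def site_key(contig: str, position: int, strand: str) -> str:
    return f"{contig}:{position}:{strand}"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_reference(path, spike_in_name: Optional[str] = None) -> ReferenceSet:
    """Load a FASTA reference, uppercasing sequences and flagging the spike-in."""
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return ReferenceSet(contigs=contigs, spike_in_name=spike_in_name)


def write_reference(reference: ReferenceSet, path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Transcript models (BED12 / GTF)
# ---------------------------------------------------------------------------

def _parse_bed12_line(fields: Sequence[str]) -> TranscriptModel:
    chrom, start = fields[0], int(fields[1])
    name, strand = fields[3], fields[5]
    thick_start, thick_end = int(fields[6]), int(fields[7])
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise FormatError(f"BED12 record {name!r}: blockCount mismatch")
    exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
    cds = (thick_start, thick_end) if thick_start < thick_end else None
    return TranscriptModel(name=name, contig=chrom, strand=strand,
                           exons=exons, cds=cds)


def _read_bed12(path) -> List[TranscriptModel]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{ln}: BED12 needs 12 columns, got {len(fields)}")
            try:
                out.append(_parse_bed12_line(fields))
            except FormatError as exc:
                warnings.warn(f"{path}:{ln}: record rejected: {exc}")
    return out


_GTF_TX_RE = re.compile(r'transcript_id "([^"]+)"')


def _read_gtf(path) -> List[TranscriptModel]:
    exons: Dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"GTF line with {len(f)} columns")
            feature = f[2]
            if feature not in ("exon", "CDS"):
                continue
            m = _GTF_TX_RE.search(f[8])
            if not m:
                raise FormatError("GTF feature without transcript_id")
            tid = m.group(1)
            rec = exons.setdefault(tid, {"contig": f[0], "strand": f[6],
                                         "exons": [], "cds": []})
            iv = (int(f[3]) - 1, int(f[4]))  # GTF is 1-based inclusive
            rec["exons" if feature == "exon" else "cds"].append(iv)
    out = []
    for tid, rec in exons.items():
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        try:
            out.append(TranscriptModel(name=tid, contig=rec["contig"],
                                       strand=rec["strand"],
                                       exons=rec["exons"], cds=cds))
        except FormatError as exc:
            warnings.warn(f"transcript {tid!r} rejected: {exc}")
    return out


def read_transcripts(path) -> List[TranscriptModel]:
    """Read transcript models from BED12 or GTF (auto-detected)."""
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    fields = first.rstrip("\n").split("\t")
    if len(fields) >= 9 and "transcript_id" in fields[-1]:
        return _read_gtf(path)
    return _read_bed12(path)


def write_transcripts_bed12(transcripts: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            start = tx.exons[0][0]
            end = tx.exons[-1][1]
            thick = tx.cds if tx.cds is not None else (start, start)
            sizes = ",".join(str(e - s) for s, e in tx.exons) + ","
            offs = ",".join(str(s - start) for s, e in tx.exons) + ","
            fh.write("\t".join(map(str, [
                tx.contig, start, end, tx.name, 0, tx.strand,
                thick[0], thick[1], 0, len(tx.exons), sizes, offs])) + "\n")


# ---------------------------------------------------------------------------
# Site tables (BED6+)
# ---------------------------------------------------------------------------

_SITE_STAT_COLUMNS = ["log2fc", "pvalue", "padj", "mean_rml"]


def _bed_score(padj: float) -> int:
    """Phred-like score column: -10 log10(padj), capped at 1000."""
    if padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return 0
    if padj <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(padj))))


def write_sites(sites: pd.DataFrame, path,
                header_lines: Sequence[str] = ()) -> None:
    """Write site calls as BED6+ (chrom, start, end, name, score, strand,
    then any statistic columns present).

    ``sites`` needs columns contig/strand/position and optionally site_id
    plus statistics. Output is sorted by (contig, position, strand); the
    score column is -10*log10(padj) capped at 1000.
    """
    df = sites.copy()
    if "site_id" not in df.columns:
        df["site_id"] = [site_key(c, p, s) for c, p, s
                         in zip(df["contig"], df["position"], df["strand"])]
    df = df.sort_values(["contig", "position", "strand"], kind="mergesort")
    extra = [c for c in df.columns
             if c not in ("contig", "strand", "position", "site_id")]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("#chrom\tchromStart\tchromEnd\tname\tscore\tstrand"
                 + ("\t" + "\t".join(extra) if extra else "") + "\n")
        for _, row in df.iterrows():
            padj = row["padj"] if "padj" in df.columns else float("nan")
            rec = [row["contig"], int(row["position"]), int(row["position"]) + 1,
                   row["site_id"], _bed_score(padj), row["strand"]]
            rec += [row[c] for c in extra]
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_sites(path) -> pd.DataFrame:
    """Read a BED6+ site table written by :func:`write_sites` (leading
    provenance comment lines are skipped)."""
    with open(path) as fh:
        header = ""
        while True:
            line = fh.readline()
            if not line:
                break
            if line.startswith("#chrom"):
                header = line.rstrip("\n")
                break
            if not line.startswith("#"):
                raise FormatError(f"{path}: missing BED6+ #chrom header line")
        if not header:
            raise FormatError(f"{path}: missing BED6+ header line")
        cols = header.lstrip("#").split("\t")
        df = pd.read_csv(fh, sep="\t", names=cols, header=None)
    if df.empty:
        return pd.DataFrame(columns=["contig", "position", "strand", "site_id"])
    out = pd.DataFrame({
        "contig": df["chrom"].astype(str),
        "position": df["chromStart"].astype(int),
        "strand": df["strand"].astype(str),
        "site_id": df["name"].astype(str),
    })
    for c in cols[6:]:
        out[c] = df[c]
    if not (df["chromEnd"].astype(int) == out["position"] + 1).all():
        raise FormatError(f"{path}: site intervals must be single-base")
    return out


def read_tss_bed(path) -> pd.DataFrame:
    """Read a strand-annotated TSS list (BED6, single-base intervals)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError("TSS BED requires 6 columns incl. strand")
            start, end, strand = int(f[1]), int(f[2]), f[5]
            pos = start if strand == "+" else end - 1
            rows.append((f[0], strand, pos))
    return pd.DataFrame(rows, columns=["contig", "strand", "position"])


# ---------------------------------------------------------------------------
# Aligned-read tables (TSV)
# ---------------------------------------------------------------------------

def read_aligned_table(path) -> pd.DataFrame:
    """Read a TSV of aligned, UMI-tagged read pairs.

    Columns: contig, strand, start, end, umi, replicate, library. ``start``
    and ``end`` are the genomic half-open fragment interval; the read-start
    (strand-aware 5' base) is ``start`` on + and ``end - 1`` on -. Rows with
    UMIs violating the N7B pattern are dropped with a warning; an unknown
    library label is a format error.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"contig": str, "strand": str, "umi": str,
                            "replicate": str, "library": str})
    missing = [c for c in ALIGNED_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad_lib = set(df["library"]) - set(LIBRARY_TYPES)
    if bad_lib:
        raise FormatError(
            f"{path}: unknown library labels {sorted(bad_lib)}; "
            f"expected one of {LIBRARY_TYPES}")
    ok = df["umi"].str.match(UMI_PATTERN)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} rows with invalid N7B UMIs")
        df = df[ok]
    df = df.reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: rows with start >= end")
    return df[ALIGNED_TABLE_COLUMNS]


def write_aligned_table(reads: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        reads.to_csv(fh, sep="\t", index=False, columns=ALIGNED_TABLE_COLUMNS)
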