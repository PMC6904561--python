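"""Downstream site-set analyses: metagene profiles, TSS alignment,
overlap significance, ROC of demethylase-regulated sites, and a
position-frequency-matrix consensus summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from m6ace.errors import AnalysisError, M6aceError
from m6ace.io import ReferenceSet, SiteRecord, TranscriptModel

SEGMENTS = ("5'UTR", "CDS", "3'UTR")


@dataclass
class MetageneProfile:
    """Site density along the scaled 5'UTR | CDS | 3'UTR metagene axis."""

    densities: np.ndarray           # length 3 * bins_per_segment, sums to 1
    bins_per_segment: int
    n_sites: int                    # sites contributing to the profile
    n_excluded: int                 # intronic / non-coding-only sites

    def segment_density(self, segment: str) -> float:
        i = SEGMENTS.index(segment)
        b = self.bins_per_segment
        return float(self.densities[i * b:(i + 1) * b].sum())


def _site_metagene_coord(site: SiteRecord,
                         transcripts: Sequence[TranscriptModel]) -> Optional[float]:
    """Scaled metagene coordinate in [0, 3): segment index + within-segment
    fraction. None when the site maps to no coding transcript's exons.
    Multi-transcript sites resolve to the longest-CDS transcript."""
    best = None  # (cds_len, t, cds_interval)
    for tx in transcripts:
        if tx.contig != site.contig or tx.strand != site.strand or tx.cds is None:
            continue
        t = tx.genomic_to_transcript(site.position)
        if t is None:
            continue
        ci = tx.cds_transcript_interval()
        cds_len = ci[1] - ci[0]
        if best is None or cds_len > best[0]:
            best = (cds_len, t, ci, tx.length)
    if best is None:
        return None
    _, t, (cs, ce), length = best
    if t < cs:
        seg, lo, hi = 0, 0, cs
    elif t < ce:
        seg, lo, hi = 1, cs, ce
    else:
        seg, lo, hi = 2, ce, length
    width = max(hi - lo, 1)
    return seg + (t - lo) / width


def metagene_profile(sites: Sequence[SiteRecord],
                     transcripts: Sequence[TranscriptModel],
                     bins_per_segment: int = 100) -> MetageneProfile:
    """Pooled metagene distribution of sites over coding transcripts.

    Each site is placed in the transcript region containing it (5'UTR, CDS
    or 3'UTR of the longest-CDS transcript covering it), scaled to [0, 1)
    within that segment, and binned on the concatenated axis. Sites mapping
    only to introns or non-coding transcripts are excluded and counted.
    """
    hist = np.zeros(3 * bins_per_segment)
    n_used = n_excluded = 0
    for site in sites:
        coord = _site_metagene_coord(site, transcripts)
        if coord is None:
            n_excluded += 1
            continue
        hist[min(int(coord * bins_per_segment), hist.size - 1)] += 1
        n_used += 1
    if n_used == 0:
        raise AnalysisError("no sites mappable to coding transcripts")
    return MetageneProfile(densities=hist / hist.sum(),
                           bins_per_segment=bins_per_segment,
                           n_sites=n_used, n_excluded=n_excluded)


def tss_alignment(sites: Sequence[SiteRecord], tss_list: pd.DataFrame,
                  max_offset: int = 5) -> pd.Series:
    """Histogram of strand-aware offsets from each site to its nearest
    same-contig/strand TSS.

    Offsets follow transcription (+2 means 2 nt 3' of the TSS); sites with
    no TSS within ``max_offset`` fall in the ``beyond`` bin.
    """
    if tss_list is None or len(tss_list) == 0:
        raise AnalysisError("empty TSS list")
    by_group: Dict[Tuple[str, str], np.ndarray] = {
        key: np.sort(grp["position"].to_numpy(dtype=np.int64))
        for key, grp in tss_list.groupby(["contig", "strand"])}
    labels = list(range(-max_offset, max_offset + 1)) + ["beyond"]
    hist = pd.Series(0, index=labels, dtype=int)
    for site in sites:
        positions = by_group.get((site.contig, site.strand))
        if positions is None or positions.size == 0:
            hist["beyond"] += 1
            continue
        i = np.searchsorted(positions, site.position)
        best = min((p for p in positions[max(i - 1, 0):i + 1]),
                   key=lambda p: abs(int(p) - site.position))
        diff = site.position - int(best)
        offset = diff if site.strand == "+" else -diff
        hist[offset if abs(offset) <= max_offset else "beyond"] += 1
    return hist


@dataclass
class OverlapTest:
    """Upper-tail hypergeometric test of the overlap of two site sets."""

    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float


def overlap_significance(set_a: Iterable, set_b: Iterable,
                         universe: Iterable) -> OverlapTest:
    """P(X >= k) for drawing |B| items from a universe of N containing |A|
    marked items and seeing k = |A n B| marked."""
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise M6aceError("both sets must be subsets of the universe")
    n_univ, k_a, n_b = len(universe), len(a), len(b)
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, n_univ, k_a, n_b))
    return OverlapTest(universe_size=n_univ, size_a=k_a, size_b=n_b,
                       overlap=k, p_value=min(p, 1.0))


@dataclass
class RocResult:
    """ROC of demethylase-regulated status over the WT-padj ranking.

    Sites are ranked most-WT-insignificant first (descending padj); for
    each minimum-LFC stratum the positives are the sites regulated at at
    least that LFC (accumulation p < 0.05). A high AUC means regulated
    sites concentrate among WT-insignificant ones.
    """

    ranking: pd.DataFrame           # site_id, padj, sorted as ranked
    curves: Dict[float, pd.DataFrame]  # stratum -> (fpr, tpr) points
    auc: Dict[float, float]         # stratum -> trapezoidal AUC (nan if undefined)


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> Tuple[pd.DataFrame, float]:
    """ROC points over descending score with ties grouped into one step."""
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0]}), float("nan")
    fpr, tpr = [0.0], [0.0]
    tp = fp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += int(labels[i:j].sum())
        fp += (j - i) - int(labels[i:j].sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    return curve, auc


def roc_regulated_vs_unmethylated(wt_sites: pd.DataFrame,
                                  regulated_calls: pd.DataFrame,
                                  lfc_strata: Sequence[float] = (0.0, 0.5, 1.0, 1.5),
                                  p_cutoff: float = 0.05) -> RocResult:
    """How well demethylase-regulated status predicts steady-state
    unmethylation.

    ``wt_sites``: audit frame of the WT condition with ``site_id``,
    ``padj`` and ``filter_status`` columns (the tested candidate universe).
    ``regulated_calls``: differential frame (accumulation direction) with
    ``site_id``, ``lfc`` and ``pvalue``. The ranked universe is the WT pass
    set united with all accumulated sites (accumulation LFC >= 0, p <
    cutoff); sites absent from the WT test carry padj = 1. Ranking is by
    descending WT padj with ties grouped; site id breaks ties
    deterministically in the stored ranking.
    """
    acc = regulated_calls[(regulated_calls["pvalue"] < p_cutoff)
                          & (regulated_calls["lfc"] >= 0.0)]
    wt_pass = set(wt_sites.loc[wt_sites["filter_status"] == "pass", "site_id"])
    universe = sorted(wt_pass | set(acc["site_id"]))
    if not universe:
        raise AnalysisError("empty ROC universe")
    padj = pd.Series(1.0, index=universe)
    known = wt_sites.set_index("site_id")["padj"]
    shared = padj.index.intersection(known.index)
    padj.loc[shared] = known.loc[shared].astype(float)
    ranking = (pd.DataFrame({"site_id": universe, "padj": padj.to_numpy()})
                 .sort_values(["padj", "site_id"], ascending=[False, True],
                              kind="mergesort")
                 .reset_index(drop=True))
    lfc = acc.set_index("site_id")["lfc"]
    curves: Dict[float, pd.DataFrame] = {}
    aucs: Dict[float, float] = {}
    scores = ranking["padj"].to_numpy(dtype=float)
    for stratum in lfc_strata:
        pos_ids = set(lfc[lfc >= stratum].index)
        labels = ranking["site_id"].isin(pos_ids).to_numpy()
        curves[stratum], aucs[stratum] = _roc_curve(scores, labels)
    return RocResult(ranking=ranking, curves=curves, auc=aucs)


_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AC"): "M", frozenset("AG"): "R",
    frozenset("AT"): "W", frozenset("CG"): "S", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def consensus_pfm(sites: Sequence[SiteRecord], reference: ReferenceSet,
                  flank: int = 5,
                  min_freq: float = 0.25) -> Tuple[pd.DataFrame, str]:
    """Strand-aware position frequency matrix around sites plus an IUPAC
    consensus (bases at frequency >= ``min_freq`` per column).

    Offset 0 is the site itself (always A by construction). Sites whose
    flanks run off the contig are skipped and counted via a warning-free
    return; an empty usable set is an error.
    """
    offsets = list(range(-flank, flank + 1))
    counts = pd.DataFrame(0, index=list("ACGT"), columns=offsets, dtype=float)
    n_used = 0
    for site in sites:
        bases = [reference.base_at_offset(site.contig, site.position,
                                          site.strand, o) for o in offsets]
        if any(b not in "ACGT" or b == "" for b in bases):
            continue
        for o, b in zip(offsets, bases):
            counts.loc[b, o] += 1
        n_used += 1
    if n_used == 0:
        raise AnalysisError("no site with complete flanks on the reference")
    pfm = counts / n_used
    consensus = "".join(
        _IUPAC[frozenset(pfm.index[pfm[o] >= min_freq])]
        if (pfm[o] >= min_freq).any() else
        _IUPAC[frozenset([pfm[o].idxmax()])]
        for o in offsets)
    return pfm, consensus
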