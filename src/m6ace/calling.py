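"""Significant-site identification: m6ACE-vs-input enrichment plus
false-positive filters.

A position is called when its read-start count in the antibody (m6ACE)
libraries is at least ``min_fold`` enriched over the matched input
libraries, with a negative-binomial Wald test adjusted by Benjamini-
Hochberg (padj < 0.05 at default). Two artefact filters follow:

* shadow filter -- exonuclease stoppage is imperfect, leaving a mild pileup
  of read-starts 3-4 nt 5' of genuine sites; an enriched site 1-4 nt
  upstream (5') of another enriched site in an R-A-C context is removed.
* cluster filter -- loci where read-starts form a diffuse cluster rather
  than a single-base pileup are removed: many distinct start positions in
  the surrounding window and no dominance of the site's own position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from m6ace.errors import AnalysisError, M6aceError
from m6ace.io import ReferenceSet, site_key
from m6ace.readstarts import ReadStartTable, candidate_positions, collate_read_starts, deduplicate

PASS = "pass"
NOT_ENRICHED = "not_enriched"
SHADOW = "shadow_filtered"
CLUSTER = "cluster_filtered"


@dataclass
class EnrichmentConfig:
    """Thresholds for enrichment testing and artefact filtering.

    ``min_fold``/``padj_cutoff`` are the published call thresholds
    (2-fold, padj < 0.05); ``fdr`` records the BH family-wise target. The
    cluster-filter constants are this implementation's own calibration --
    the underlying observation ("clustered read-starts are false
    positives") carries no published numbers -- and are deliberately
    exposed here.
    """

    min_fold: float = 2.0
    padj_cutoff: float = 0.05
    fdr: float = 0.1
    min_mean: float = 1.0
    pseudocount: float = 0.5
    dispersion_shrinkage: float = 0.5
    min_dispersion: float = 1e-8
    shadow_max_offset: int = 4
    cluster_window: int = 10
    cluster_max_distinct_starts: int = 10
    cluster_dominance: float = 0.5

    def __post_init__(self) -> None:
        if self.min_fold < 1:
            raise M6aceError("min_fold must be >= 1")
        for name in ("padj_cutoff", "fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise M6aceError(f"{name} must lie in (0, 1)")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (computed across the candidate
    sites), falling back to total-count ratios when no row has all-positive
    counts."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.isfinite(logs).all(axis=1)
    if finite.any():
        loggeo = logs[finite].mean(axis=1)
        sf = np.exp(np.median(logs[finite] - loggeo[:, None], axis=0))
    else:
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise AnalysisError("cannot derive size factors: empty library column")
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=counts.columns)


def _mom_dispersion(q: np.ndarray, inv_s_mean: float, groups) -> np.ndarray:
    """Per-site method-of-moments NB dispersion from normalised counts,
    pooled over the two library groups."""
    num = np.zeros(q.shape[0])
    den = 0.0
    for idx in groups:
        sub = q[:, idx]
        n = sub.shape[1]
        if n < 2:
            continue
        mu = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - inv_s_mean * mu) / np.square(mu)
        a = np.where(np.isfinite(a), a, 0.0)
        num += (n - 1) * a
        den += n - 1
    if den == 0:
        raise AnalysisError("need >= 2 replicates per library type")
    return num / den


def test_enrichment(candidates: pd.DataFrame,
                    config: Optional[EnrichmentConfig] = None,
                    library_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Negative-binomial Wald test of m6ACE over input at candidate positions.

    ``candidates`` is a count DataFrame indexed by (contig, strand,
    position) with (replicate, library) columns, as produced by
    :func:`m6ace.readstarts.candidate_positions`. Per-site dispersions are
    method-of-moments estimates shrunk halfway toward the trimmed-mean
    dispersion across sites; the one-sided Wald p-value tests enrichment
    only. Reported log2 fold changes add ``pseudocount`` to both normalised
    group means (reporting only, not the test).

    Normalisation uses median-of-ratios size factors computed across the
    candidate sites; passing ``library_sizes`` (e.g. total deduplicated
    reads per column) overrides this with factors proportional to the given
    sizes.

    Returns a site-indexed frame with counts, log2fc, pvalue, padj,
    ``enriched`` and an initial ``filter_status``.
    """
    cfg = config or EnrichmentConfig()
    if candidates.empty:
        raise AnalysisError("no candidate sites to test")
    cols = list(candidates.columns)
    m6_idx = [i for i, c in enumerate(cols) if c[1] == "m6ACE"]
    in_idx = [i for i, c in enumerate(cols) if c[1] == "input"]
    if len(m6_idx) < 2 or len(in_idx) < 2:
        raise AnalysisError("need >= 2 replicates per library type")

    k = candidates.to_numpy(dtype=float)
    if library_sizes is not None:
        sizes = library_sizes.reindex(candidates.columns).to_numpy(dtype=float)
        if (sizes <= 0).any() or np.isnan(sizes).any():
            raise AnalysisError("library sizes must be positive for all columns")
        sf = sizes / np.exp(np.mean(np.log(sizes)))
    else:
        sf = size_factors(candidates).to_numpy()
    q = k / sf
    s1, s0 = sf[m6_idx].sum(), sf[in_idx].sum()
    q1 = k[:, m6_idx].sum(axis=1) / s1
    q0 = k[:, in_idx].sum(axis=1) / s0

    alpha = _mom_dispersion(q, float(np.mean(1.0 / sf)), [m6_idx, in_idx])
    alpha = np.maximum(alpha, cfg.min_dispersion)
    centre = stats.trim_mean(alpha, 0.125) if len(alpha) > 1 else alpha[0]
    w = cfg.dispersion_shrinkage
    alpha = np.maximum(w * alpha + (1 - w) * max(centre, cfg.min_dispersion),
                       cfg.min_dispersion)

    # Wald statistic: beta = ln(q1/q0), Fisher information from the NB
    # variance function Var(K_ij) = mu_ij + alpha mu_ij^2 with mu_ij = s_j q.
    q0_t = np.where(q0 > 0, q0, cfg.pseudocount / s0)
    q1_t = np.where(q1 > 0, q1, cfg.pseudocount / s1)
    beta = np.log(q1_t) - np.log(q0_t)

    def info(qg: np.ndarray, idx) -> np.ndarray:
        mu = qg[:, None] * sf[idx][None, :]
        return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)

    se = np.sqrt(1.0 / info(q1_t, m6_idx) + 1.0 / info(q0_t, in_idx))
    z = beta / se
    pvalue = stats.norm.sf(z)
    pvalue = np.where(q1 > 0, pvalue, 1.0)

    log2fc = np.log2((q1 + cfg.pseudocount) / (q0 + cfg.pseudocount))
    padj = multipletests(pvalue, method="fdr_bh")[1]
    enriched = (log2fc >= np.log2(cfg.min_fold)) & (padj < cfg.padj_cutoff)

    idx = candidates.index
    out = pd.DataFrame({
        "contig": idx.get_level_values("contig"),
        "strand": idx.get_level_values("strand"),
        "position": idx.get_level_values("position").astype(int),
    })
    out["site_id"] = [site_key(c, p, s) for c, p, s
                      in zip(out["contig"], out["position"], out["strand"])]
    for j, (rep, lib) in enumerate(cols):
        out[f"{rep}.{lib}"] = k[:, j].astype(int)
    out["base_mean_m6ace"] = q1
    out["base_mean_input"] = q0
    out["dispersion"] = alpha
    out["log2fc"] = log2fc
    out["pvalue"] = pvalue
    out["padj"] = padj
    out["enriched"] = enriched
    out["shadow_flag"] = False
    out["cluster_flag"] = False
    out["filter_status"] = np.where(enriched, PASS, NOT_ENRICHED)
    out = out.set_index("site_id", drop=False)
    out.index.name = None
    return out


def _is_rac(reference: ReferenceSet, contig: str, position: int, strand: str) -> bool:
    """Strand-aware R-A-C context check (R = A/G) centred on ``position``."""
    return (reference.base_at_offset(contig, position, strand, -1) in ("A", "G")
            and reference.base_at_offset(contig, position, strand, 0) == "A"
            and reference.base_at_offset(contig, position, strand, +1) == "C")


def filter_shadow_sites(sites: pd.DataFrame, reference: ReferenceSet,
                        config: Optional[EnrichmentConfig] = None) -> pd.DataFrame:
    """Flag enriched sites sitting 1-4 nt 5' of another enriched site whose
    sequence context is R-A-C (imperfect exonuclease stoppage shadows)."""
    cfg = config or EnrichmentConfig()
    out = sites.copy()
    enriched = out[out["enriched"]]
    by_group: Dict[Tuple[str, str], Set[int]] = {}
    for contig, strand, pos in zip(enriched["contig"], enriched["strand"],
                                   enriched["position"]):
        by_group.setdefault((contig, strand), set()).add(int(pos))
    flag = []
    for _, row in out.iterrows():
        if not row["enriched"]:
            flag.append(False)
            continue
        contig, strand, pos = row["contig"], row["strand"], int(row["position"])
        step = 1 if strand == "+" else -1
        hit = False
        for d in range(1, cfg.shadow_max_offset + 1):
            t = pos + step * d  # strand-aware downstream (3') neighbour
            if t in by_group.get((contig, strand), ()) and _is_rac(reference, contig, t, strand):
                hit = True
                break
        flag.append(hit)
    out["shadow_flag"] = flag
    return _refresh_status(out)


def filter_clustered_noise(sites: pd.DataFrame, full_table: ReadStartTable,
                           config: Optional[EnrichmentConfig] = None) -> pd.DataFrame:
    """Flag enriched sites embedded in diffuse read-start clusters.

    Within +/- ``cluster_window`` of the site in the pooled m6ACE full
    table, a site is noise when more than ``cluster_max_distinct_starts``
    positions carry reads AND the site's own position holds less than
    ``cluster_dominance`` of the pooled window counts.
    """
    cfg = config or EnrichmentConfig()
    out = sites.copy()
    m6_cols = [i for i, c in enumerate(full_table.counts.columns) if c[1] == "m6ACE"]
    flag = []
    for _, row in out.iterrows():
        if not row["enriched"]:
            flag.append(False)
            continue
        contig, strand, pos = row["contig"], row["strand"], int(row["position"])
        positions, mat = full_table._group_arrays(contig, strand)
        i = np.searchsorted(positions, pos - cfg.cluster_window, side="left")
        j = np.searchsorted(positions, pos + cfg.cluster_window, side="right")
        pooled = mat[i:j][:, m6_cols].sum(axis=1)
        distinct = int((pooled > 0).sum())
        total = float(pooled.sum())
        own_idx = np.searchsorted(positions[i:j], pos)
        own = float(pooled[own_idx]) if (own_idx < j - i
                                         and positions[i:j][own_idx] == pos) else 0.0
        flag.append(distinct > cfg.cluster_max_distinct_starts
                    and total > 0 and own < cfg.cluster_dominance * total)
    out["cluster_flag"] = flag
    return _refresh_status(out)


def _refresh_status(sites: pd.DataFrame) -> pd.DataFrame:
    status = np.where(~sites["enriched"], NOT_ENRICHED,
                      np.where(sites["shadow_flag"], SHADOW,
                               np.where(sites["cluster_flag"], CLUSTER, PASS)))
    sites["filter_status"] = status
    return sites


def call_sites(reads: pd.DataFrame, reference: ReferenceSet,
               config: Optional[EnrichmentConfig] = None,
               deduplicated: bool = False):
    """Full calling pipeline: deduplicate -> collate -> candidate filter ->
    enrichment test -> shadow filter -> cluster filter.

    Returns ``(passed, audit, full_table)``: the pass-only site frame, the
    full audit frame with per-stage flags, and the full read-start table.
    """
    cfg = config or EnrichmentConfig()
    if not deduplicated:
        reads = deduplicate(reads)
    full = collate_read_starts(reads, reference)
    cand = candidate_positions(full, reference, min_mean=cfg.min_mean)
    audit = test_enrichment(cand, cfg)
    audit = filter_shadow_sites(audit, reference, cfg)
    audit = filter_clustered_noise(audit, full, cfg)
    audit = audit.sort_values(["contig", "position", "strand"], kind="mergesort")
    passed = audit[audit["filter_status"] == PASS]
    return passed, audit, full
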