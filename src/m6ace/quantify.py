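"""Spike-in-normalised methylation stoichiometry (RML) and differential
methylation between conditions.

For each site and replicate,

    X   = m6ACE read-starts summed over offsets -4..0 at the site
          / input read-starts summed over offsets -51..0 at the site
    Y   = the same ratio at the spike-in's methylated site, with the
          input window -21..0 (the spike-in oligo is short)
    RML = X / Y

The spike-in is present at the same mass in every library and is fully
methylated, so dividing by Y cancels crosslinking/IP/exonuclease
efficiency; RML is proportional to the methylated fraction of transcripts
at the site. Differential methylation compares per-replicate RML between
two conditions with a one-tailed t-test in a declared direction (reduction
on writer loss, accumulation on eraser loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from m6ace.errors import AnalysisError, M6aceError
from m6ace.io import SiteRecord
from m6ace.readstarts import ReadStartTable

SITE_M6ACE_WINDOW = (-4, 0)
SITE_INPUT_WINDOW = (-51, 0)
SPIKE_INPUT_WINDOW = (-21, 0)

REDUCTION = "reduction"
ACCUMULATION = "accumulation"
DEFAULT_LFC_CUTOFF = {REDUCTION: 2.0, ACCUMULATION: 1.0}

DEPENDENT = "dependent"
REGULATED = "regulated"
INDEPENDENT = "independent"
UNTESTABLE = "untestable"

_EPS = 1e-6  # pseudo-RML guarding the log2 of condition means


@dataclass
class RMLRecord:
    """Per-replicate X, Y and RML for one site, plus the condition mean.

    Replicates with a zero denominator carry NaN (undefined), never 0; the
    mean is taken over defined replicates only.
    """

    site_id: str
    replicates: List[str]
    x: np.ndarray
    y: np.ndarray
    rml: np.ndarray

    @property
    def mean_rml(self) -> float:
        defined = self.rml[np.isfinite(self.rml)]
        return float(defined.mean()) if defined.size else float("nan")

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.rml).sum())


def _spike_ratio(full_table: ReadStartTable, spike_site: SiteRecord,
                 replicates: Sequence[str]) -> np.ndarray:
    num = full_table.window_sums(spike_site.contig, spike_site.strand,
                                 spike_site.position, SITE_M6ACE_WINDOW)
    den = full_table.window_sums(spike_site.contig, spike_site.strand,
                                 spike_site.position, SPIKE_INPUT_WINDOW)
    y = np.empty(len(replicates))
    for i, rep in enumerate(replicates):
        n = float(num.get((rep, "m6ACE"), 0.0))
        d = float(den.get((rep, "input"), 0.0))
        if n <= 0 or d <= 0:
            raise AnalysisError(
                f"spike-in read-starts missing in replicate {rep!r}; the "
                "spike-in is mandatory for RML")
        y[i] = n / d
    return y


def compute_rml(site: SiteRecord, full_table: ReadStartTable,
                spike_site: SiteRecord,
                spike_y: Optional[np.ndarray] = None) -> RMLRecord:
    """RML of one site across all replicates of the table.

    ``spike_y`` lets callers precompute the per-replicate spike ratio when
    quantifying many sites against the same table.
    """
    reps = full_table.replicates
    y = spike_y if spike_y is not None else _spike_ratio(full_table, spike_site, reps)
    num = full_table.window_sums(site.contig, site.strand, site.position,
                                 SITE_M6ACE_WINDOW)
    den = full_table.window_sums(site.contig, site.strand, site.position,
                                 SITE_INPUT_WINDOW)
    x = np.empty(len(reps))
    for i, rep in enumerate(reps):
        d = float(den.get((rep, "input"), 0.0))
        x[i] = float(num.get((rep, "m6ACE"), 0.0)) / d if d > 0 else np.nan
    return RMLRecord(site_id=site.site_id, replicates=list(reps),
                     x=x, y=np.asarray(y, dtype=float), rml=x / y)


def rml_table(sites: Sequence[SiteRecord], full_table: ReadStartTable,
              spike_site: SiteRecord) -> pd.DataFrame:
    """Per-replicate RML for many sites; one row per site, one ``rml.<rep>``
    column per replicate plus the condition mean."""
    reps = full_table.replicates
    y = _spike_ratio(full_table, spike_site, reps)
    rows = []
    for site in sites:
        rec = compute_rml(site, full_table, spike_site, spike_y=y)
        row = {"site_id": rec.site_id, "contig": site.contig,
               "strand": site.strand, "position": site.position}
        for rep, xv, rv in zip(reps, rec.x, rec.rml):
            row[f"x.{rep}"] = xv
            row[f"rml.{rep}"] = rv
        row["mean_rml"] = rec.mean_rml
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id", drop=False).rename_axis(None)


@dataclass
class DifferentialCall:
    """One site's condition comparison.

    ``lfc`` is oriented by ``direction`` so that a called site always has a
    positive value: log2(mean_A / mean_B) for reductions (condition A is
    the reference, e.g. WT vs writer-KO) and log2(mean_B / mean_A) for
    accumulations (eraser-KO).
    """

    site_id: str
    direction: str
    lfc: float
    pvalue: float
    category: str
    mean_a: float = float("nan")
    mean_b: float = float("nan")


def differential_methylation(rml_a: Sequence[float], rml_b: Sequence[float],
                             direction: str,
                             lfc_cutoff: Optional[float] = None,
                             p_cutoff: float = 0.05,
                             equal_var: bool = False,
                             site_id: str = "") -> DifferentialCall:
    """Compare per-replicate RML between reference condition A and
    perturbed condition B.

    A one-tailed two-sample t-test (Welch by default) is run in the stated
    direction; the site is called ``dependent`` (reduction, default LFC
    cutoff 2.0) or ``regulated`` (accumulation, default cutoff 1.0) when
    both the LFC and p-value thresholds are met. Fewer than two defined
    replicate RMLs in either condition makes the site ``untestable``.
    """
    if direction not in (REDUCTION, ACCUMULATION):
        raise M6aceError(f"unknown direction {direction!r}")
    if lfc_cutoff is None:
        lfc_cutoff = DEFAULT_LFC_CUTOFF[direction]
    a = np.asarray(rml_a, dtype=float)
    b = np.asarray(rml_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return DifferentialCall(site_id, direction, float("nan"), float("nan"),
                                UNTESTABLE)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if direction == REDUCTION:
        lfc = float(np.log2((mean_a + _EPS) / (mean_b + _EPS)))
        alternative = "greater"  # reference mean larger: RML fell in B
    else:
        lfc = float(np.log2((mean_b + _EPS) / (mean_a + _EPS)))
        alternative = "less"     # perturbed mean larger: RML accumulated in B
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(a, b, equal_var=equal_var,
                            alternative=alternative).pvalue
    p = float(p) if np.isfinite(p) else 1.0
    called = lfc >= lfc_cutoff and p < p_cutoff
    if called:
        category = DEPENDENT if direction == REDUCTION else REGULATED
    else:
        category = INDEPENDENT
    return DifferentialCall(site_id, direction, lfc, p, category,
                            mean_a=mean_a, mean_b=mean_b)


def differential_table(rml_a: pd.DataFrame, rml_b: pd.DataFrame,
                       direction: str, lfc_cutoff: Optional[float] = None,
                       p_cutoff: float = 0.05,
                       equal_var: bool = False) -> pd.DataFrame:
    """Site-wise differential calls from two :func:`rml_table` frames
    (joined on site_id; sites absent from either side are skipped)."""
    reps_a = [c for c in rml_a.columns if c.startswith("rml.")]
    reps_b = [c for c in rml_b.columns if c.startswith("rml.")]
    common = rml_a.index.intersection(rml_b.index)
    rows = []
    for sid in common:
        call = differential_methylation(
            rml_a.loc[sid, reps_a].to_numpy(dtype=float),
            rml_b.loc[sid, reps_b].to_numpy(dtype=float),
            direction, lfc_cutoff=lfc_cutoff, p_cutoff=p_cutoff,
            equal_var=equal_var, site_id=str(sid))
        rows.append({"site_id": call.site_id, "direction": call.direction,
                     "mean_rml_a": call.mean_a, "mean_rml_b": call.mean_b,
                     "lfc": call.lfc, "pvalue": call.pvalue,
                     "category": call.category})
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.set_index("site_id", drop=False).rename_axis(None)
    return out


@dataclass
class MixingSeries:
    """Pooled linear fit of normalised RML against WT fraction."""

    slope: float
    intercept: float
    r_squared: float
    n_sites: int
    points: pd.DataFrame  # columns: site_id, wt_fraction, normalised_rml


def mixing_linearity(mean_rml: pd.DataFrame) -> MixingSeries:
    """Linearity of RML across WT/KO mixtures.

    ``mean_rml``: rows = sites, columns = WT fractions in [0, 1] (floats),
    values = per-condition mean RML. Each site's series is normalised to
    its value in the 100% WT condition; all site-level points are pooled
    into one least-squares regression on the WT fraction.
    """
    fractions = [float(c) for c in mean_rml.columns]
    if len(set(fractions)) < 3:
        raise AnalysisError("mixing series needs >= 3 distinct WT fractions")
    if not any(np.isclose(f, 1.0) for f in fractions):
        raise AnalysisError("mixing series requires the 100% WT condition")
    wt_col = mean_rml.columns[int(np.argmin(np.abs(np.array(fractions) - 1.0)))]
    wt = mean_rml[wt_col].to_numpy(dtype=float)
    usable = np.isfinite(wt) & (wt > 0)
    if not usable.any():
        raise AnalysisError("no site has defined RML in the 100% WT condition")
    norm = mean_rml.loc[usable].div(mean_rml.loc[usable, wt_col], axis=0)
    pts = (norm.rename_axis("site_id")
               .reset_index()
               .melt(id_vars="site_id", var_name="wt_fraction",
                     value_name="normalised_rml"))
    pts["wt_fraction"] = pts["wt_fraction"].astype(float)
    pts = pts[np.isfinite(pts["normalised_rml"])]
    if pts["wt_fraction"].nunique() < 3:
        raise AnalysisError("fewer than 3 fractions with defined RML")
    fit = stats.linregress(pts["wt_fraction"], pts["normalised_rml"])
    return MixingSeries(slope=float(fit.slope), intercept=float(fit.intercept),
                        r_squared=float(fit.rvalue ** 2),
                        n_sites=int(usable.sum()), points=pts.reset_index(drop=True))
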