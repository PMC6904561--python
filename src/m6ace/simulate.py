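"""Generative simulator for m6ACE-seq experiments.

Emulates, per replicate and condition, the two library types the method
compares:

* m6ACE library -- methylated fragments are antibody-captured with a
  configurable efficiency; exonuclease digestion stops at the protected
  base, so the fragment 5' end lands exactly on the site with most of the
  probability mass, with a minor spillover 3-4 nt 5' of it (imperfect
  stoppage, the source of "shadow" artefacts). A low uniform nonspecific
  background and occasional diffuse read-start clusters (noise loci) are
  added.
* input library -- uniform random fragmentation of the same transcripts.

Each transcript lives on its own contig (transcriptome-style alignment)
with a 5'UTR/CDS/3'UTR architecture; a fully methylated 41-nt spike-in
contig (single m6A at 1-based position 21) is present in every library at
fixed depth. PCR duplicates (repeated coordinate+UMI) are injected at a
configurable rate; UMIs follow the N7B layout.

All randomness flows from a single integer seed through named
SeedSequence spawns, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from m6ace.errors import ConfigurationError, M6aceError
from m6ace.io import (ALIGNED_TABLE_COLUMNS, ReferenceSet, SiteRecord,
                      TranscriptModel, site_key)

#: Synthetic spike-in stand-in: 41 nt, single methylated A at 1-based
#: position 21 (0-based 20) in a GGACT (RAC) context. The only other A, at
#: 0-based 17, sits 3 nt 5' of the site so the imperfect-stoppage spillover
#: exercises the shadow filter on every simulated run.
SPIKE_SEQUENCE = "CTGCGTCCGGTTCGTC" + "TA" + "GGACT" + "CGTCCGGTCGTTCGGTCC"
SPIKE_SITE_POSITION = 20  # 0-based

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B_BASES = np.frombuffer(b"CGT", dtype=np.uint8)

DRACH_D = set("AGT")
DRACH_R = set("AG")
DRACH_H = set("ACT")


@dataclass
class SimConfig:
    """Study conditions for the generative model.

    Depths and replicate structure mirror a triplicate m6ACE/input design;
    the exonuclease stop profile places most mass exactly at the site with
    a minor 3-4 nt 5' spillover. Capture efficiency and the stop profile
    are declared model assumptions (not published quantities).
    """

    seed: int
    n_transcripts: int = 30
    replicates: int = 3
    utr5_length: Tuple[int, int] = (60, 150)
    cds_length: Tuple[int, int] = (300, 900)
    utr3_length: Tuple[int, int] = (150, 450)
    minus_strand_fraction: float = 0.5
    methyl_fraction: float = 0.1          # fraction of DRACH motifs methylated
    stoichiometry_range: Tuple[float, float] = (0.3, 1.0)
    min_site_separation: int = 10         # nt between planted sites
    m6ace_depth: int = 100                # expected captured reads per fully methylated site
    capture_efficiency: float = 0.9
    stop_profile: Dict[int, float] = field(
        default_factory=lambda: {0: 0.85, -3: 0.075, -4: 0.075})
    input_rate: float = 2.0               # input read starts per nt per replicate
    m6ace_background_rate: float = 0.3    # nonspecific m6ACE starts per nt per replicate
    n_noise_loci: int = 5
    noise_reads: int = 60                 # m6ACE reads per noise locus per replicate
    noise_span: int = 10                  # cluster half-width
    duplication_rate: float = 0.2         # PCR duplicate fraction of final reads
    read_length: int = 75
    spike_name: str = "spike"
    spike_m6ace_depth: int = 300
    spike_input_reads: int = 500
    tss_m6am: bool = False                # additionally plant cap-adjacent sites at TSSs

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        total = sum(self.stop_profile.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError(f"stop profile mass sums to {total}, not 1")
        if not 0 <= self.duplication_rate < 0.5:
            raise ConfigurationError("duplication_rate must lie in [0, 0.5)")
        for p in (self.capture_efficiency, self.methyl_fraction,
                  self.minus_strand_fraction):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"probability {p} outside [0, 1]")

    def spike_site(self) -> SiteRecord:
        return SiteRecord(contig=self.spike_name, strand="+",
                          position=SPIKE_SITE_POSITION)


@dataclass
class TrueMethylome:
    """Ground-truth site stoichiometries per condition.

    ``sites`` holds one row per planted site; ``stoichiometry`` is indexed
    by site_id with one column per condition label.
    """

    sites: pd.DataFrame                # contig, strand, position, site_id
    stoichiometry: pd.DataFrame        # index site_id, columns = conditions

    @property
    def conditions(self) -> List[str]:
        return list(self.stoichiometry.columns)

    def condition(self, name: str) -> pd.Series:
        return self.stoichiometry[name]

    def site_records(self) -> List[SiteRecord]:
        return [SiteRecord(contig=r.contig, strand=r.strand,
                           position=int(r.position), site_id=r.site_id)
                for r in self.sites.itertuples(index=False)]

    def with_condition(self, name: str, values: pd.Series) -> "TrueMethylome":
        stoich = self.stoichiometry.copy()
        stoich[name] = values.reindex(stoich.index)
        return TrueMethylome(self.sites, stoich)


def _spawn(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=tuple(path)))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


def simulate_reference(config: SimConfig):
    """Random single-exon transcript contigs plus the spike-in contig.

    Returns ``(ReferenceSet, [TranscriptModel])``; the spike-in carries no
    transcript model. Deterministic under the config seed.
    """
    rng = _spawn(config.seed, 0)
    contigs: Dict[str, str] = {}
    transcripts: List[TranscriptModel] = []
    for i in range(config.n_transcripts):
        u5 = int(rng.integers(*config.utr5_length))
        cds = int(rng.integers(*config.cds_length))
        cds -= cds % 3
        u3 = int(rng.integers(*config.utr3_length))
        length = u5 + cds + u3
        seq = list(_random_seq(rng, length))
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        if config.tss_m6am:
            # cap-adjacent adenosine at the first transcribed base
            if strand == "+":
                seq[0] = "A"
            else:
                seq[-1] = "T"
        name = f"tx{i:04d}"
        contigs[name] = "".join(seq)
        cds_genomic = (u5, u5 + cds) if strand == "+" else (u3, u3 + cds)
        transcripts.append(TranscriptModel(name=name, contig=name,
                                           strand=strand, exons=[(0, length)],
                                           cds=cds_genomic))
    contigs[config.spike_name] = SPIKE_SEQUENCE
    assert SPIKE_SEQUENCE[SPIKE_SITE_POSITION] == "A"
    return ReferenceSet(contigs=contigs, spike_in_name=config.spike_name), transcripts


def _drach_motifs(transcripts: Sequence[TranscriptModel],
                  reference: ReferenceSet) -> pd.DataFrame:
    """All DRACH-context adenosines in transcript (RNA) space, with a
    sampling weight favouring the CDS and stop-proximal region."""
    rows = []
    for tx in transcripts:
        rna = tx.rna_sequence(reference)
        ci = tx.cds_transcript_interval()
        stop = ci[1] if ci else None
        for t in range(2, len(rna) - 2):
            if (rna[t] == "A" and rna[t - 2] in DRACH_D and rna[t - 1] in DRACH_R
                    and rna[t + 1] == "C" and rna[t + 2] in DRACH_H):
                if ci is None:
                    w = 1.0
                elif t < ci[0]:
                    w = 0.5
                elif stop is not None and abs(t - stop) <= 100:
                    w = 3.0
                elif t < ci[1]:
                    w = 1.0
                else:
                    w = 1.5
                rows.append((tx.contig, tx.strand, tx.transcript_to_genomic(t),
                             t, w))
    return pd.DataFrame(rows, columns=["contig", "strand", "position",
                                       "tpos", "weight"])


def simulate_methylome(reference: ReferenceSet,
                       transcripts: Sequence[TranscriptModel],
                       config: SimConfig,
                       condition: str = "WT") -> TrueMethylome:
    """Plant methylated sites on a fraction of DRACH adenosines.

    Selection is weighted toward the CDS/3'UTR stop-proximal region;
    planted sites keep a minimum mutual separation so that genuine sites do
    not shadow one another. Stoichiometries are uniform over the configured
    range. With ``tss_m6am`` set, every transcript also receives a
    cap-adjacent site at its TSS.
    """
    rng = _spawn(config.seed, 1)
    motifs = _drach_motifs(transcripts, reference)
    chosen: List[Tuple[str, str, int]] = []
    if len(motifs) and config.methyl_fraction > 0:
        n_target = int(round(config.methyl_fraction * len(motifs)))
        p = motifs["weight"] / motifs["weight"].sum()
        order = rng.choice(len(motifs), size=len(motifs), replace=False,
                           p=p.to_numpy())
        taken: Dict[str, List[int]] = {}
        for idx in order:
            if len(chosen) >= n_target:
                break
            row = motifs.iloc[idx]
            near = taken.setdefault(row["contig"], [])
            if any(abs(row["position"] - q) < config.min_site_separation
                   for q in near):
                continue
            near.append(int(row["position"]))
            chosen.append((row["contig"], row["strand"], int(row["position"])))
    if config.tss_m6am:
        for tx in transcripts:
            if reference.base(tx.contig, tx.tss, tx.strand) == "A":
                chosen.append((tx.contig, tx.strand, tx.tss))
    chosen.sort()
    sites = pd.DataFrame(chosen, columns=["contig", "strand", "position"])
    sites["site_id"] = [site_key(c, p, s) for c, s, p
                        in zip(sites["contig"], sites["strand"], sites["position"])]
    lo, hi = config.stoichiometry_range
    stoich = pd.DataFrame(
        {condition: rng.uniform(lo, hi, len(sites))},
        index=pd.Index(sites["site_id"], name="site_id"))
    return TrueMethylome(sites=sites, stoichiometry=stoich)


def simulate_mixture(wt: TrueMethylome, ko: TrueMethylome,
                     fractions: Sequence[float],
                     wt_condition: str = "WT",
                     ko_condition: str = "KO") -> TrueMethylome:
    """Mixture methylomes: stoichiometry = f * WT + (1 - f) * KO per site."""
    if not wt.stoichiometry.index.equals(ko.stoichiometry.index):
        raise M6aceError("mixture requires identical site universes")
    stoich = pd.DataFrame(index=wt.stoichiometry.index)
    for f in fractions:
        stoich[mixture_condition(f)] = (f * wt.stoichiometry[wt_condition]
                                        + (1 - f) * ko.stoichiometry[ko_condition])
    return TrueMethylome(sites=wt.sites, stoichiometry=stoich)


def mixture_condition(fraction: float) -> str:
    return f"mix_{fraction:.2f}"


def _make_umis(rng: np.random.Generator, n: int) -> np.ndarray:
    arr = np.empty((n, 8), dtype=np.uint8)
    arr[:, :7] = _BASES[rng.integers(0, 4, (n, 7))]
    arr[:, 7] = _B_BASES[rng.integers(0, 3, n)]
    return arr.view("S8").ravel().astype(str)


def _fragments(five_prime: np.ndarray, strand: str, contig_len: int,
               read_length: int) -> Tuple[np.ndarray, np.ndarray]:
    if strand == "+":
        start = five_prime
        end = np.minimum(five_prime + read_length, contig_len)
    else:
        end = five_prime + 1
        start = np.maximum(end - read_length, 0)
    return start, end


def simulate_libraries(methylome: TrueMethylome, reference: ReferenceSet,
                       config: SimConfig, condition: str = "WT",
                       stream: int = 0,
                       transcripts: Optional[Sequence[TranscriptModel]] = None
                       ) -> pd.DataFrame:
    """Aligned-read table (m6ACE + input, all replicates) for one condition.

    ``stream`` decorrelates conditions sharing a seed. Read counts at a
    methylated site are Binomial(depth, stoichiometry x capture); read
    starts land on the site with spillover per the stop profile. The input
    library fragments uniformly. PCR duplicates repeat coordinate+UMI.
    """
    rng = _spawn(config.seed, 2, stream)
    stoich = methylome.condition(condition) if condition in methylome.conditions \
        else methylome.stoichiometry.iloc[:, 0] * 0
    offsets = np.array(sorted(config.stop_profile), dtype=np.int64)
    probs = np.array([config.stop_profile[o] for o in offsets])

    # Transcription strand per contig: RNA-derived reads (input
    # fragmentation, nonspecific background, noise) follow it.
    contig_strand = {config.spike_name: "+"}
    if transcripts is not None:
        for tx in transcripts:
            contig_strand[tx.contig] = tx.strand
    for cid, grp in methylome.sites.groupby("contig"):
        contig_strand.setdefault(cid, grp["strand"].iloc[0])

    # Clustered-noise loci: fixed across replicates so the cluster filter
    # has a consistent artefact to remove.
    noise_loci: List[Tuple[str, str, int]] = []
    tx_names = [c for c in reference.contigs if c != config.spike_name]
    for _ in range(config.n_noise_loci):
        if not tx_names:
            break
        c = tx_names[int(rng.integers(len(tx_names)))]
        L = reference.length(c)
        if L <= 2 * config.noise_span + 2:
            continue
        pos = int(rng.integers(config.noise_span + 1, L - config.noise_span - 1))
        noise_loci.append((c, contig_strand.get(c, "+"), pos))

    site_rows = list(methylome.sites.itertuples(index=False))
    frames: List[pd.DataFrame] = []
    for r in range(config.replicates):
        rep = f"rep{r + 1}"
        chunks: List[pd.DataFrame] = []

        def emit(contig: str, strand: str, five_prime: np.ndarray, library: str):
            if five_prime.size == 0:
                return
            L = reference.length(contig)
            five_prime = five_prime[(five_prime >= 0) & (five_prime < L)]
            if five_prime.size == 0:
                return
            start, end = _fragments(five_prime, strand, L, config.read_length)
            chunks.append(pd.DataFrame({
                "contig": contig, "strand": strand,
                "start": start, "end": end,
                "umi": _make_umis(rng, five_prime.size),
                "replicate": rep, "library": library}))

        # m6ACE: site pileups
        for row in site_rows:
            s = float(stoich.get(row.site_id, 0.0))
            n = int(rng.binomial(config.m6ace_depth,
                                 min(s * config.capture_efficiency, 1.0)))
            if n == 0:
                continue
            off = rng.choice(offsets, size=n, p=probs)
            fp = row.position + off if row.strand == "+" else row.position - off
            emit(row.contig, row.strand, fp, "m6ACE")
        # spike-in site (fully methylated, every condition)
        n = int(rng.binomial(config.spike_m6ace_depth, config.capture_efficiency))
        off = rng.choice(offsets, size=n, p=probs)
        emit(config.spike_name, "+", SPIKE_SITE_POSITION + off, "m6ACE")

        # m6ACE: nonspecific background + clustered noise
        for contig in reference.contigs:
            L = reference.length(contig)
            n_bg = int(rng.poisson(config.m6ace_background_rate * L))
            if n_bg:
                emit(contig, contig_strand.get(contig, "+"),
                     rng.integers(0, L, n_bg), "m6ACE")
        for contig, strand, pos in noise_loci:
            n = int(rng.poisson(config.noise_reads))
            fp = pos + rng.integers(-config.noise_span, config.noise_span + 1, n)
            emit(contig, strand, fp, "m6ACE")

        # input: uniform fragmentation
        for contig in reference.contigs:
            L = reference.length(contig)
            rate = (config.spike_input_reads / L if contig == config.spike_name
                    else config.input_rate)
            n = int(rng.poisson(rate * L))
            if n:
                emit(contig, contig_strand.get(contig, "+"),
                     rng.integers(0, L, n), "input")

        frames.extend(chunks)

    reads = pd.concat(frames, ignore_index=True)
    # PCR duplicates: each read gains one extra copy with probability
    # d / (1 - d), so duplicates make up fraction d of the final table.
    d = config.duplication_rate
    if d > 0:
        dup_rng = _spawn(config.seed, 3, stream)
        mask = dup_rng.random(len(reads)) < d / (1.0 - d)
        reads = pd.concat([reads, reads[mask]], ignore_index=True)
        reads = reads.sample(frac=1.0, random_state=dup_rng.integers(2**31)) \
                     .reset_index(drop=True)
    return reads[ALIGNED_TABLE_COLUMNS]


MIXTURE_FRACTIONS = (1.0, 0.75, 0.5, 0.25, 0.0)
SCENARIOS = ("basic", "mixture", "demethylase-ko", "tss-m6am")


@dataclass
class SimScenario:
    """One fully simulated experiment: reference, ground truth and reads."""

    name: str
    config: SimConfig
    reference: ReferenceSet
    transcripts: List[TranscriptModel]
    methylome: TrueMethylome
    reads: Dict[str, pd.DataFrame]      # condition -> aligned-read table
    extras: Dict[str, object] = field(default_factory=dict)

    def truth(self) -> pd.DataFrame:
        long = (self.methylome.stoichiometry
                .rename_axis("site_id")
                .reset_index()
                .melt(id_vars="site_id", var_name="condition",
                      value_name="stoichiometry"))
        return long.merge(self.methylome.sites, on="site_id")


def simulate_scenario(name: str, seed: int, **overrides) -> SimScenario:
    """Canned end-to-end experiments.

    * ``basic`` -- one WT condition with planted DRACH sites; exercises the
      full calling pipeline including the spike-in.
    * ``mixture`` -- WT and writer-KO RNA mixed at WT fractions 1, 0.75,
      0.5, 0.25, 0 (stoichiometry scales exactly with the fraction);
      exercises RML linearity.
    * ``demethylase-ko`` -- WT plus eraser-KO where regulated sites
      accumulate RML; the true accumulation is anti-correlated with WT
      stoichiometry, so strongly regulated sites are steady-state
      unmethylated (the ROC scenario).
    * ``tss-m6am`` -- additionally plants cap-adjacent sites at TSSs.
    """
    if name not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if name == "mixture":
        overrides.setdefault("n_transcripts", 60)
        overrides.setdefault("methyl_fraction", 0.15)
    if name == "demethylase-ko":
        overrides.setdefault("n_transcripts", 40)
        overrides.setdefault("methyl_fraction", 0.15)
    if name == "tss-m6am":
        overrides.setdefault("tss_m6am", True)
    config = SimConfig(seed=seed, **overrides)
    reference, transcripts = simulate_reference(config)
    methylome = simulate_methylome(reference, transcripts, config)
    extras: Dict[str, object] = {}

    if name in ("basic", "tss-m6am"):
        reads = {"WT": simulate_libraries(methylome, reference, config, "WT",
                                          stream=0, transcripts=transcripts)}
    elif name == "mixture":
        ko = TrueMethylome(methylome.sites,
                           pd.DataFrame({"KO": 0.0},
                                        index=methylome.stoichiometry.index))
        methylome = simulate_mixture(methylome, ko, MIXTURE_FRACTIONS)
        reads = {}
        for i, f in enumerate(MIXTURE_FRACTIONS):
            cond = mixture_condition(f)
            reads[cond] = simulate_libraries(methylome, reference, config, cond,
                                             stream=i, transcripts=transcripts)
        extras["fractions"] = {mixture_condition(f): f for f in MIXTURE_FRACTIONS}
    else:  # demethylase-ko
        rng = _spawn(seed, 4)
        sids = methylome.stoichiometry.index
        regulated = rng.random(len(sids)) < 0.5
        base = 0.6
        true_lfc = np.where(regulated, rng.uniform(0.3, 3.0, len(sids)), 0.0)
        # The eraser suppresses steady-state methylation: the stronger a
        # site is regulated, the lower its WT stoichiometry, reaching zero
        # (undetectable in WT) for accumulations of 2-fold-log2 and beyond.
        ko_stoich = pd.Series(base, index=sids)
        wt_stoich = pd.Series(base * np.maximum(0.0, 1.0 - true_lfc / 2.0),
                              index=sids)
        stoich = pd.DataFrame({"WT": wt_stoich, "KO": ko_stoich})
        methylome = TrueMethylome(methylome.sites, stoich)
        reads = {
            "WT": simulate_libraries(methylome, reference, config, "WT",
                                     stream=0, transcripts=transcripts),
            "KO": simulate_libraries(methylome, reference, config, "KO",
                                     stream=1, transcripts=transcripts),
        }
        extras["regulated_sites"] = set(sids[regulated])
        extras["true_lfc"] = pd.Series(true_lfc, index=sids)

    return SimScenario(name=name, config=config, reference=reference,
                       transcripts=transcripts, methylome=methylome,
                       reads=reads, extras=extras)
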