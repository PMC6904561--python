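# Methods

This document records the statistical model, the default parameters and
why they hold, the simulator's design, and known limitations.

## Signal model

m6ACE-seq converts methylation into read-start pileups: the antibody
crosslink halts a 5'→3' exoribonuclease, so a fragment's strand-aware
5'-most coordinate falls on (or 3–4 nt 5' of) the methylated adenosine.
All statistics therefore operate on read-start counts per
(contig, strand, position), never on coverage.

- **Read start**: `start` on the plus strand, `end - 1` on the minus
  strand, for a BED-like half-open `[start, end)` fragment.
- **UMI**: 8-mers matching `[ACGT]{7}[CGT]` (N7B). Reads sharing
  (contig, strand, start, end, UMI) within a (replicate, library) are PCR
  duplicates; the first occurrence is kept.
- **Candidate positions**: strand-aware reference base A with mean m6ACE
  read-start count across replicates ≥ 1.

## Enrichment test

Counts at candidate positions are modelled as negative binomial, and
m6ACE enrichment over input is tested per site with a one-sided Wald test:

- **Normalisation**: median-of-ratios size factors computed across
  candidate sites (rows with all-positive counts), falling back to
  total-count ratios if no such row exists. Callers may instead supply
  explicit library sizes (e.g. total deduplicated reads per column).
- **Dispersion**: per-site method-of-moments estimate from the NB
  variance function Var = μ + αμ², pooled across the two library groups,
  then shrunk halfway (weight 0.5) toward the 12.5%-trimmed mean of all
  per-site estimates. This moderates unstable triplicate variances
  without per-site priors.
- **Wald statistic**: β = ln(q_m6ACE / q_input) with Fisher-information
  standard error from μ_ij = s_j·q_g; one-sided p = P(Z ≥ β/SE). Sites
  with zero m6ACE counts receive p = 1. Zero input means are replaced by
  pseudocount/Σs for the test only.
- **Calling**: Benjamini–Hochberg adjustment; a site is enriched iff
  log2 fold change ≥ log2(2) and adjusted p < 0.05. The reported log2
  fold change adds a pseudocount of 0.5 to both normalised group means
  (reporting only; the test uses the raw means).

A null simulation (2,000 sites, matched Poisson counts in both libraries)
yields a raw-p false-positive fraction of ~0.03–0.05 at α = 0.05: close
to nominal with a mild conservative bias inherited from the dispersion
moderation. The test suite asserts the fraction lies in [0.03, 0.07].

## Artefact filters

- **Shadow filter**: an enriched site is removed when another enriched
  site lies 1–4 nt 3' of it (strand-aware) in an R-A-C sequence context
  (R = A/G). Imperfect exonuclease stoppage leaks a minority of stops to
  3–4 nt 5' of genuine sites; those stops can reach significance at depth
  and would otherwise be called.
- **Cluster filter**: within ±10 nt of a site in the pooled m6ACE table,
  the site is removed when more than 10 distinct positions carry
  read-starts AND the site's own position holds less than 50% of the
  pooled window counts. Genuine crosslink stops are near-single-base;
  diffuse clusters indicate nonspecific binding. The ±10 nt window
  matches the extent of the simulated noise clusters and, more
  importantly, keeps two genuine sites ≥10 nt apart (the simulator's
  minimum separation) from vetoing each other — with a wider window the
  dominance clause can reject pairs of real sites that split a window's
  counts roughly evenly.

## RML (Relative Methylation Level)

For each site and replicate:

- X = m6ACE read-starts summed over strand-aware offsets −4..0 at the
  site ÷ input read-starts summed over −51..0;
- Y = the same ratio at the spike-in's methylated base, with input window
  −21..0 (the spike-in oligo is short);
- RML = X / Y.

Offset −k means k nt 5' of the position in transcript orientation
(genomic position − k on the plus strand, + k on the minus strand);
windows are inclusive. The −4..0 numerator window captures the stop
profile's 5' spillover; the long input windows smooth fragmentation
noise. Replicates with a zero denominator are undefined (NaN), never 0;
condition means use defined replicates only. A missing spike-in is an
error — RML is meaningless without it. The spike-in's own RML is exactly
1, and RML is invariant under global count scaling; both identities are
asserted in the tests.

## Differential methylation

Per site, per-replicate RMLs of two conditions are compared with a
one-tailed Welch t-test in a declared direction:

- **reduction** (writer depletion): called **dependent** when
  log2(mean_ref / mean_perturbed) ≥ 2 and p < 0.05;
- **accumulation** (demethylase depletion): called **regulated** when
  log2(mean_perturbed / mean_ref) ≥ 1 and p < 0.05.

Means are guarded with ε = 1e-6 before the log. Fewer than two defined
replicates on either side makes the site **untestable**. Identical inputs
are never called (asserted).

Mixing-series linearity pools all sites' per-fraction mean RML,
normalised to each site's 100% WT value, into one least-squares
regression against the WT fraction; a correct pipeline gives slope ≈ 1.

## Downstream analyses

- **Metagene**: each site is scaled into its segment (5'UTR, CDS, 3'UTR)
  of the longest-CDS transcript covering it and binned on the
  concatenated axis; densities sum to 1. Intron-only or
  non-coding-only sites are excluded and counted.
- **TSS alignment**: strand-aware offset histogram to the nearest
  same-contig/strand TSS, with a "beyond" bin past ±max_offset.
- **Overlap**: upper-tail hypergeometric P(X ≥ k) for the intersection of
  two site sets within a declared universe (both sets must be subsets).
- **ROC**: sites ranked by descending WT adjusted p (most insignificant
  first; ties grouped into single steps); positives are sites regulated
  at at least each LFC stratum. The universe is the WT pass set united
  with all significantly accumulated sites; sites missing a WT test carry
  padj = 1. AUC is the trapezoidal area and equals the Mann–Whitney
  statistic (asserted against scipy on random data).
- **Consensus**: position-frequency matrix over strand-aware site flanks;
  the IUPAC consensus letter per column covers bases at frequency ≥ 0.25.

## Simulator

Each transcript is its own single-exon contig with 5'UTR/CDS/3'UTR drawn
from configurable length ranges (CDS trimmed to a multiple of 3), random
strand, plus a fixed 41 nt spike-in contig whose methylated adenosine
sits at 0-based position 20 in a GGACT context; the spike-in also
contains a decoy adenosine 3 nt 5' of the site, which exercises the
shadow filter. Sites are planted on DRACH-context adenosines with
sampling weights favouring the CDS and the stop-codon-proximal region
(0.5 5'UTR / 3.0 within 100 nt of the stop / 1.0 CDS / 1.5 3'UTR) and a
minimum mutual separation of 10 nt.

Per replicate:

- site reads ~ Binomial(depth, stoichiometry × capture efficiency 0.9),
  with 5' ends drawn from the stop profile {0: 0.85, −3: 0.075,
  −4: 0.075};
- nonspecific m6ACE background: Poisson, 0.3 read-starts/nt on the
  transcription strand;
- clustered noise: 5 loci × ~60 reads spread over ±10 nt (the cluster
  filter's target);
- input: uniform fragmentation at 2.0 read-starts/nt;
- PCR duplicates: each read gains an extra copy with probability
  d/(1−d), so duplicates form fraction d (default 0.2) of the final
  table.

The background rate matters structurally, not just cosmetically. Two
properties of real data must both hold: (a) genuine sites are isolated
near-single-base pileups, and (b) the candidate universe (all adenosines
with mean m6ACE ≥ 1) is dominated by unenriched background positions —
this is exactly what makes median-of-ratios size factors valid. At very
high background, (a) fails and the cluster filter misfires; at very low
background, (b) fails, the candidate list collapses to the enriched
sites themselves, and normalisation absorbs the enrichment. 0.3/nt
satisfies both at the default depths.

Randomness is deterministic per seed via independent `SeedSequence`
spawn keys per module/condition/purpose, so conditions sharing a seed are
decorrelated but reproducible. Canned scenarios: `basic`, `mixture`
(WT fractions 1/0.75/0.5/0.25/0 with stoichiometry scaling exactly),
`demethylase-ko` (KO stoichiometry 0.6; WT = 0.6·max(0, 1 − LFC/2) with
true LFC ~ U(0.3, 3) on a random half of sites, so strong regulation
implies steady-state unmethylation — the ROC scenario), and `tss-m6am`
(additional cap-adjacent sites at TSSs).

## Limitations

- With heavily site-enriched candidate universes (small fixtures, or
  extreme enrichment), median-of-ratios size factors absorb part of the
  fold change; observed log2 fold changes shrink by up to ~2–3× depth
  ratio at desk scale. The `library_sizes` override exists for callers
  who know the true sequencing depths.
- The cluster filter cannot distinguish two genuine sites closer than
  ~10 nt that are comparable in strength within one window; the
  simulator's minimum site separation mirrors this resolution limit.
- The dispersion moderation makes the Wald test mildly conservative
  (null false-positive rate slightly below nominal), which costs a little
  power at very low counts.
- Differential calls on fewer than two defined replicate RMLs per side
  are refused (`untestable`) rather than guessed.
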