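import numpy as np
import pandas as pd
import pytest
from conftest import equal_sizes, make_candidates

from m6ace.calling import (CLUSTER, NOT_ENRICHED, PASS, SHADOW,
                           EnrichmentConfig, call_sites,
                           filter_clustered_noise, filter_shadow_sites,
                           size_factors)
from m6ace.calling import test_enrichment as run_enrichment
from m6ace.errors import AnalysisError, M6aceError
from m6ace.io import ReferenceSet
from m6ace.readstarts import AlignedRead, collate_read_starts, reads_to_frame


class TestEnrichment:
    def test_single_site_oracle(self):
        m6, inp = (40, 50, 45), (4, 5, 5)
        cand = make_candidates([m6], [inp])
        res = run_enrichment(cand, library_sizes=equal_sizes(cand))
        row = res.iloc[0]
        # with equal sizes the group means are plain averages; the reported
        # fold change adds the 0.5 pseudocount to both means
        q1, q0 = sum(m6) / 3, sum(inp) / 3
        expected_lfc = np.log2((q1 + 0.5) / (q0 + 0.5))
        assert row["log2fc"] == pytest.approx(expected_lfc)
        assert row["padj"] == row["pvalue"]  # single test: BH is identity
        assert row["pvalue"] < 0.01
        assert bool(row["enriched"])
        assert row["filter_status"] == PASS

    def test_swapped_roles_not_enriched(self):
        cand = make_candidates([(4, 5, 5)], [(40, 50, 45)])
        res = run_enrichment(cand, library_sizes=equal_sizes(cand))
        row = res.iloc[0]
        assert row["log2fc"] < 0
        assert not bool(row["enriched"])
        assert row["filter_status"] == NOT_ENRICHED

    def test_zero_m6ace_counts_give_p_one(self):
        cand = make_candidates([(0, 0, 0), (30, 28, 35)],
                               [(5, 5, 5), (5, 5, 5)])
        res = run_enrichment(cand, library_sizes=equal_sizes(cand))
        assert res.iloc[0]["pvalue"] == 1.0
        assert not bool(res.iloc[0]["enriched"])

    def test_single_replicate_rejected(self):
        cand = make_candidates([[30]], [[5]])
        with pytest.raises(AnalysisError):
            run_enrichment(cand)

    def test_size_factors_recover_depth_ratio(self):
        rng = np.random.default_rng(5)
        base = rng.integers(20, 200, size=(300, 1)).astype(float)
        depth = np.array([1.0, 2.0, 0.5, 1.0, 1.0, 1.0])
        counts = rng.poisson(base * depth[None, :])
        cand = make_candidates(counts[:, 0::2], counts[:, 1::2],
                               positions=range(100, 100 + 300))
        # reorder depth to match the interleaved (rep, lib) column layout
        col_depth = np.empty(6)
        col_depth[0::2], col_depth[1::2] = depth[0::2], depth[1::2]
        sf = size_factors(cand).to_numpy()
        expected = col_depth / np.exp(np.mean(np.log(col_depth)))
        np.testing.assert_allclose(sf, expected, rtol=0.06)

    def test_null_calibration(self):
        # matched Poisson counts in both libraries: the fraction of raw
        # p-values below 0.05 should sit near (at most mildly below) 0.05
        rng = np.random.default_rng(42)
        n = 2000
        mu = rng.uniform(5, 200, size=n)
        counts = rng.poisson(mu[:, None], size=(n, 6)).astype(float)
        cand = make_candidates(counts[:, 0::2], counts[:, 1::2],
                               positions=range(1000, 1000 + n))
        res = run_enrichment(cand, library_sizes=equal_sizes(cand))
        frac = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        n = 200
        mu = rng.uniform(5, 80, size=n)
        fold = rng.choice([1.0, 2.0, 4.0, 8.0], size=n)
        m6 = rng.poisson(mu[:, None] * fold[:, None], size=(n, 3))
        inp = rng.poisson(mu[:, None], size=(n, 3))
        cand = make_candidates(m6, inp, positions=range(100, 100 + n))
        sizes = equal_sizes(cand)
        n_enriched = [
            int(run_enrichment(cand, EnrichmentConfig(min_fold=f,
                                                       padj_cutoff=p),
                                library_sizes=sizes)["enriched"].sum())
            for f, p in [(1.5, 0.05), (2.0, 0.05), (4.0, 0.05),
                         (2.0, 0.01), (2.0, 0.001)]]
        assert n_enriched[0] >= n_enriched[1] >= n_enriched[2]
        assert n_enriched[1] >= n_enriched[3] >= n_enriched[4]

    def test_invalid_config_rejected(self):
        with pytest.raises(M6aceError):
            EnrichmentConfig(min_fold=0.5)
        with pytest.raises(M6aceError):
            EnrichmentConfig(padj_cutoff=1.5)


@pytest.fixture
def rac_reference():
    # target site at 20 sits in an A-A-C (R-A-C) context; 60 also A but its
    # following base is G, so R-A-C is not satisfied there
    seq = ["T"] * 100
    seq[19], seq[20], seq[21] = "A", "A", "C"
    seq[59], seq[60], seq[61] = "A", "A", "G"
    return ReferenceSet({"chrT": "".join(seq)})


def _two_enriched(positions, strand="+"):
    cand = make_candidates([(40, 50, 45)] * len(positions),
                           [(4, 5, 5)] * len(positions),
                           positions=positions, strand=strand)
    res = run_enrichment(cand, library_sizes=equal_sizes(cand))
    assert res["enriched"].all()
    return res


class TestShadowFilter:
    @pytest.mark.parametrize("offset", [1, 2, 3, 4])
    def test_shadow_within_four_nt_filtered(self, rac_reference, offset):
        res = _two_enriched([20 - offset, 20])
        out = filter_shadow_sites(res, rac_reference)
        assert out.loc[f"chrT:{20 - offset}:+", "filter_status"] == SHADOW
        assert out.loc["chrT:20:+", "filter_status"] == PASS

    def test_five_nt_upstream_retained(self, rac_reference):
        out = filter_shadow_sites(_two_enriched([15, 20]), rac_reference)
        assert (out["filter_status"] == PASS).all()

    def test_motif_unmet_retained(self, rac_reference):
        # 60 is enriched but A-A-G, so 58 casts no shadow flag
        out = filter_shadow_sites(_two_enriched([58, 60]), rac_reference)
        assert (out["filter_status"] == PASS).all()

    def test_minus_strand_shadow_is_mirrored(self):
        # minus-strand R-A-C at genomic 40 reads right-to-left: genomic 41
        # must be T (=A on minus), 40 must be T, 39 must be G (=C on minus)
        seq = ["A"] * 100
        seq[39], seq[40], seq[41] = "G", "T", "T"
        ref = ReferenceSet({"chrT": "".join(seq)})
        # shadow sits 2 nt 5' of the target on the minus strand: genomic 42
        out = filter_shadow_sites(_two_enriched([40, 42], strand="-"), ref)
        assert out.loc["chrT:42:-", "filter_status"] == SHADOW
        assert out.loc["chrT:40:-", "filter_status"] == PASS

    def test_non_enriched_neighbour_casts_no_shadow(self, rac_reference):
        cand = make_candidates([(40, 50, 45), (4, 4, 4)],
                               [(4, 5, 5), (5, 5, 5)], positions=[18, 20])
        res = run_enrichment(cand, library_sizes=equal_sizes(cand))
        out = filter_shadow_sites(res, rac_reference)
        assert out.loc["chrT:18:+", "filter_status"] == PASS


def _cluster_table(window_counts):
    """Full read-start table with the given {position: m6ACE count} map."""
    reads = []
    umis = [f"{a}{b}CGTAC{c}" for a in "ACGT" for b in "ACGT" for c in "CGT"]
    k = 0
    for pos, n in window_counts.items():
        for _ in range(n):
            reads.append(AlignedRead("chrT", "+", pos, pos + 60,
                                     umis[k % len(umis)], "rep1", "m6ACE"))
            k += 1
    reads.append(AlignedRead("chrT", "+", 5, 70, "ACGTACGC", "rep1", "input"))
    ref = ReferenceSet({"chrT": "T" * 200})
    return collate_read_starts(reads_to_frame(reads), ref)


class TestClusterFilter:
    def sites_at_50(self):
        return _two_enriched([50])

    def test_diffuse_cluster_filtered(self):
        counts = {p: 1 for p in range(40, 61)}  # 21 distinct starts
        out = filter_clustered_noise(self.sites_at_50(), _cluster_table(counts))
        assert out.loc["chrT:50:+", "filter_status"] == CLUSTER

    def test_dominant_site_retained(self):
        counts = {p: 1 for p in range(40, 61) if p != 50}
        counts[50] = 80  # 80% of window counts at the site itself
        out = filter_clustered_noise(self.sites_at_50(), _cluster_table(counts))
        assert out.loc["chrT:50:+", "filter_status"] == PASS

    def test_isolated_site_retained(self):
        out = filter_clustered_noise(self.sites_at_50(), _cluster_table({50: 40}))
        assert out.loc["chrT:50:+", "filter_status"] == PASS

    def test_few_distinct_starts_retained_even_when_minor(self):
        # heavy neighbours but only 3 distinct starts: not a diffuse cluster
        out = filter_clustered_noise(
            self.sites_at_50(), _cluster_table({48: 50, 50: 5, 52: 50}))
        assert out.loc["chrT:50:+", "filter_status"] == PASS


class TestStrandMirror:
    def build_world(self, mirrored: bool):
        rng = np.random.default_rng(17)
        length = 400
        seq = list(rng.choice(list("CGT"), size=length))
        site_positions = [60, 150, 260]
        anchor_positions = [p for p in range(20, 380, 6)
                            if min(abs(p - s) for s in site_positions) > 12]
        for p in site_positions + anchor_positions:
            seq[p] = "A"
        seq = "".join(seq)
        reads = []
        def umi_gen():
            k = 0
            while True:  # encode a counter in base 4 over the 7 free bases
                digits = [(k >> (2 * i)) & 3 for i in range(7)]
                yield "".join("ACGT"[d] for d in digits) + "C"
                k += 1
        umis = umi_gen()
        for p in site_positions:
            for rep in ("rep1", "rep2", "rep3"):
                for _ in range(25):
                    reads.append(("chrT", "+", p, min(p + 70, length),
                                  next(umis), rep, "m6ACE"))
        for rep in ("rep1", "rep2", "rep3"):
            for p in site_positions:  # baseline input coverage at each site
                for _ in range(4):
                    reads.append(("chrT", "+", p, min(p + 70, length),
                                  next(umis), rep, "input"))
            # null anchor positions with matched coverage in both libraries:
            # these dominate the candidate universe, as background does on
            # real data, so the median-of-ratios size factors stay honest
            for p in anchor_positions:
                for lib, n in (("m6ACE", 1 + int(rng.poisson(4))),
                               ("input", 1 + int(rng.poisson(4)))):
                    for _ in range(n):
                        reads.append(("chrT", "+", p, min(p + 70, length),
                                      next(umis), rep, lib))
            for _ in range(120):
                s = int(rng.integers(0, length - 70))
                reads.append(("chrT", "+", s, s + 70, next(umis), rep, "input"))
        if mirrored:
            comp = str.maketrans("ACGT", "TGCA")
            seq = seq.translate(comp)[::-1]
            reads = [("chrT", "-", length - e, length - s, u, rep, lib)
                     for (_, _, s, e, u, rep, lib) in reads]
        ref = ReferenceSet({"chrT": seq})
        frame = reads_to_frame([AlignedRead(*r) for r in reads])
        return call_sites(frame, ref)

    def test_calls_identical_under_reverse_complement(self):
        passed_fwd, audit_fwd, _ = self.build_world(False)
        passed_rev, audit_rev, _ = self.build_world(True)
        length = 400
        fwd = sorted(passed_fwd["position"])
        rev = sorted(length - 1 - passed_rev["position"])
        assert fwd == rev == [60, 150, 260]
        # per-site statistics match exactly under the mirror map
        audit_rev = audit_rev.assign(
            position=length - 1 - audit_rev["position"]).sort_values("position")
        audit_fwd = audit_fwd.sort_values("position")
        np.testing.assert_allclose(audit_fwd["log2fc"].to_numpy(),
                                   audit_rev["log2fc"].to_numpy())
        np.testing.assert_allclose(audit_fwd["padj"].to_numpy(),
                                   audit_rev["padj"].to_numpy())


class TestPipelineOnSimulatedData:
    def test_basic_scenario_recovery(self, basic_scenario, basic_calls):
        from conftest import score_calls
        passed, audit, _ = basic_calls
        prec, rec, f1 = score_calls(passed, basic_scenario.methylome)
        assert prec >= 0.9
        assert rec >= 0.9
        assert "spike:20:+" in set(passed["site_id"])

    def test_audit_partitions_candidates(self, basic_calls):
        _, audit, _ = basic_calls
        assert set(audit["filter_status"]) <= {PASS, NOT_ENRICHED, SHADOW,
                                               CLUSTER}
        passed = audit[audit["filter_status"] == PASS]
        assert passed["enriched"].all()
        assert not passed["shadow_flag"].any()
        assert not passed["cluster_flag"].any()
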