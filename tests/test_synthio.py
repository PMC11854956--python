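import numpy as np
import pytest

from saltnet.duplex import align_duplex
from saltnet.mimic import etm_check
from saltnet.models import InputError, SizingError, to_rna
from saltnet.synthio import (
    SyntheticScenario,
    default_junctions,
    make_annotation,
    make_mirnas,
    make_network_fixture,
    plant_duplex_sites,
    simulate_backsplice_reads,
    simulate_counts,
)


class TestAnnotation:
    def test_deterministic_for_a_seed(self):
        sc = SyntheticScenario(seed=5)
        t1, g1 = make_annotation(sc)
        t2, g2 = make_annotation(SyntheticScenario(seed=5))
        assert g1 == g2
        assert t1 == t2
        t3, g3 = make_annotation(SyntheticScenario(seed=6))
        assert g3 != g1

    def test_feature_counts_and_shapes(self):
        sc = SyntheticScenario(seed=5)
        ts, genome = make_annotation(sc)
        mrnas = [t for t in ts if t.biotype == "mRNA"]
        lncs = [t for t in ts if t.biotype == "lncRNA_candidate"]
        assert len(mrnas) == sc.n_genes
        assert len(lncs) == sc.n_lncrna
        assert len(genome) == sc.chrom_length
        assert all(2 <= len(t.exons) <= 9 for t in mrnas)
        assert all(len(t.exons) in (1, 2) for t in lncs)
        # study shape: lncRNAs short, mRNAs mostly long
        assert np.median([t.spliced_length for t in lncs]) < 600
        assert np.median([t.spliced_length for t in mrnas]) > 1000

    def test_features_do_not_overlap(self):
        ts, _ = make_annotation(SyntheticScenario(seed=5))
        spans = sorted(t.span for t in ts)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_sizing_error_when_chromosome_too_small(self):
        with pytest.raises(SizingError):
            make_annotation(SyntheticScenario(seed=5, chrom_length=30_000))

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            make_annotation(SyntheticScenario(seed=5, n_genes=-1))


class TestMirnas:
    def test_lengths_and_alphabet(self):
        mirnas = make_mirnas(SyntheticScenario(seed=5, n_mirna=20))
        assert len(mirnas) == 20
        for seq in mirnas.values():
            assert 18 <= len(seq) <= 25
            assert set(seq) <= set("ACGU")

    def test_deterministic(self):
        a = make_mirnas(SyntheticScenario(seed=5))
        b = make_mirnas(SyntheticScenario(seed=5))
        assert a == b


class TestPlanting:
    def test_planted_sites_survive_extraction(self):
        sc = SyntheticScenario(seed=5)
        ts, genome = make_annotation(sc)
        mirnas = make_mirnas(sc)
        genome, truth = plant_duplex_sites(sc, ts, genome, mirnas, "target", 4, 4)
        by_id = {t.transcript_id: t for t in ts}
        for rec in truth.to_dict("records"):
            host = by_id[rec["transcript_id"]]
            seq = to_rna(host.extract(genome))
            site = seq[rec["site_start"]:rec["site_end"]]
            aln = align_duplex(mirnas[rec["mirna_id"]], site)
            assert aln.allen_score == rec["allen_score"]
            qualifies = aln.allen_score <= 7.0 and aln.mfe_ratio > 0.65
            assert qualifies == rec["expect_pass"]

    def test_planted_mimics_match_intended_rule(self):
        sc = SyntheticScenario(seed=5)
        ts, genome = make_annotation(sc)
        mirnas = make_mirnas(sc)
        genome, truth = plant_duplex_sites(sc, ts, genome, mirnas, "mimic", 5, 5)
        by_id = {t.transcript_id: t for t in ts}
        for rec in truth.to_dict("records"):
            host = by_id[rec["transcript_id"]]
            seq = to_rna(host.extract(genome))
            site = seq[rec["site_start"]:rec["site_end"]]
            call = etm_check(align_duplex(mirnas[rec["mirna_id"]], site))
            if rec["expect_pass"]:
                assert call.verdict == "pass"
            else:
                assert call.fail_reason == rec["decoy_rule"]

    def test_decoy_rules_cycle_through_every_rule(self):
        sc = SyntheticScenario(seed=5)
        ts, genome = make_annotation(sc)
        mirnas = make_mirnas(sc)
        _, truth = plant_duplex_sites(sc, ts, genome, mirnas, "mimic", 0, 10)
        assert set(truth["decoy_rule"]) == {
            "bulge_side", "bulge_position", "middle_mismatch",
            "mismatch_count", "consecutive_mismatches",
        }

    def test_invalid_mode_rejected(self):
        sc = SyntheticScenario(seed=5)
        ts, genome = make_annotation(sc)
        with pytest.raises(InputError):
            plant_duplex_sites(sc, ts, genome, make_mirnas(sc), "sponge")


class TestCounts:
    def test_shape_groups_and_determinism(self):
        sc = SyntheticScenario(seed=5)
        ids = [f"f{i}" for i in range(50)]
        cm, truth = simulate_counts(sc, ids)
        assert cm.counts.shape == (50, 6)
        assert cm.samples("control") == ["CTRL_1", "CTRL_2", "CTRL_3"]
        assert cm.samples("treated") == ["NaCl_1", "NaCl_2", "NaCl_3"]
        cm2, _ = simulate_counts(SyntheticScenario(seed=5), ids)
        assert cm.counts.equals(cm2.counts)

    def test_nb_moments(self):
        sc = SyntheticScenario(seed=5, dispersion=0.2, n_samples_per_group=200)
        cm, truth = simulate_counts(
            sc, ["f1"], de_fraction=0.0, mu_range=(500.0, 500.001)
        )
        vals = cm.counts.iloc[0].to_numpy(dtype=float)
        mu = truth["mu"].iloc[0]
        assert vals.mean() == pytest.approx(mu, rel=0.1)
        assert vals.var(ddof=1) == pytest.approx(mu + 0.2 * mu * mu, rel=0.3)

    def test_planted_fold_change_applied(self):
        sc = SyntheticScenario(seed=5, planted_log2fc=3.0, n_samples_per_group=50)
        cm, truth = simulate_counts(
            sc, ["a", "b"], de_fraction=0.0, de_ids=["a"], mu_range=(400.0, 500.0)
        )
        ctrl = cm.counts.loc["a", cm.samples("control")].mean()
        trt = cm.counts.loc["a", cm.samples("treated")].mean()
        observed = np.log2(trt / ctrl)
        assert abs(abs(observed) - 3.0) < 0.5
        assert truth.set_index("feature_id").loc["b", "log2fc"] == 0.0

    def test_parameter_validation(self):
        with pytest.raises(InputError):
            simulate_counts(SyntheticScenario(seed=5, dispersion=0.0), ["a"])
        with pytest.raises(InputError):
            simulate_counts(SyntheticScenario(seed=5, n_samples_per_group=1), ["a"])


class TestBacksplice:
    def test_reads_match_declared_junctions(self):
        sc = SyntheticScenario(seed=5)
        reads, truth = simulate_backsplice_reads(
            sc, [("chr1", 5000, 2000, 3, 1), ("chr1", 9000, 8000, 0, 0)]
        )
        assert len(reads) == 3
        assert (reads.seg2_start == 2000).all()
        assert (reads.seg1_end == 5000).all()
        assert list(truth.verdict) == ["accept", "undetectable"]

    def test_verdicts_name_the_failing_rule(self):
        sc = SyntheticScenario(seed=5)
        _, truth = simulate_backsplice_reads(
            sc,
            [
                ("chr1", 5000, 2000, 2, 3),
                ("chr1", 500_000, 2000, 2, 0),
            ],
        )
        assert list(truth.verdict) == ["reject: mismatches", "reject: span"]

    def test_invalid_junction_rejected(self):
        sc = SyntheticScenario(seed=5)
        with pytest.raises(InputError):
            simulate_backsplice_reads(sc, [("chr1", 2000, 5000, 1, 0)])

    def test_default_junctions_cover_rules_and_types(self):
        sc = SyntheticScenario(seed=5)
        ts, _ = make_annotation(sc)
        juncs = default_junctions(sc, ts, n_total=9)
        assert len(juncs) == 12  # 9 valid + 3 rule violations
        _, truth = simulate_backsplice_reads(sc, juncs)
        verdicts = set(truth.verdict)
        assert {"accept", "undetectable", "reject: mismatches",
                "reject: span"} <= verdicts


class TestNetworkFixture:
    def test_expected_edges_are_consistent(self):
        de, targets, mimics, exp_edges = make_network_fixture(seed=3)
        de_ids = {
            cls: set(df[df.status != "ns"].index) for cls, df in de.items()
        }
        for a, b in exp_edges:
            ids = {a, b}
            assert any(i in de_ids["miRNA"] for i in ids)

    def test_deterministic(self):
        a = make_network_fixture(seed=4)
        b = make_network_fixture(seed=4)
        assert a[3] == b[3]
        assert a[1].equals(b[1]) and a[2].equals(b[2])
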