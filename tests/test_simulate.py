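"""Fixture generation, validation, and the assay/conservation simulators."""

import numpy as np
import pandas as pd
import pytest

from utrvar.scanner import ConservationTrack, UtrSequence, conservation_gate, scan_uorfs
from utrvar.simulate import (
    PANEL_HGVS,
    AssaySimConfig,
    FixtureError,
    generate_fixture,
    panel_variants,
    simulate_assay,
    simulate_conservation,
    validate_fixture,
    write_variant_panel,
)
from utrvar.variants import apply_variant, classify_consequence


class TestGenerateFixture:
    def test_default_seed_passes_validator(self, fixture_utr):
        report = validate_fixture(fixture_utr)
        assert report.passed, report.failures()

    def test_deterministic_per_seed(self):
        a, _ = generate_fixture(seed=5)
        b, _ = generate_fixture(seed=5)
        assert a.seq == b.seq and a.cds_prefix == b.cds_prefix

    def test_different_seeds_validator_passing(self):
        seqs = set()
        for seed in range(30):
            utr, _ = generate_fixture(seed=seed)
            assert validate_fixture(utr).passed
            seqs.add(utr.seq)
        assert len(seqs) > 1  # the search genuinely varies

    def test_peptides_read_from_sequence(self, fixture_utr):
        from Bio.Seq import Seq

        assert str(Seq(fixture_utr.seq[122:143]).translate()) == "MPSAGPA"
        assert str(Seq(fixture_utr.seq[189:204]).translate()) == "MRALP"


class TestValidateFixture:
    def test_mutated_uaug_fails_uorf_count(self, fixture_utr):
        broken = UtrSequence(
            seq=fixture_utr.seq[:122] + "ACG" + fixture_utr.seq[125:],
            cds_prefix=fixture_utr.cds_prefix,
        )
        report = validate_fixture(broken)
        assert not report.passed
        assert any("two_uorfs" in name for name, ok, _ in report.checks if not ok)

    def test_extra_planted_uorf_fails(self, fixture_utr):
        # plant ATG + immediate stop in the upstream spacer
        s = fixture_utr.seq
        broken = UtrSequence(seq=s[:30] + "ATGTAA" + s[36:], cds_prefix=fixture_utr.cds_prefix)
        report = validate_fixture(broken)
        assert not report.passed

    def test_generator_never_trusted(self, fixture_utr):
        """The validator recomputes the panel behaviour from primitives."""
        report = validate_fixture(fixture_utr)
        names = [name for name, _, _ in report.checks]
        for label in PANEL_HGVS:
            if label != "wildtype":
                assert f"panel_{label}" in names


class TestSimulateAssay:
    def test_same_seed_identical_tables(self):
        c = AssaySimConfig(seed=9)
        pd.testing.assert_frame_equal(simulate_assay(c), simulate_assay(c))

    def test_replicate_structure(self):
        t = simulate_assay(AssaySimConfig(seed=1))
        one = t[t.construct == "wildtype"]
        assert len(one) == 12 * 2  # 12 transfections x 2 duplicates
        assert set(one.experiment) == {1, 2}
        assert one.groupby(["experiment", "replicate"]).size().eq(2).all()

    def test_planted_sd_realised_on_relative_scale(self):
        from utrvar.assay import normalize

        rel = pd.concat(
            normalize(simulate_assay(AssaySimConfig(seed=s)))
            for s in range(30)
        )
        sds = rel.groupby("construct")["relative_activity"].std()
        # per-replicate noise is planted at 0.1; the wildtype group is
        # slightly tighter because its experiment mean is 1 by construction
        assert 0.06 < sds.drop("wildtype").mean() < 0.14

    def test_rejects_nonpositive_truth(self):
        with pytest.raises(ValueError):
            AssaySimConfig(true_means={"wildtype": 1.0, "v": 0.0})


class TestSimulateConservation:
    def test_planted_codons_recovered_by_gate(self, fixture_utr):
        uorfs = scan_uorfs(fixture_utr)
        track = simulate_conservation(uorfs, fixture_utr.utr_length, seed=2)
        for u in uorfs:
            g = conservation_gate(u, track)
            assert g.conserved_start is True and g.conserved_stop is True

    def test_thresholds_above_planted_scores_fail(self, fixture_utr):
        uorfs = scan_uorfs(fixture_utr)
        track = simulate_conservation(uorfs, fixture_utr.utr_length, seed=2)
        hard = ConservationTrack(
            basewise=track.basewise,
            elementwise=track.elementwise,
            basewise_min=99.0,
            elementwise_min=1.5,
        )
        g = conservation_gate(uorfs[0], hard)
        assert g.conserved_start is False

    def test_seeded_reproducibility(self, fixture_utr):
        uorfs = scan_uorfs(fixture_utr)
        a = simulate_conservation(uorfs, fixture_utr.utr_length, seed=4)
        b = simulate_conservation(uorfs, fixture_utr.utr_length, seed=4)
        assert a.basewise == b.basewise and a.elementwise == b.elementwise


class TestVariantPanel:
    def test_tsv_round_trips_through_parser(self, fixture_pair, tmp_path):
        import utrvar.io as uio

        utr, model = fixture_pair
        tsv, vcf = tmp_path / "panel.tsv", tmp_path / "panel.vcf"
        write_variant_panel(utr, model, str(tsv), str(vcf))
        table = uio.read_variant_table(str(tsv))
        by_label = dict(table)
        assert set(by_label) == set(PANEL_HGVS)
        call = classify_consequence(utr, by_label["patient"])
        assert call.code == "uStop_lost_oORF"

    def test_vcf_ref_matches_plus_strand_fixture(self, fixture_pair, tmp_path):
        import pysam

        utr, model = fixture_pair
        comp = str.maketrans("ACGT", "TGCA")
        plus = utr.seq.translate(comp)[::-1]  # genomic plus strand of the UTR
        vcf_path = tmp_path / "panel.vcf"
        write_variant_panel(utr, model, str(tmp_path / "p.tsv"), str(vcf_path))
        with pysam.VariantFile(str(vcf_path)) as vcf:
            n = 0
            for rec in vcf:
                idx = rec.pos - model.utr5_start
                assert plus[idx] == rec.ref[0]
                n += 1
        assert n == 7  # unique simple variants of the nine constructs

    def test_dup_rendered_as_insertion_after_plus_anchor(self, fixture_pair, tmp_path):
        """c.-69dupG on the minus strand is written as an insertion of C
        after plus-strand position 2,135,757 — the paired dual notation."""
        import pysam

        utr, model = fixture_pair
        vcf_path = tmp_path / "panel.vcf"
        write_variant_panel(utr, model, str(tmp_path / "p.tsv"), str(vcf_path))
        with pysam.VariantFile(str(vcf_path)) as vcf:
            dups = [r for r in vcf if len(r.alts[0]) > len(r.ref)]
        assert len(dups) == 1
        rec = dups[0]
        assert rec.pos == 2_135_757
        assert rec.alts[0] == rec.ref + "C"

    def test_vcf_round_trips_to_transcript_variants(self, fixture_pair, tmp_path):
        import utrvar.io as uio

        utr, model = fixture_pair
        vcf_path = tmp_path / "panel.vcf"
        write_variant_panel(utr, model, str(tmp_path / "p.tsv"), str(vcf_path))
        specs = uio.read_vcf(str(vcf_path), utr, model)
        labels = sorted(s.label for s in specs)
        expected = sorted({h for hs in PANEL_HGVS.values() for h in hs})
        assert labels == expected
        # and each applies cleanly to the fixture
        for s in specs:
            apply_variant(utr, [s])
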