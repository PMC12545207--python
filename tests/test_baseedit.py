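import itertools

import numpy as np
import pandas as pd
import pytest

from cropscreen.baseedit import (
    ABE,
    CBE,
    EditorSpec,
    GeneModel,
    count_with_expanded_reference,
    design_controls,
    enumerate_guides,
    expand_self_edit_reference,
    filter_guides,
    mutagenesis_map,
    predict_edits,
    quantify_editing,
    select_validation_guides,
    summary_consequence,
)
from cropscreen.baseedit.models import revcomp
from cropscreen.baseedit.quantify import self_edit_variants
from cropscreen.synthetic import GuideLibrary, GuideRecord


from tests_baseedit_helpers import brute_force_enumeration, random_sequence, toy_gene


class TestEnumerate:
    @pytest.mark.parametrize("pam_mode", ["NGG", "pamless"])
    def test_matches_brute_force_on_toy_genes(self, pam_mode):
        rng = np.random.default_rng(42)
        for _ in range(10):
            model = toy_gene(rng)
            editor = ABE.with_pam_mode(pam_mode)
            ours = {(g.spacer, g.strand, g.start) for g in enumerate_guides(model, editor)}
            assert ours == brute_force_enumeration(model, pam_mode)

    def test_pamless_one_guide_per_position_per_strand(self):
        model = toy_gene(seed=3)
        editor = ABE.with_pam_mode("pamless")
        guides = enumerate_guides(model, editor)
        keys = [(g.start, g.strand) for g in guides]
        assert len(keys) == len(set(keys))

    def test_no_g_means_no_plus_strand_ngg(self):
        seq = "ACTA" * 30  # no G anywhere
        model = GeneModel("nog", seq, [(0, len(seq))], [])
        guides = enumerate_guides(model, ABE)
        assert not any(g.strand == "+" for g in guides)

    def test_short_sequence_empty(self):
        model = GeneModel("tiny", "ACGTACGTACGTACG", [(0, 15)], [])
        assert enumerate_guides(model, ABE) == []

    def test_design_region_flank(self):
        # guide far outside exon+/-flank is not designed
        rng = np.random.default_rng(5)
        seq = random_sequence(rng, 400)
        model = GeneModel("m", seq, [(180, 220)], [], flank=20)
        guides = enumerate_guides(model, ABE.with_pam_mode("pamless"))
        for g in guides:
            assert g.start < 240 and g.start + 20 > 160


class TestFilter:
    def _guide(self, spacer, pam="AGG"):
        from cropscreen.baseedit.models import BaseEditGuide

        return BaseEditGuide("g", spacer, pam, "+", 0)

    def test_t_stretch_excluded(self):
        res = filter_guides([self._guide("ACG" + "TTTT" + "A" * 13)])
        assert not res.kept
        assert res.excluded[0].excluded["t_stretch"]

    def test_bsmbi_excluded(self):
        res = filter_guides([self._guide("ACGCGTCTCACGACGACGAC")])
        assert res.excluded[0].excluded["bsmbi"]

    def test_bsmbi_reverse_complement(self):
        res = filter_guides([self._guide("ACGGAGACGACGACGACGAC")])
        assert res.excluded[0].excluded["bsmbi"]

    def test_bsmbi_spans_spacer_pam_junction(self):
        res = filter_guides([self._guide("A" * 16 + "CGTC", pam="TCA")])
        assert res.excluded[0].excluded["bsmbi"]

    def test_clean_spacer_kept(self):
        res = filter_guides([self._guide("ACGACGACGACGACGACGAC")])
        assert res.kept and not res.excluded

    def test_idempotent(self):
        guides = [
            self._guide("ACGACGACGACGACGACGAC"),
            self._guide("TTTTACGACGACGACGACGA"),
        ]
        first = filter_guides(guides)
        second = filter_guides(first.kept)
        assert not second.excluded
        assert [g.spacer for g in second.kept] == [g.spacer for g in first.kept]


class TestPredict:
    def _model_with_codons(self, codons, pad="G" * 30):
        cds = "ATG" + "".join(codons) + "TAA"
        seq = pad + cds + pad
        return GeneModel("m", seq, [(len(pad), len(pad) + len(cds))],
                         [(len(pad), len(pad) + len(cds))]), len(pad)

    def _guide_covering(self, model, editor, genomic_pos, spacer_pos=5):
        for g in enumerate_guides(model, editor.with_pam_mode("pamless")):
            if g.strand == "+" and g.genomic_position(spacer_pos) == genomic_pos \
                    and g.spacer[spacer_pos - 1] == editor.ref_base:
                return g
        raise AssertionError("no covering guide")

    def test_cbe_nonsense_cag_to_tag(self):
        model, off = self._model_with_codons(["CAG"])
        pos = off + 3  # the C of CAG
        g = self._guide_covering(model, CBE, pos)
        out = predict_edits(g, CBE, model, window=(5, 5))
        assert out[0].consequence == "nonsense"
        assert out[0].codon_change == ("CAG", "TAG")
        assert out[0].aa_change == "Q2*"

    def test_abe_silent_third_position(self):
        model, off = self._model_with_codons(["GCA", "CTG"])
        pos = off + 5  # third base of GCA
        g = self._guide_covering(model, ABE, pos)
        out = predict_edits(g, ABE, model, window=(5, 5))
        assert out[0].consequence == "silent"
        assert out[0].codon_change == ("GCA", "GCG")

    def test_abe_missense(self):
        model, off = self._model_with_codons(["AAA"])  # K -> (A->G at pos1) GAA = E
        pos = off + 3
        g = self._guide_covering(model, ABE, pos)
        out = predict_edits(g, ABE, model, window=(5, 5))
        assert out[0].consequence == "missense"
        assert out[0].aa_change == "K2E"

    def test_no_ref_base_in_window_empty(self):
        model, off = self._model_with_codons(["CCC"])
        editor = ABE
        for g in enumerate_guides(model, editor.with_pam_mode("pamless")):
            if all(g.spacer[p - 1] != "A" for p in range(5, 8)):
                assert predict_edits(g, editor, model) == []
                break

    def test_splice_site_precedence(self):
        rng = np.random.default_rng(9)
        model = toy_gene(rng)
        splice = model.splice_site_positions()
        editor = ABE.with_pam_mode("pamless")
        for g in enumerate_guides(model, editor):
            for o in predict_edits(g, editor, model, window=(1, 20)):
                if o.position in splice:
                    assert o.consequence == "splice_site"

    def test_consequence_soundness_on_toy_genes(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            model = toy_gene(rng)
            protein_ref = model.translate()
            editor = CBE.with_pam_mode("pamless")
            for g in enumerate_guides(model, editor)[:50]:
                for o in predict_edits(g, editor, model):
                    edited = (
                        model.sequence[: o.position] + o.alt
                        + model.sequence[o.position + 1 :]
                    )
                    protein_alt = model.translate(edited)
                    if o.consequence == "nonsense":
                        assert "*" in protein_alt[: len(protein_ref) - 1]
                    elif o.consequence == "silent":
                        assert protein_alt == protein_ref

    def test_severity_order(self):
        from cropscreen.baseedit.models import EditOutcome

        outs = [
            EditOutcome(0, "A", "G", "silent"),
            EditOutcome(1, "A", "G", "missense"),
            EditOutcome(2, "A", "G", "nonsense"),
        ]
        assert summary_consequence(outs) == "nonsense"
        assert summary_consequence([]) is None


class TestControls:
    def _region(self, rng, n=600):
        return random_sequence(rng, n)

    def test_quota_cells_n8(self, rng):
        controls = design_controls(ABE, self._region(rng), 8, seed=1)
        assert len(controls) == 8
        lo, hi = ABE.design_window
        cells = {"A-NGG": 0, "A-nonNGG": 0, "C-NGG": 0, "C-nonNGG": 0}
        for g in controls:
            window = g.spacer[lo - 1 : hi]
            base = "A" if "A" in window else "C"
            assert ("A" in window) != ("C" in window)
            pam = "NGG" if (len(g.pam) == 3 and g.pam[1:] == "GG") else "nonNGG"
            cells[f"{base}-{pam}"] += 1
        assert all(v == 2 for v in cells.values())

    def test_impossible_region_raises(self):
        with pytest.raises(ValueError, match="quota"):
            design_controls(ABE, "GT" * 100, 8, seed=0)

    def test_seed_determinism(self, rng):
        region = self._region(rng)
        a = design_controls(ABE, region, 12, seed=7)
        b = design_controls(ABE, region, 12, seed=7)
        assert [g.guide_id for g in a] == [g.guide_id for g in b]

    def test_zero_controls(self):
        assert design_controls(ABE, "ACGT" * 50, 0, seed=0) == []


class TestExpansion:
    def _library(self, spacers):
        return GuideLibrary(
            [GuideRecord(f"g{i}", "G", sp, "target") for i, sp in enumerate(spacers)]
        )

    def test_two_ref_bases_three_variants(self):
        spacer = "CCC" + "A" + "C" + "A" + "CC" + "C" * 12  # A at positions 4 and 6
        assert len(self_edit_variants(spacer, ABE)) == 3

    def test_no_ref_base_no_variants(self):
        spacer = "CCC" + "CCCCC" + "A" * 12  # no A in 4-8
        assert self_edit_variants(spacer, ABE) == []

    def test_expansion_count_law(self, rng):
        spacers = set()
        while len(spacers) < 30:
            spacers.add(random_sequence(rng, 20))
        lib = self._library(sorted(spacers))
        expanded = expand_self_edit_reference(lib, ABE)
        lo, hi = ABE.self_edit_window
        for rec in lib:
            m = sum(rec.spacer[p - 1] == "A" for p in range(lo, hi + 1))
            expected = 2**m - 1
            assert expanded.n_variants_per_parent[rec.guide_id] <= expected
            if not expanded.dropped_collisions:
                assert expanded.n_variants_per_parent[rec.guide_id] == expected

    def test_collision_dropped_with_warning(self):
        # two spacers whose single edits converge on the same variant
        s1 = "CCC" + "A" + "C" * 16
        s2 = "CCC" + "G" + "C" * 16  # s1 edited at pos 4 -> equals s2 (an original)
        lib = self._library([s1, s2])
        with pytest.warns(UserWarning, match="collides"):
            expanded = expand_self_edit_reference(lib, ABE)
        # both parents keep their originals
        assert expanded.lookup(s1) == "g0"
        assert expanded.lookup(s2) == "g1"

    def test_self_edited_read_recovery(self, rng):
        spacers = set()
        while len(spacers) < 50:
            sp = random_sequence(rng, 20)
            if "A" in sp[3:8]:
                spacers.add(sp)
        lib = self._library(sorted(spacers))
        expanded = expand_self_edit_reference(lib, ABE)
        reads, parents = [], []
        edited_flags = []
        for _ in range(2000):
            rec = lib.records[rng.integers(0, len(lib))]
            if rng.random() < 0.3:
                variants = self_edit_variants(rec.spacer, ABE)
                reads.append(variants[rng.integers(0, len(variants))])
                edited_flags.append(True)
            else:
                reads.append(rec.spacer)
                edited_flags.append(False)
            parents.append(rec.guide_id)
        counts, matched, total = count_with_expanded_reference(reads, expanded)
        assert matched / total >= 0.99
        # without expansion, recovery drops by exactly the self-edited fraction
        plain = {r.spacer: r.guide_id for r in lib}
        plain_matched = sum(r in plain for r in reads)
        assert total - plain_matched == sum(edited_flags)


class TestValidationSelection:
    def test_identical_donors_single_set(self, rng):
        z = pd.Series(rng.normal(size=100), index=[f"g{i:03d}" for i in range(100)])
        donors = pd.DataFrame({"d1": z, "d2": z})
        selected = select_validation_guides(donors, fraction=0.035)
        assert len(selected) == 4  # ceil(0.035 * 100)
        top4 = set(z.sort_values(ascending=False).index[:4])
        assert selected == top4

    def test_anticorrelated_union_larger(self, rng):
        z = pd.Series(rng.normal(size=100), index=[f"g{i:03d}" for i in range(100)])
        donors = pd.DataFrame({"d1": z, "d2": -z})
        selected = select_validation_guides(donors, fraction=0.035)
        assert len(selected) > 4

    def test_fraction_zero_empty(self, rng):
        donors = pd.DataFrame({"d1": [1.0, 2.0], "d2": [0.5, 1.5]})
        assert select_validation_guides(donors, fraction=0.0) == set()

    def test_depleted_direction(self):
        donors = pd.DataFrame(
            {"d1": [5.0, -5.0, 0.0], "d2": [4.0, -4.0, 0.0]}, index=["up", "down", "mid"]
        )
        selected = select_validation_guides(donors, fraction=0.34, direction="depleted")
        assert "down" in selected and "up" not in selected

    def test_requires_two_donors(self):
        with pytest.raises(ValueError, match="two donors"):
            select_validation_guides(pd.DataFrame({"d1": [1.0]}))


class TestMutagenesisMap:
    def _ann(self, rows):
        return pd.DataFrame(
            rows, columns=["guide_id", "z_lfc", "residue", "aa_change", "consequence"]
        )

    def test_single_guide_score(self):
        ann = self._ann([("g1", 3.0, 16, "K16R", "missense")])
        table = mutagenesis_map(ann, protein_length=100)
        assert table.loc[0, "residue"] == 16
        assert table.loc[0, "mean_z"] == pytest.approx(3.0)

    def test_mean_of_two_guides(self):
        ann = self._ann(
            [("g1", 1.0, 5, "A5T", "missense"), ("g2", 3.0, 5, "A5V", "missense")]
        )
        table = mutagenesis_map(ann, protein_length=10)
        assert table.loc[0, "mean_z"] == pytest.approx(2.0)

    def test_non_coding_filtered(self):
        ann = self._ann([("g1", 9.0, 5, "A5A", "silent"), ("g2", 1.0, 6, "A6T", "missense")])
        table = mutagenesis_map(ann, protein_length=10)
        assert table["residue"].tolist() == [6]

    def test_hot_residue_recovery(self):
        recovered = 0
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            hot = set(rng.choice(np.arange(1, 101), size=5, replace=False).tolist())
            rows = []
            gid = 0
            for residue in range(1, 101):
                for _ in range(3):
                    z = rng.normal(3.0 if residue in hot else 0.0, 0.5)
                    rows.append((f"g{gid}", z, residue, f"A{residue}V", "missense"))
                    gid += 1
            table = mutagenesis_map(self._ann(rows), protein_length=100, top_n=5)
            top = set(table.loc[table["top"], "residue"])
            recovered += len(top & hot)
            total += len(hot)
        assert recovered / total >= 0.90


class TestQuantifyEditing:
    REF = "ACGTACGTAAGGCTCATGCCGTACGGATCCATGCAA"

    def _expected(self):
        pos = self.REF.index("A", 10)
        return [(pos, "A", "G")]

    def test_expected_conversion_counts_as_edited(self):
        exp = self._expected()
        pos = exp[0][0]
        read = self.REF[:pos] + "G" + self.REF[pos + 1 :]
        res = quantify_editing([read], self.REF, exp)
        assert res.fraction_edited == 1.0

    def test_conversion_plus_deletion_not_edited(self):
        exp = self._expected()
        pos = exp[0][0]
        read = (self.REF[:pos] + "G" + self.REF[pos + 1 :])
        read = read[:25] + read[26:]  # 1-base deletion elsewhere
        res = quantify_editing([read], self.REF, exp)
        assert res.n_edited == 0
        assert res.n_aligned == 1

    def test_unedited_reads_zero(self):
        res = quantify_editing([self.REF] * 5, self.REF, self._expected())
        assert res.fraction_edited == 0.0

    def test_unexpected_substitution_not_edited(self):
        exp = self._expected()
        read = "T" + self.REF[1:] if self.REF[0] != "T" else "C" + self.REF[1:]
        res = quantify_editing([read], self.REF, exp)
        assert res.n_edited == 0

    def test_unalignable_excluded(self):
        res = quantify_editing(["TTTTTTTT"], self.REF, self._expected())
        assert res.n_excluded == 1
        assert res.n_aligned == 0

    def test_bad_expected_conversion_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            quantify_editing([self.REF], self.REF, [(0, "G", "A")])


class TestGeneModel:
    def test_invalid_exons(self):
        with pytest.raises(ValueError):
            GeneModel("m", "ACGT" * 10, [(0, 10), (5, 15)], [])

    def test_cds_outside_exon(self):
        with pytest.raises(ValueError, match="within an exon"):
            GeneModel("m", "ACGT" * 10, [(0, 10)], [(5, 15)])

    def test_internal_stop_rejected(self):
        seq = "ATGTAACCC" + "G" * 21
        with pytest.raises(ValueError, match="stop"):
            GeneModel("m", seq, [(0, 9)], [(0, 9)])

    def test_genbank_roundtrip(self, tmp_path):
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord

        seq = "G" * 30 + "ATGGCATGCTAA" + "G" * 30
        record = SeqRecord(Seq(seq), id="toygene", annotations={"molecule_type": "DNA"})
        record.features = [
            SeqFeature(FeatureLocation(30, 42), type="exon"),
            SeqFeature(FeatureLocation(30, 42), type="CDS"),
        ]
        path = tmp_path / "gene.gb"
        SeqIO.write(record, str(path), "genbank")
        model = GeneModel.from_genbank(path)
        assert model.translate() == "MAC*"

    def test_gff3_constructor(self, tmp_path):
        seq = "G" * 30 + "ATGGCATGCTAA" + "G" * 30
        (tmp_path / "g.fa").write_text(">chr1\n" + seq + "\n")
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "chr1\ttest\tgene\t31\t42\t.\t+\t.\tID=toygene;gene_name=toygene\n"
            "chr1\ttest\texon\t31\t42\t.\t+\t.\tID=toygene.e1;Parent=toygene\n"
            "chr1\ttest\tCDS\t31\t42\t.\t+\t0\tID=toygene.c1;Parent=toygene\n"
        )
        model = GeneModel.from_gff3(tmp_path / "g.gff3", tmp_path / "g.fa", "toygene")
        assert model.translate() == "MAC*"
        assert model.exons == [(30, 42)]

    def test_minus_strand_translation(self):
        cds_plus = "ATGGCATGCTAA"
        seq = "C" * 25 + revcomp(cds_plus) + "C" * 25
        model = GeneModel("m", seq, [(25, 37)], [(25, 37)], strand="-")
        assert model.translate() == "MAC*"

    def test_splice_sites_two_bases_each_side(self):
        seq = "A" * 100
        model = GeneModel("m", seq, [(10, 30), (60, 80)], [])
        sites = model.splice_site_positions()
        assert sites == {30, 31, 58, 59}
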