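"""Readers/writers: inventory parsing, gene-model round trips, translation."""

import pytest
from hypothesis import given, strategies as st

import aarsloc as a
from aarsloc.sequence_io import (
    GeneModelError,
    InventoryParseError,
    ProfileError,
    TranslationError,
    parse_localization,
    profile_from_dict,
    reverse_complement,
)

from .oracles import _COMPLEMENT


class TestInventory:
    def test_fixture_counts(self, inventory):
        """The packaged inventory yields 58 + 43 + 43 nuclear synthetase rows
        plus 4 amidotransferase rows, every field populated."""
        nuclear = [r for r in inventory if not r.is_gat and r.encoding_genome == "nucleus"]
        per_org = {}
        for r in nuclear:
            per_org[r.organism] = per_org.get(r.organism, 0) + 1
        assert per_org == {
            "Guillardia theta": 58,
            "Phaeodactylum tricornutum": 43,
            "Thalassiosira pseudonana": 43,
        }
        assert sum(r.is_gat for r in inventory) == 4
        for r in inventory:
            assert r.gene_name and r.aars_type and r.subunit_kind

    def test_ambiguity_expression_parses_to_alternative_sets(self, inventory):
        row = next(
            r for r in inventory
            if r.organism == "Guillardia theta" and r.gene_name == "cysRS2"
        )
        assert row.alternatives == (
            frozenset({"plastid", "mitochondrion"}),
            frozenset({"ppc", "mitochondrion"}),
        )

    def test_incomplete_models_parse_to_unknown(self, inventory):
        unknown = [r.gene_name for r in inventory if r.alternatives is None]
        assert sorted(unknown) == ["alaRS2", "aspRS2", "valRS2"]

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "inv.tsv"
        p.write_text(
            "organism\taars_type\tgene_name\tencoding_genome\tsubunit_kind\t"
            "predicted_localization\n"
        )
        assert a.read_inventory(p) == []

    @pytest.mark.parametrize(
        "cell,expected",
        [
            ("Cytosol", (frozenset({"cytosol"}),)),
            ("Plastid/mito", (frozenset({"plastid", "mitochondrion"}),)),
            ("Mitochondrion/PPC", (frozenset({"mitochondrion", "ppc"}),)),
            ("PPC or plastid", (frozenset({"ppc"}), frozenset({"plastid"}))),
            ("? (incomplete model)", None),
        ],
    )
    def test_localization_grammar(self, cell, expected):
        assert parse_localization(cell) == expected

    def test_bad_rows_name_the_line(self, tmp_path):
        header = (
            "organism\taars_type\tgene_name\tencoding_genome\tsubunit_kind\t"
            "predicted_localization\n"
        )
        p = tmp_path / "inv.tsv"
        p.write_text(header + "X\tfooRS\tg1\tnucleus\tstandard\tCytosol\n")
        with pytest.raises(InventoryParseError, match="line 2"):
            a.read_inventory(p)
        p.write_text(header + "X\talaRS\tg1\tnucleus\tstandard\tNucleus\n")
        with pytest.raises(InventoryParseError, match="line 2"):
            a.read_inventory(p)

    def test_roundtrip(self, inventory, tmp_path):
        out = tmp_path / "copy.tsv"
        from aarsloc.sequence_io import write_inventory

        write_inventory(inventory, out)
        assert a.read_inventory(out) == inventory


def _toy_models():
    return [
        a.GeneModel("m1", "s1", "+", ((4, 12),), 0),
        a.GeneModel("m2", "s1", "-", ((30, 38), (10, 20)), 0),
        a.GeneModel("m3", "s2", "+", ((1, 6), (10, 18)), 2),
    ]


class TestGeneModelIO:
    @pytest.mark.parametrize("suffix", ["json", "gff3"])
    def test_roundtrip_three_models(self, tmp_path, suffix):
        path = tmp_path / f"models.{suffix}"
        models = _toy_models()
        a.write_gene_models(models, path)
        assert a.read_gene_models(path) == sorted(models, key=lambda m: m.locus_id)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("+-"),
                st.integers(0, 2),
                st.lists(st.integers(1, 200), min_size=2, max_size=8, unique=True),
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_roundtrip_randomized(self, specs):
        """write o read is the identity on randomized valid models."""
        import tempfile
        from pathlib import Path

        models = []
        for i, (strand, phase, bounds) in enumerate(specs):
            bounds = sorted(bounds)
            segments = [
                (bounds[j], bounds[j + 1] - 1)
                for j in range(0, len(bounds) - 1, 2)
                if bounds[j] <= bounds[j + 1] - 1
            ]
            if not segments:
                continue
            if strand == "-":
                segments = segments[::-1]
            models.append(a.GeneModel(f"m{i}", "s", strand, tuple(segments), phase))
        if not models:
            return
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "models.json"
            a.write_gene_models(models, path)
            assert a.read_gene_models(path) == models

    def test_mixed_strand_gff_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "s\t.\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=g1\n"
            "s\t.\tCDS\t10\t15\t.\t-\t0\tID=c2;Parent=g1\n"
        )
        with pytest.raises(GeneModelError, match="mixed"):
            a.read_gene_models(p)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(GeneModelError, match="overlap"):
            a.GeneModel("m", "s", "+", ((1, 10), (5, 20)), 0)


class TestConceptualTranslate:
    def test_single_codon_plus(self):
        scaffold = a.SequenceRecord("s", "", "ATGGCATAA", "nucleotide")
        model = a.GeneModel("m", "s", "+", ((1, 9),), 0)
        assert a.conceptual_translate(model, scaffold).residues == "MA"

    def test_single_codon_minus(self):
        scaffold = a.SequenceRecord("s", "", reverse_complement("ATGGCATAA"), "nucleotide")
        model = a.GeneModel("m", "s", "-", ((1, 9),), 0)
        assert a.conceptual_translate(model, scaffold).residues == "MA"

    def test_internal_stop_reports_codon_offset(self):
        scaffold = a.SequenceRecord("s", "", "ATGTAGGCA", "nucleotide")
        model = a.GeneModel("m", "s", "+", ((1, 9),), 0)
        with pytest.raises(TranslationError) as err:
            a.conceptual_translate(model, scaffold)
        assert err.value.codon_offset == 2

    def test_ambiguous_base_gives_x(self):
        scaffold = a.SequenceRecord("s", "", "ATGGCNTAA", "nucleotide")
        model = a.GeneModel("m", "s", "+", ((1, 9),), 0)
        assert a.conceptual_translate(model, scaffold).residues == "MX"

    def test_two_exon_minus_strand_matches_manual_translation(self):
        """Hand-constructed 60 nt toy: two minus-strand exons, translation
        order descending in genomic coordinates."""
        exon2 = "GCCTTT"                       # ala phe after revcomp handling
        exon1 = "ATGAAA"                       # met lys
        # on the minus strand the transcript reads revcomp(exon1)+revcomp(exon2)
        scaffold_nt = "T" * 20 + reverse_complement(exon2) + "TTTT" + \
            reverse_complement(exon1) + "T" * 24
        scaffold = a.SequenceRecord("s", "", scaffold_nt, "nucleotide")
        model = a.GeneModel(
            "m", "s", "-",
            ((31, 36), (21, 26)),  # translation order: descending
            0,
        )
        assert a.conceptual_translate(model, scaffold).residues == "MKAF"

    def test_matches_bruteforce_codon_walk(self, rng):
        """Agreement with an independent per-strand codon-walk oracle on 100
        random toy models."""
        code = dict(a.sequence_io.CODON_TO_AA)
        for _ in range(100):
            n_codons = int(rng.integers(2, 20))
            codons = []
            while len(codons) < n_codons:
                c = "".join(rng.choice(list("ACGT"), size=3))
                if c not in ("TAA", "TAG", "TGA"):
                    codons.append(c)
            cds = "".join(codons)
            strand = "+" if rng.random() < 0.5 else "-"
            flank_l = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 10))))
            flank_r = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 10))))
            if strand == "+":
                scaffold_nt = flank_l + cds + flank_r
            else:
                rc = "".join(_COMPLEMENT[b] for b in reversed(cds))
                scaffold_nt = flank_l + rc + flank_r
            start = len(flank_l) + 1
            model = a.GeneModel(
                "m", "s", strand, ((start, start + len(cds) - 1),), 0
            )
            scaffold = a.SequenceRecord("s", "", scaffold_nt, "nucleotide")
            expected = "".join(code[c] for c in codons)
            assert a.conceptual_translate(model, scaffold).residues == expected


class TestProfiles:
    def test_packaged_profiles_load(self, gt_profile, pt_profile, tp_profile):
        assert gt_profile.has_ppc
        assert not pt_profile.has_ppc
        assert tp_profile.compartments == ("cytosol", "mitochondrion", "plastid")

    def test_cytosol_is_mandatory(self):
        with pytest.raises(ProfileError, match="cytosol"):
            profile_from_dict({"name": "x", "compartments": ["plastid"]})

    def test_trna_organelle_must_translate(self):
        with pytest.raises(ProfileError):
            profile_from_dict(
                {
                    "name": "x",
                    "compartments": ["cytosol", "mitochondrion"],
                    "organelle_trna_presence": {"nucleomorph": {"missing": []}},
                }
            )
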