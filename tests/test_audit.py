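"""Compartment accounting: required sets, functional units, assignment search."""

import itertools

import numpy as np
import pytest

import aarsloc as a
from aarsloc.audit import AuditError, FunctionalUnit, assign_type, required_set
from aarsloc.sequence_io import InventoryRow, ProfileError, profile_from_dict
from aarsloc.synthetic import DEFAULT_PARAMS, make_inventory

from .oracles import assignment_oracle


def _row(organism, aars_type, gene, loc, kind="standard", genome="nucleus"):
    from aarsloc.sequence_io import parse_localization

    return InventoryRow(
        organism=organism, aars_type=aars_type, gene_name=gene,
        encoding_genome=genome, subunit_kind=kind,
        alternatives=parse_localization(loc),
    )


class TestRequiredSet:
    def test_three_compartments_need_sixty(self):
        profile = profile_from_dict(
            {"name": "d", "compartments": ["cytosol", "mitochondrion", "plastid"]}
        )
        req = required_set(profile)
        assert req.total == 60
        assert not req.exclusions

    def test_four_compartments_need_eighty(self):
        profile = profile_from_dict(
            {"name": "c", "compartments": ["cytosol", "mitochondrion", "plastid", "ppc"]}
        )
        assert required_set(profile).total == 80

    def test_transamidation_removes_mitochondrial_glnrs(self, pt_profile):
        req = required_set(pt_profile)
        assert req.total == 59
        assert ("mitochondrion", "glnRS", "transamidation") in req.exclusions
        assert "glnRS" in req.required["cytosol"]

    def test_missing_trna_removes_requirement(self, gt_profile):
        req = required_set(gt_profile)
        assert ("mitochondrion", "lysRS", "trna_absent") in req.exclusions
        assert ("ppc", "gluRS", "trna_absent") in req.exclusions
        assert req.total == 78

    def test_unknown_transamidation_compartment_is_an_error(self):
        profile = profile_from_dict(
            {
                "name": "x",
                "compartments": ["cytosol", "mitochondrion"],
                "transamidation": [{"compartment": "plastid",
                                    "subunits": ["gatA", "gatB"]}],
            }
        )
        with pytest.raises(ProfileError, match="plastid"):
            required_set(profile)

    def test_totals_arithmetic_on_randomized_profiles(self, rng):
        """Sum of required cells is 20*|compartments| - |exclusions|, for
        random compartment sets, transamidation placements and missing tRNAs."""
        organelle_of = {"mitochondrion": "mitochondrion", "plastid": "plastid",
                        "ppc": "nucleomorph"}
        for _ in range(50):
            extra = [c for c in ("mitochondrion", "plastid", "ppc")
                     if rng.random() < 0.7]
            comps = ["cytosol"] + extra
            transam = [
                {"compartment": c, "subunits": ["gatA", "gatB"]}
                for c in extra if rng.random() < 0.3
            ]
            trna = {}
            for c in extra:
                missing = [aa for aa in a.sequence_io.AMINO_ACIDS
                           if rng.random() < 0.08]
                trna[organelle_of[c]] = {"missing": missing}
            profile = profile_from_dict(
                {"name": "r", "compartments": comps,
                 "organelle_trna_presence": trna, "transamidation": transam}
            )
            req = required_set(profile)
            assert req.total == 20 * len(comps) - len(req.exclusions)


class TestFunctionalUnits:
    def test_diatom_phers_set_resolves_to_three_complete_units(self, pt_profile):
        """Cytosolic alpha+beta pair, mitochondrial monomer, and a
        plastid-targeted alpha completed by the plastid-genome beta."""
        rows = [
            _row("Phaeodactylum tricornutum", "pheRS", "pheRS1a", "Cytosol", "alpha"),
            _row("Phaeodactylum tricornutum", "pheRS", "pheRS1b", "Cytosol", "beta"),
            _row("Phaeodactylum tricornutum", "pheRS", "pheRS2", "Mitochondrion", "monomer"),
            _row("Phaeodactylum tricornutum", "pheRS", "pheRS3", "Plastid", "alpha"),
        ]
        units = a.resolve_functional_units(rows, pt_profile)
        complete = [u for u in units if u.complete and u.alternatives]
        assert len(complete) == 3
        covered = {next(iter(u.alternatives[0])) for u in complete}
        assert covered == {"cytosol", "mitochondrion", "plastid"}
        pair = next(u for u in complete if "pheRS3" in u.members)
        assert "pheRS@plastid" in pair.members

    def test_monomer_needs_no_partner(self, tp_profile):
        rows = [_row("Thalassiosira pseudonana", "pheRS", "pheRS3", "Plastid", "monomer")]
        units = a.resolve_functional_units(rows, tp_profile)
        assert units[0].complete and units[0].alternatives == (frozenset({"plastid"}),)

    def test_unpaired_alpha_is_flagged_incomplete(self, tp_profile):
        rows = [_row("Thalassiosira pseudonana", "pheRS", "pheRSx", "Plastid", "alpha")]
        units = a.resolve_functional_units(rows, tp_profile)
        assert not units[0].complete
        assert "unpaired" in units[0].note

    def test_gat_rows_never_become_suppliers(self, pt_profile):
        rows = [_row("Phaeodactylum tricornutum", "gatA", "gatA", "Mitochondrion")]
        assert a.resolve_functional_units(rows) == []
        units = a.resolve_functional_units(rows, pt_profile)
        assert all("gatA" not in u.members for u in units)


@pytest.fixture(scope="module")
def reports(inventory):
    out = {}
    for org in ("Phaeodactylum tricornutum", "Thalassiosira pseudonana",
                "Guillardia theta"):
        profile = a.load_packaged_profile(org)
        rows = [r for r in inventory if r.organism == org]
        out[org] = a.audit(rows, profile)
    return out


class TestAuditFixture:
    def test_pt_has_seventeen_dual_plastid_mito_types(self, reports):
        duals = reports["Phaeodactylum tricornutum"].dual_types(
            ("plastid", "mitochondrion")
        )
        assert len(duals) == 17

    def test_pt_has_no_gaps(self, reports):
        assert reports["Phaeodactylum tricornutum"].gaps == ()

    def test_gt_argrs_ppc_gap(self, reports):
        gaps = {(t, c) for t, c, _ in reports["Guillardia theta"].gaps}
        assert ("argRS", "ppc") in gaps

    def test_gt_serrs_covered_by_nucleomorph_copy(self, reports):
        report = reports["Guillardia theta"]
        gaps = {t for t, _, _ in report.gaps}
        assert "serRS" not in gaps
        assert report.coverage[("serRS", "ppc")] == ("serRS@nucleomorph",)
        assert "serRS" in report.dual_types(("plastid", "mitochondrion"))

    def test_gt_mitochondrial_lysrs_is_surplus(self, reports):
        surplus = reports["Guillardia theta"].surplus
        assert ("lysRS2", "mitochondrion", "supplied but not required") in surplus

    def test_gt_ambiguous_types_reported_co_optimal(self, reports):
        co = reports["Guillardia theta"].co_optimal
        assert co["cysRS"] > 1 and co["glnRS"] > 1

    def test_wrong_organism_is_an_error(self, inventory, pt_profile):
        rows = [r for r in inventory if r.organism == "Guillardia theta"]
        with pytest.raises(AuditError):
            a.audit(rows, pt_profile)

    def test_coverage_matrix_is_total(self, reports):
        """Every required (type, compartment) cell appears exactly once, as
        supplied or as a gap."""
        for report in reports.values():
            gap_cells = {(t, c) for t, c, _ in report.gaps}
            for compartment, types in report.required.required.items():
                for t in types:
                    units = report.coverage[(t, compartment)]
                    assert bool(units) != ((t, compartment) in gap_cells)


class TestAssignmentSearch:
    def _check_instance(self, suppliers, required):
        usable = [(u, alts) for u, alts in suppliers if alts is not None]
        units = [
            FunctionalUnit(unit_id=u, aars_type="t", members=(u,),
                           alternatives=alts)
            for u, alts in suppliers
        ]
        result = assign_type("t", units, required)
        assert result.cost == assignment_oracle(usable, frozenset(required))
        for unit_id, alt, served in result.assignment:
            assert served <= alt & frozenset(required)

    def test_matches_bruteforce_on_fixture_instances(self, inventory):
        for org in ("Phaeodactylum tricornutum", "Guillardia theta"):
            profile = a.load_packaged_profile(org)
            req = required_set(profile)
            units = a.resolve_functional_units(
                [r for r in inventory if r.organism == org], profile
            )
            for aars_type in a.sequence_io.AARS_TYPES:
                suppliers = [
                    (u.unit_id, u.alternatives)
                    for u in units
                    if u.aars_type == aars_type and u.complete
                ]
                self._check_instance(suppliers, req.compartments_for(aars_type))

    def test_matches_bruteforce_on_random_instances(self, rng):
        comps = list(a.sequence_io.COMPARTMENTS)
        for _ in range(200):
            required = [c for c in comps if rng.random() < 0.8] or ["cytosol"]
            n_units = int(rng.integers(0, 5))
            suppliers = []
            for i in range(n_units):
                n_alts = int(rng.integers(1, 3))
                alts = []
                for _ in range(n_alts):
                    alt = frozenset(c for c in comps if rng.random() < 0.45)
                    if alt:
                        alts.append(alt)
                suppliers.append((f"u{i}", tuple(alts) or None))
            self._check_instance(suppliers, required)


class TestAuditOnSyntheticInventories:
    def test_saturated_inventory_has_no_gaps_or_duals(self, rng):
        """One single-compartment locus per required cell: zero gaps, zero
        dual assignments, across randomized profiles."""
        for _ in range(20):
            comps = ["cytosol"] + [
                c for c in ("mitochondrion", "plastid", "ppc") if rng.random() < 0.7
            ]
            profile = profile_from_dict({"name": "r", "compartments": comps})
            params = DEFAULT_PARAMS.__class__(
                inventory=a.synthetic.InventoryGenParams(dual_fraction=0.0)
            )
            rows, truth = make_inventory(profile, params, rng)
            report = a.audit(rows, profile)
            assert report.gaps == ()
            assert report.dual_assignments == ()

    def test_planted_gap_is_reported_exactly(self, rng, pt_profile):
        params = a.synthetic.SynthParams(
            inventory=a.synthetic.InventoryGenParams(
                dual_fraction=0.0, planted_gaps=(("argRS", "ppc"), ("alaRS", "plastid")),
            )
        )
        rows, truth = make_inventory(pt_profile, params, rng)
        report = a.audit(rows, pt_profile)
        assert {(t, c) for t, c, _ in report.gaps} == {("alaRS", "plastid")}

    def test_planted_assignments_recovered(self, rng, pt_profile):
        recovered = total = 0
        for _ in range(30):
            rows, truth = make_inventory(pt_profile, DEFAULT_PARAMS, rng)
            report = a.audit(rows, pt_profile)
            assigned = {}
            for compartment_key, units in report.coverage.items():
                for u in units:
                    assigned.setdefault(u, set()).add(compartment_key[1])
            for gene, expected in truth.expected_assignments.items():
                total += 1
                recovered += assigned.get(gene, set()) == set(expected)
        assert recovered / total >= 0.95


class TestSummarizeCounts:
    def test_totals(self, inventory):
        summary = a.summarize_counts(inventory)
        assert summary["Guillardia theta"]["n_nuclear_aars_loci"] == 58
        assert summary["Phaeodactylum tricornutum"]["n_nuclear_aars_loci"] == 43
        assert summary["Thalassiosira pseudonana"]["n_nuclear_aars_loci"] == 43

    def test_per_type_counts(self, inventory):
        summary = a.summarize_counts(inventory)
        assert summary["Guillardia theta"]["loci_per_type"]["lysRS"] == 4
        for org in ("Phaeodactylum tricornutum", "Thalassiosira pseudonana"):
            assert summary[org]["loci_per_type"]["pheRS"] == 4
            assert summary[org]["loci_per_type"]["cysRS"] == 3

    def test_cytosolic_phers_merge_gives_fifteen_triples(self, inventory):
        merged = a.summarize_counts(inventory, merge_phe_cytosolic_pair=True)
        dist = merged["Guillardia theta"]["copies_distribution"]
        assert dist[3] == 15
        unmerged = a.summarize_counts(inventory)
        assert unmerged["Guillardia theta"]["copies_distribution"].get(3, 0) == 14
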