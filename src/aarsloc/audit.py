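"""Compartment accounting: required synthetase sets, coverage, forced duals.

Every translating compartment needs all 20 synthetase activities, minus two
documented exceptions: a compartment hosting both amidotransferase subunits
can transamidate mischarged glu-tRNA(gln) instead of importing a glnRS, and
an organelle whose genome lacks a tRNA may import it charged, removing the
corresponding synthetase requirement. Comparing this requirement against the
capability sets supplied by the inventory forces dual assignments wherever
loci are scarce, and exposes gaps and surplus otherwise.

Per synthetase type the locus-to-compartment assignment is found by
exhaustive enumeration (instances are tiny) under a lexicographic parsimony:
fewest uncovered required cells, then fewest multi-compartment loci, then
fewest total assignments. Co-optimal assignments are reported, never
silently dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .caller import LocalizationCall
from .sequence_io import (
    AARS_TYPES,
    AMINO_ACIDS,
    COMPARTMENTS,
    InventoryRow,
    OrganismProfile,
    ORGANELLE_TO_COMPARTMENT,
    ProfileError,
)

REASON_TRANSAMIDATION = "transamidation"
REASON_TRNA_ABSENT = "trna_absent"

_COMP_ORDER = {c: i for i, c in enumerate(COMPARTMENTS)}


class AuditError(ValueError):
    pass


@dataclass(frozen=True)
class RequiredSet:
    """Per-compartment required synthetase activities, with exclusions."""

    required: dict[str, frozenset[str]]
    exclusions: tuple[tuple[str, str, str], ...]  # (compartment, aars_type, reason)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.required.values())

    def compartments_for(self, aars_type: str) -> tuple[str, ...]:
        return tuple(
            c for c in self.required if aars_type in self.required[c]
        )


def required_set(profile: OrganismProfile) -> RequiredSet:
    """The synthetase requirement matrix of one organism.

    Starts from 20 activities per translating compartment, then removes
    glnRS (and asnRS where configured) from compartments hosting both
    amidotransferase subunits, and removes activity X from an organelle
    compartment whose genome lacks tRNA(X).
    """
    required = {c: set(AARS_TYPES) for c in profile.compartments}
    exclusions: list[tuple[str, str, str]] = []
    for compartment, subunits in profile.transamidation:
        if compartment not in profile.compartments:
            raise ProfileError(
                f"{profile.name}: transamidation names unknown compartment "
                f"{compartment!r}"
            )
        if {"gatA", "gatB"} <= set(subunits):
            targets = ["glnRS"]
            if profile.remove_asnrs_on_transamidation:
                targets.append("asnRS")
            for t in targets:
                if t in required[compartment]:
                    required[compartment].discard(t)
                    exclusions.append((compartment, t, REASON_TRANSAMIDATION))
    for organelle, presence in profile.organelle_trna_presence.items():
        compartment = ORGANELLE_TO_COMPARTMENT[organelle]
        for aa in AMINO_ACIDS:
            if not presence.get(aa, True):
                t = aa + "RS"
                if t in required[compartment]:
                    required[compartment].discard(t)
                    exclusions.append((compartment, t, REASON_TRNA_ABSENT))
    return RequiredSet(
        required={c: frozenset(v) for c, v in required.items()},
        exclusions=tuple(sorted(exclusions)),
    )


@dataclass(frozen=True)
class FunctionalUnit:
    """One supplier of a synthetase activity.

    Most loci map one-to-one; pheRS can serve a compartment either as a
    monomer or as a co-localizable alpha+beta pair (organelle-genome-encoded
    subunits pair with imported nuclear partners). ``alternatives`` is None
    for unusable suppliers (unknown localization or incomplete pair).
    """

    unit_id: str
    aars_type: str
    members: tuple[str, ...]
    alternatives: tuple[frozenset[str], ...] | None
    complete: bool = True
    note: str = ""


def _pair_alternatives(
    a: tuple[frozenset[str], ...], b: tuple[frozenset[str], ...]
) -> tuple[frozenset[str], ...]:
    seen, out = set(), []
    for x, y in itertools.product(a, b):
        inter = x & y
        if inter and inter not in seen:
            seen.add(inter)
            out.append(inter)
    return tuple(out)


def resolve_functional_units(
    rows: Sequence[InventoryRow],
    profile: OrganismProfile | None = None,
) -> list[FunctionalUnit]:
    """Map inventory rows (plus profile-injected organelle genes) to suppliers.

    Amidotransferase rows are evidence for the transamidation exception only
    and never become synthetase suppliers.
    """
    units: list[FunctionalUnit] = []
    injected: list[InventoryRow] = []
    if profile is not None:
        for aars_type, subunit_kind, organelle in profile.organelle_encoded_aars:
            compartment = ORGANELLE_TO_COMPARTMENT[organelle]
            injected.append(
                InventoryRow(
                    organism=profile.name,
                    aars_type=aars_type,
                    gene_name=f"{aars_type}@{organelle}",
                    encoding_genome=organelle,
                    subunit_kind=subunit_kind,
                    alternatives=(frozenset({compartment}),),
                )
            )
    pool = [r for r in list(rows) + injected if not r.is_gat]

    for aars_type in sorted({r.aars_type for r in pool}):
        members = [r for r in pool if r.aars_type == aars_type]
        alphas = [r for r in members if r.subunit_kind == "alpha"]
        betas = [r for r in members if r.subunit_kind == "beta"]
        rest = [r for r in members if r.subunit_kind not in ("alpha", "beta")]
        for r in rest:
            units.append(
                FunctionalUnit(
                    unit_id=r.gene_name,
                    aars_type=aars_type,
                    members=(r.gene_name,),
                    alternatives=r.alternatives,
                    note="" if r.alternatives is not None else "unknown localization",
                )
            )
        if not alphas and not betas:
            continue
        # pair each alpha with a co-localizable beta; tiny instances, so try
        # every injective pairing and keep the one with the most usable pairs
        best_pairs: list[tuple[InventoryRow, InventoryRow]] = []
        order = range(len(betas))
        for perm in itertools.permutations(order, min(len(alphas), len(betas))):
            pairs = []
            for a, bi in zip(alphas, perm):
                b = betas[bi]
                if a.alternatives is None or b.alternatives is None:
                    continue
                if _pair_alternatives(a.alternatives, b.alternatives):
                    pairs.append((a, b))
            if len(pairs) > len(best_pairs):
                best_pairs = pairs
        paired = {id(r) for a, b in best_pairs for r in (a, b)}
        for a, b in best_pairs:
            units.append(
                FunctionalUnit(
                    unit_id=f"{a.gene_name}+{b.gene_name}",
                    aars_type=aars_type,
                    members=(a.gene_name, b.gene_name),
                    alternatives=_pair_alternatives(a.alternatives, b.alternatives),
                )
            )
        for r in alphas + betas:
            if id(r) not in paired:
                units.append(
                    FunctionalUnit(
                        unit_id=r.gene_name,
                        aars_type=aars_type,
                        members=(r.gene_name,),
                        alternatives=None,
                        complete=False,
                        note=f"unpaired {r.subunit_kind} subunit",
                    )
                )
    units.sort(key=lambda u: (u.aars_type, u.unit_id))
    return units


# ---------------------------------------------------------------------------
# Per-type assignment search

def _supplier_options(
    alternatives: tuple[frozenset[str], ...], required: frozenset[str]
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """(capability set, served subset) choices for one supplier, in
    deterministic order: alternatives as given, subsets by size then
    compartment order."""
    options = []
    for alt in alternatives:
        usable = sorted(alt & required, key=_COMP_ORDER.__getitem__)
        for size in range(len(usable) + 1):
            for combo in itertools.combinations(usable, size):
                options.append((alt, frozenset(combo)))
    return options


@dataclass(frozen=True)
class TypeAssignment:
    aars_type: str
    required: tuple[str, ...]
    assignment: tuple[tuple[str, frozenset[str], frozenset[str]], ...]
    # (unit_id, chosen capability set, served compartments)
    gaps: tuple[str, ...]
    n_co_optimal: int

    @property
    def cost(self) -> tuple[int, int, int]:
        multi = sum(len(served) > 1 for *_, served in self.assignment)
        total = sum(len(served) for *_, served in self.assignment)
        return (len(self.gaps), multi, total)


def assign_type(
    aars_type: str,
    suppliers: Sequence[FunctionalUnit],
    required: Iterable[str],
) -> TypeAssignment:
    """Exhaustive lexicographic-parsimony assignment for one synthetase type."""
    required_set_ = frozenset(required)
    usable = [u for u in suppliers if u.alternatives is not None and u.complete]
    per_unit = [
        _supplier_options(u.alternatives, required_set_) for u in usable
    ]
    reachable = [frozenset().union(*(alt for alt, _ in opts)) if opts else frozenset()
                 for opts in per_unit]
    suffix_reach = [frozenset()] * (len(usable) + 1)
    for i in range(len(usable) - 1, -1, -1):
        suffix_reach[i] = suffix_reach[i + 1] | (reachable[i] & required_set_)

    best_cost: tuple[int, int, int] | None = None
    best_solutions: list[tuple[tuple[frozenset[str], frozenset[str]], ...]] = []

    def dfs(i: int, covered: frozenset[str], multi: int, total: int,
            chosen: list[tuple[frozenset[str], frozenset[str]]]):
        nonlocal best_cost, best_solutions
        optimistic_gaps = len(required_set_ - covered - suffix_reach[i])
        if best_cost is not None and (optimistic_gaps, multi, total) > best_cost:
            return
        if i == len(usable):
            cost = (len(required_set_ - covered), multi, total)
            if best_cost is None or cost < best_cost:
                best_cost = cost
                best_solutions = [tuple(chosen)]
            elif cost == best_cost:
                best_solutions.append(tuple(chosen))
            return
        for alt, served in per_unit[i]:
            chosen.append((alt, served))
            dfs(
                i + 1,
                covered | served,
                multi + (len(served) > 1),
                total + len(served),
                chosen,
            )
            chosen.pop()

    dfs(0, frozenset(), 0, 0, [])
    if best_cost is None:  # no usable suppliers at all
        best_cost = (len(required_set_), 0, 0)
        best_solutions = [()]
    solution = best_solutions[0]
    assignment = tuple(
        (u.unit_id, alt, served)
        for u, (alt, served) in zip(usable, solution)
    )
    covered = frozenset().union(*(s for *_, s in assignment)) if assignment else frozenset()
    gaps = tuple(sorted(required_set_ - covered, key=_COMP_ORDER.__getitem__))
    # distinct co-optimal solutions (identical tuples can arise from
    # identical capability alternatives)
    n_co = len(set(best_solutions))
    return TypeAssignment(
        aars_type=aars_type,
        required=tuple(sorted(required_set_, key=_COMP_ORDER.__getitem__)),
        assignment=assignment,
        gaps=gaps,
        n_co_optimal=n_co,
    )


# ---------------------------------------------------------------------------
# Whole-organism audit

@dataclass(frozen=True)
class AuditReport:
    organism: str
    required: RequiredSet
    coverage: dict[tuple[str, str], tuple[str, ...]]  # (type, compartment) -> units
    dual_assignments: tuple[tuple[str, str, frozenset[str]], ...]
    gaps: tuple[tuple[str, str, str], ...]            # (type, compartment, note)
    surplus: tuple[tuple[str, str, str], ...]         # (unit, compartment, note)
    co_optimal: dict[str, int]
    functional_units: tuple[FunctionalUnit, ...]
    notes: tuple[str, ...] = ()

    def dual_types(self, compartments: Iterable[str]) -> set[str]:
        """Synthetase types whose optimal assignment includes one locus
        serving every compartment in ``compartments``."""
        wanted = frozenset(compartments)
        return {
            aars_type
            for _, aars_type, served in self.dual_assignments
            if wanted <= served
        }

    def to_json_dict(self) -> dict:
        return {
            "organism": self.organism,
            "required": {c: sorted(v) for c, v in self.required.required.items()},
            "exclusions": [list(e) for e in self.required.exclusions],
            "coverage": {
                f"{t}:{c}": list(units) if units else ["GAP"]
                for (t, c), units in sorted(self.coverage.items())
            },
            "dual_assignments": [
                [unit, t, sorted(served)] for unit, t, served in self.dual_assignments
            ],
            "gaps": [list(g) for g in self.gaps],
            "surplus": [list(s) for s in self.surplus],
            "co_optimal": dict(sorted(self.co_optimal.items())),
            "notes": list(self.notes),
        }


def _rows_from_calls(
    calls: Sequence[LocalizationCall],
    aars_types: dict[str, str],
    organism: str,
) -> list[InventoryRow]:
    rows = []
    for call in calls:
        alternatives = tuple(dict.fromkeys(call.alternatives))
        rows.append(
            InventoryRow(
                organism=organism,
                aars_type=aars_types[call.locus_id],
                gene_name=call.locus_id,
                encoding_genome="nucleus",
                subunit_kind="standard",
                alternatives=alternatives,
            )
        )
    return rows


def audit(
    inventory: Sequence[InventoryRow] | Sequence[LocalizationCall],
    profile: OrganismProfile,
    aars_types: dict[str, str] | None = None,
) -> AuditReport:
    """Audit one organism's inventory against its requirement matrix.

    ``inventory`` is either parsed inventory rows or locus-level localization
    calls (the latter need ``aars_types`` mapping locus id to synthetase
    type). Organelle-genome-encoded synthetases from the profile are injected
    as fixed-compartment suppliers.
    """
    if inventory and isinstance(inventory[0], LocalizationCall):
        rows = _rows_from_calls(inventory, aars_types or {}, profile.name)
    else:
        rows = list(inventory)
        for r in rows:
            if r.organism != profile.name:
                raise AuditError(
                    f"inventory row {r.gene_name} belongs to {r.organism!r}, "
                    f"profile is {profile.name!r}"
                )
    req = required_set(profile)
    units = resolve_functional_units(rows, profile)

    coverage: dict[tuple[str, str], tuple[str, ...]] = {}
    duals: list[tuple[str, str, frozenset[str]]] = []
    gaps: list[tuple[str, str, str]] = []
    surplus: list[tuple[str, str, str]] = []
    co_optimal: dict[str, int] = {}
    notes: list[str] = []

    for aars_type in AARS_TYPES:
        required_comps = req.compartments_for(aars_type)
        suppliers = [u for u in units if u.aars_type == aars_type]
        for u in suppliers:
            if u.alternatives is None:
                notes.append(f"{u.unit_id}: unusable supplier ({u.note})")
        result = assign_type(aars_type, suppliers, required_comps)
        co_optimal[aars_type] = result.n_co_optimal
        serving: dict[str, list[str]] = {c: [] for c in required_comps}
        for unit_id, alt, served in result.assignment:
            for c in served:
                serving[c].append(unit_id)
            if len(served) > 1:
                duals.append((unit_id, aars_type, served))
            for c in sorted(alt - set(required_comps), key=_COMP_ORDER.__getitem__):
                surplus.append((unit_id, c, "supplied but not required"))
        for c in required_comps:
            coverage[(aars_type, c)] = tuple(serving[c])
        for c in result.gaps:
            gaps.append((aars_type, c, "no supplying locus"))

    return AuditReport(
        organism=profile.name,
        required=req,
        coverage=coverage,
        dual_assignments=tuple(duals),
        gaps=tuple(gaps),
        surplus=tuple(surplus),
        co_optimal=co_optimal,
        functional_units=tuple(units),
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Inventory summaries

def summarize_counts(
    rows: Sequence[InventoryRow], merge_phe_cytosolic_pair: bool = False
) -> dict[str, dict]:
    """Per-organism locus counts (amidotransferase rows excluded throughout).

    With ``merge_phe_cytosolic_pair`` the cytosolic pheRS alpha+beta pair
    counts as one functional copy; the merge is never applied silently.
    """
    out: dict[str, dict] = {}
    for organism in dict.fromkeys(r.organism for r in rows):
        mine = [r for r in rows if r.organism == organism and not r.is_gat]
        nuclear = [r for r in mine if r.encoding_genome == "nucleus"]
        per_type: dict[str, int] = {}
        for r in nuclear:
            per_type[r.aars_type] = per_type.get(r.aars_type, 0) + 1
        functional = dict(per_type)
        if merge_phe_cytosolic_pair and "pheRS" in functional:
            cyt = frozenset({"cytosol"})
            phe = [r for r in nuclear if r.aars_type == "pheRS"]
            n_pairs = min(
                sum(1 for r in phe
                    if r.subunit_kind == "alpha" and r.alternatives == (cyt,)),
                sum(1 for r in phe
                    if r.subunit_kind == "beta" and r.alternatives == (cyt,)),
            )
            functional["pheRS"] -= n_pairs
        distribution: dict[int, int] = {}
        for n in functional.values():
            distribution[n] = distribution.get(n, 0) + 1
        out[organism] = {
            "n_nuclear_aars_loci": len(nuclear),
            "loci_per_type": dict(sorted(per_type.items())),
            "functional_copies_per_type": dict(sorted(functional.items())),
            "copies_distribution": dict(sorted(distribution.items())),
        }
    return out
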