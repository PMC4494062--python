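"""Ground-truth synthetic data: targeting peptides, whole loci with genomic
context, and whole-organism inventories.

Every emitted object carries labels that are true by construction: peptides
are assembled block-by-block from the stated anatomy of each signal class,
genomic scaffolds are back-translated with planted upstream ATG/stop
structure guaranteeing a unique correct 5' extension, and inventories plant
exactly the compartment-sharing structure the audit must recover.

Alphabet discipline does the heavy lifting: blocks upstream of the conserved
domain avoid methionine except at planted starts (so the variant set is
known), and avoid the small (-3,-1)-rule residues except in planted c-regions
(so the admissible cleavage site is unique or dominated by the planted one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gene_models import (
    STATUS_EXTENDED,
    STATUS_NO_UPSTREAM_ATG,
    STATUS_SCAFFOLD_EDGE,
    STATUS_STOP_ADJACENT,
)
from .sequence_io import (
    CODON_TO_AA,
    GeneModel,
    InventoryRow,
    OrganismProfile,
    SequenceRecord,
    reverse_complement,
)
from .audit import required_set

_SYNONYMOUS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    _SYNONYMOUS.setdefault(aa, []).append(codon)
_STOPS = ("TAA", "TAG", "TGA")
#: codons that are neither starts nor stops, for upstream padding
_NEUTRAL_CODONS = tuple(
    c for c in sorted(CODON_TO_AA) if c != "ATG" and c not in _STOPS
)

#: background amino-acid composition (approximate proteome frequencies)
_BG_LETTERS = "ARNDCQEGHILKMFPSTWYV"
_BG_WEIGHTS = np.array(
    [7, 5, 4, 5, 1, 4, 6, 7, 2, 5, 9, 6, 2, 4, 5, 7, 6, 1, 3, 6], dtype=float
)
_BG_WEIGHTS /= _BG_WEIGHTS.sum()


@dataclass(frozen=True)
class SignalGenParams:
    n_basic_range: tuple[int, int] = (2, 4)     # K/R residues after the M
    h_length_range: tuple[int, int] = (10, 12)  # hydrophobic core length
    h_alphabet: str = "LIF"
    c_length: int = 3                            # c-region, all small residues
    c_alphabet: str = "AS"


@dataclass(frozen=True)
class PresequenceGenParams:
    length_range: tuple[int, int] = (24, 36)
    helix_period: float = 3.6                    # residues per helical turn
    hydrophobic_alphabet: str = "LF"
    basic_alphabet: str = "RK"
    basic_prob: float = 0.65
    filler_alphabet: str = "NQ"
    target_charge20: int = 6                     # minimum net charge, first 20

    def __post_init__(self):
        if self.target_charge20 <= 0:
            raise ValueError(
                "contradictory presequence parameters: target net charge "
                "must be positive"
            )


@dataclass(frozen=True)
class TplGenParams:
    length_range: tuple[int, int] = (18, 28)
    plus_one_pool_plastid: str = "FWYL"
    plus_one_pool_ppc: str = "ANQST"             # anything outside F/W/Y/L
    guard_length: int = 5                        # first residues kept non-small
    guard_alphabet: str = "NQ"
    body_alphabet: str = "STANQG"


@dataclass(frozen=True)
class LocusGenParams:
    dual_fraction: float = 0.5
    ambiguous_mechanism_prob: float = 0.5        # vs alternate_start
    truncated_prob: float = 0.35                 # annotated model 5'-truncated
    edge_prob: float = 0.05                      # annotated start at scaffold edge
    upstream_pad_codons: tuple[int, int] = (4, 10)
    decoy_upstream_atg_prob: float = 0.5         # ATG beyond the blocking stop
    spacer_range: tuple[int, int] = (8, 16)
    spacer_alphabet: str = "NQE"
    body_range: tuple[int, int] = (60, 120)
    anchor: str = "WHIDPKNERLYF"                 # conserved-domain stand-in

    def __post_init__(self):
        if not 0 <= self.dual_fraction <= 1:
            raise ValueError("dual_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class InventoryGenParams:
    dual_fraction: float = 0.6
    planted_gaps: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class SynthParams:
    signal: SignalGenParams = field(default_factory=SignalGenParams)
    presequence: PresequenceGenParams = field(default_factory=PresequenceGenParams)
    tpl: TplGenParams = field(default_factory=TplGenParams)
    locus: LocusGenParams = field(default_factory=LocusGenParams)
    inventory: InventoryGenParams = field(default_factory=InventoryGenParams)


DEFAULT_PARAMS = SynthParams()


@dataclass(frozen=True)
class PeptideFragment:
    sequence: str
    peptide_class: str
    cleavage_site: int | None = None             # for signal fragments


@dataclass(frozen=True)
class LocusTruth:
    locus_id: str
    compartments: frozenset[str]
    mechanism: str                               # none | ambiguous_peptide | alternate_start
    variant_labels: tuple[tuple[int, frozenset[str]], ...]
    domain_start: int
    expected_status: str
    expected_codons_added: int
    expected_extended_segments: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SimulatedLocus:
    scaffold: SequenceRecord
    model: GeneModel                             # the annotated (possibly truncated) model
    protein: SequenceRecord                      # full-length product
    anchor: str
    truth: LocusTruth


def _draw(rng: np.random.Generator, letters: str, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(list(letters), size=n))


def _draw_background(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(list(_BG_LETTERS), size=n, p=_BG_WEIGHTS))


def _helix_positions(length: int, period: float) -> set[int]:
    positions, j = set(), 0
    while True:
        k = round(j * period)
        if k >= length:
            return positions
        positions.add(k)
        j += 1


def make_peptide(
    peptide_class: str,
    params: SynthParams = DEFAULT_PARAMS,
    rng: np.random.Generator | None = None,
) -> PeptideFragment:
    """Draw one labeled peptide fragment of the requested class.

    ``signal`` fragments start with M and end at their cleavage site;
    ``presequence`` fragments start with M; ``tpl_*`` fragments begin with the
    discriminating +1 residue; ``cytosolic`` is composition-matched background.
    """
    rng = np.random.default_rng() if rng is None else rng
    if peptide_class == "signal":
        p = params.signal
        n_basic = int(rng.integers(p.n_basic_range[0], p.n_basic_range[1] + 1))
        h_len = int(rng.integers(p.h_length_range[0], p.h_length_range[1] + 1))
        seq = (
            "M"
            + _draw(rng, "KR", n_basic)
            + _draw(rng, p.h_alphabet, h_len)
            + _draw(rng, p.c_alphabet, p.c_length)
        )
        return PeptideFragment(seq, "signal", cleavage_site=len(seq))
    if peptide_class == "presequence":
        p = params.presequence
        length = int(rng.integers(p.length_range[0], p.length_range[1] + 1))
        helix = _helix_positions(length, p.helix_period)
        residues = ["M"]
        for k in range(1, length):
            if k in helix:
                residues.append(str(rng.choice(list(p.hydrophobic_alphabet))))
            elif rng.random() < p.basic_prob:
                residues.append(str(rng.choice(list(p.basic_alphabet))))
            else:
                residues.append(str(rng.choice(list(p.filler_alphabet))))
        # top up the N-terminal net charge to the configured target
        window = min(20, length)
        charge = sum(r in "KR" for r in residues[:window])
        for k in range(1, window):
            if charge >= p.target_charge20:
                break
            if residues[k] in p.filler_alphabet:
                residues[k] = "R"
                charge += 1
        return PeptideFragment("".join(residues), "presequence")
    if peptide_class in ("tpl_plastid", "tpl_ppc"):
        p = params.tpl
        pool = (
            p.plus_one_pool_plastid
            if peptide_class == "tpl_plastid"
            else p.plus_one_pool_ppc
        )
        length = int(rng.integers(p.length_range[0], p.length_range[1] + 1))
        seq = (
            str(rng.choice(list(pool)))
            + _draw(rng, p.guard_alphabet, p.guard_length)
            + _draw(rng, p.body_alphabet, length - 1 - p.guard_length)
        )
        return PeptideFragment(seq, peptide_class)
    if peptide_class == "cytosolic":
        length = int(rng.integers(25, 46))
        return PeptideFragment(_draw_background(rng, length), "cytosolic")
    raise ValueError(f"unknown peptide class {peptide_class!r}")


def _make_ambiguous_nterm(params: SynthParams, rng: np.random.Generator) -> str:
    """One N-terminus that satisfies both the signal and presequence scorers.

    Layout: basic start, hydrophobic h-region inside residues 3..20, a second
    basic block, an amphipathic helix inside residues 20..37 (high muH with
    net positive charge), and a unique admissible cleavage site at residue 40
    (the flanking alphabets carry no small residues).
    """
    helix = _helix_positions(18, params.presequence.helix_period)
    amphipathic = []
    for j in range(18):
        if j in helix:
            amphipathic.append(str(rng.choice(["L", "F"])))
        elif rng.random() < 0.6:
            amphipathic.append(str(rng.choice(["R", "K"])))
        else:
            amphipathic.append(str(rng.choice(["N", "Q"])))
    return (
        "M"
        + _draw(rng, "RK", 2)                 # residues 2-3
        + _draw(rng, "LIF", 10)               # residues 4-13: h-region
        + _draw(rng, "RK", 6)                 # residues 14-19
        + "".join(amphipathic)                # residues 20-37
        + "ANA"                               # residues 38-40: c-region
    )


def make_locus(
    compartments: frozenset[str] | set[str],
    mechanism: str,
    params: SynthParams = DEFAULT_PARAMS,
    rng: np.random.Generator | None = None,
    locus_id: str = "locus",
    profile: OrganismProfile | None = None,
) -> SimulatedLocus:
    """Assemble one locus (protein + genomic scaffold) for a desired truth.

    The protein is N-terminal targeting blocks + conserved-domain anchor +
    background body; the scaffold is its back-translation with planted
    upstream in-frame ATG/stop structure matching the labeled 5' extension.
    """
    rng = np.random.default_rng() if rng is None else rng
    compartments = frozenset(compartments)
    if profile is not None and not compartments <= set(profile.compartments):
        raise ValueError(
            f"requested compartments {sorted(compartments)} outside profile"
        )
    lp = params.locus
    spacer = _draw(rng, lp.spacer_alphabet,
                   int(rng.integers(lp.spacer_range[0], lp.spacer_range[1] + 1)))
    body = _draw_background(rng, int(rng.integers(lp.body_range[0], lp.body_range[1] + 1)))

    planted: list[tuple[int, frozenset[str]]] = []
    if compartments == {"cytosol"}:
        nterm = "M" + _draw_background(rng, int(rng.integers(25, 45)))
        prefix = nterm + spacer
        planted.append((1, frozenset({"none"})))
    elif compartments == {"mitochondrion"}:
        prefix = make_peptide("presequence", params, rng).sequence + spacer
        planted.append((1, frozenset({"presequence"})))
    elif compartments in ({"plastid"}, {"ppc"}, frozenset({"plastid"}), frozenset({"ppc"})):
        tpl_class = "tpl_plastid" if "plastid" in compartments else "tpl_ppc"
        prefix = (
            make_peptide("signal", params, rng).sequence
            + make_peptide(tpl_class, params, rng).sequence
            + spacer
        )
        planted.append((1, frozenset({"signal"})))
    elif compartments == {"plastid", "mitochondrion"}:
        if mechanism == "ambiguous_peptide":
            prefix = (
                _make_ambiguous_nterm(params, rng)
                + make_peptide("tpl_plastid", params, rng).sequence
                + spacer
            )
            planted.append((1, frozenset({"signal", "presequence"})))
        elif mechanism == "alternate_start":
            signal_part = (
                make_peptide("signal", params, rng).sequence
                + make_peptide("tpl_plastid", params, rng).sequence
            )
            preseq = make_peptide("presequence", params, rng).sequence
            prefix = signal_part + preseq + spacer
            planted.append((1, frozenset({"signal"})))
            planted.append((len(signal_part) + 1, frozenset({"presequence"})))
        else:
            raise ValueError(
                f"dual plastid/mitochondrion locus needs a mechanism, got {mechanism!r}"
            )
    else:
        raise ValueError(f"unsupported truth compartments {sorted(compartments)}")

    protein_str = prefix + lp.anchor + body
    domain_start = len(prefix) + 1
    planted_index = dict(planted)
    labels = tuple(
        (i + 1, planted_index.get(i + 1, frozenset({"none"})))
        for i in range(domain_start - 1)
        if protein_str[i] == "M"
    )

    # ---- back-translate and plant the upstream genomic structure
    codons = [str(rng.choice(_SYNONYMOUS[aa])) for aa in protein_str]
    cds_nt = "".join(codons) + str(rng.choice(_STOPS))

    truncation_candidates = [i for i, _ in labels if 1 < i]
    truncate = bool(truncation_candidates) and rng.random() < lp.truncated_prob
    if truncate:
        t = int(rng.choice(truncation_candidates))
        expected_status, codons_added = STATUS_EXTENDED, t - 1
    else:
        t = 1
        roll = rng.random()
        if roll < lp.edge_prob:
            expected_status, codons_added = STATUS_SCAFFOLD_EDGE, 0
        elif roll < 0.5 + lp.edge_prob:
            expected_status, codons_added = STATUS_STOP_ADJACENT, 0
        else:
            expected_status, codons_added = STATUS_NO_UPSTREAM_ATG, 0

    upstream_parts: list[str] = []
    if expected_status == STATUS_SCAFFOLD_EDGE:
        upstream_parts.append(_draw(rng, "ACGT", int(rng.integers(0, 3))))
    else:
        n_pad = int(rng.integers(lp.upstream_pad_codons[0], lp.upstream_pad_codons[1] + 1))
        pad = [str(rng.choice(_NEUTRAL_CODONS)) for _ in range(n_pad)]
        if pad and rng.random() < lp.decoy_upstream_atg_prob:
            # an ATG beyond the blocking stop must never be reached
            pad[int(rng.integers(0, len(pad)))] = "ATG"
        upstream_parts.extend(pad)
        upstream_parts.append(str(rng.choice(_STOPS)))
        if expected_status == STATUS_NO_UPSTREAM_ATG:
            upstream_parts.extend(
                str(rng.choice(_NEUTRAL_CODONS))
                for _ in range(int(rng.integers(1, 6)))
            )
        # for a truncated model (STATUS_EXTENDED) the codons of residues
        # 1..t-1 already sit inside the CDS upstream of the annotated start,
        # so the blocking stop goes directly before the full CDS

    upstream_nt = "".join(upstream_parts)
    downstream_nt = _draw(rng, "ACGT", int(rng.integers(10, 31)))
    scaffold_nt = upstream_nt + cds_nt + downstream_nt

    cds_start = len(upstream_nt) + 1
    cds_end = len(upstream_nt) + len(cds_nt)
    annotated_start = cds_start + 3 * (t - 1)
    annotated = ((annotated_start, cds_end),)
    extended = ((cds_start, cds_end),) if truncate else annotated
    strand = "+"
    scaffold_id = f"scaf_{locus_id}"
    if rng.random() < 0.5:
        strand = "-"
        L = len(scaffold_nt)
        scaffold_nt = reverse_complement(scaffold_nt)
        annotated = tuple((L - e + 1, L - s + 1) for s, e in annotated)
        extended = tuple((L - e + 1, L - s + 1) for s, e in extended)

    scaffold = SequenceRecord(
        id=scaffold_id, description="synthetic scaffold",
        residues=scaffold_nt, kind="nucleotide",
    )
    model = GeneModel(
        locus_id=locus_id, scaffold_id=scaffold_id, strand=strand,
        cds_segments=annotated, phase=0,
    )
    truth = LocusTruth(
        locus_id=locus_id,
        compartments=compartments,
        mechanism=mechanism,
        variant_labels=labels,
        domain_start=domain_start,
        expected_status=expected_status,
        expected_codons_added=codons_added,
        expected_extended_segments=extended,
    )
    protein = SequenceRecord(
        id=locus_id, description="synthetic full-length product",
        residues=protein_str, kind="protein",
    )
    return SimulatedLocus(
        scaffold=scaffold, model=model, protein=protein,
        anchor=lp.anchor, truth=truth,
    )


def simulate_loci(
    profile: OrganismProfile,
    n: int,
    params: SynthParams = DEFAULT_PARAMS,
    rng: np.random.Generator | None = None,
) -> list[SimulatedLocus]:
    """Draw n loci with class frequencies set by the generator parameters."""
    rng = np.random.default_rng() if rng is None else rng
    singles: list[frozenset[str]] = [
        frozenset({"cytosol"}),
        frozenset({"mitochondrion"}),
        frozenset({"plastid"}),
    ]
    if profile.has_ppc:
        singles.append(frozenset({"ppc"}))
    loci = []
    for i in range(n):
        locus_id = f"L{i + 1:05d}"
        if rng.random() < params.locus.dual_fraction:
            mechanism = (
                "ambiguous_peptide"
                if rng.random() < params.locus.ambiguous_mechanism_prob
                else "alternate_start"
            )
            compartments = frozenset({"plastid", "mitochondrion"})
        else:
            mechanism = "none"
            compartments = singles[int(rng.integers(0, len(singles)))]
        loci.append(
            make_locus(compartments, mechanism, params, rng, locus_id, profile)
        )
    return loci


@dataclass(frozen=True)
class InventoryTruth:
    expected_assignments: dict[str, frozenset[str]]  # gene -> served compartments
    expected_gaps: tuple[tuple[str, str], ...]       # (aars_type, compartment)


def make_inventory(
    profile: OrganismProfile,
    params: SynthParams = DEFAULT_PARAMS,
    rng: np.random.Generator | None = None,
) -> tuple[list[InventoryRow], InventoryTruth]:
    """Plant a coverable inventory: per type, one locus per required
    compartment, except that a ``dual_fraction`` of types replace their
    plastid and mitochondrion singles with one dual locus. ``planted_gaps``
    omit the corresponding supply for negative tests."""
    rng = np.random.default_rng() if rng is None else rng
    req = required_set(profile)
    gaps = set(params.inventory.planted_gaps)
    rows: list[InventoryRow] = []
    assignments: dict[str, frozenset[str]] = {}
    expected_gaps: list[tuple[str, str]] = []
    for aars_type in sorted({t for v in req.required.values() for t in v}):
        required_comps = [c for c in profile.compartments
                          if aars_type in req.required[c]]
        targets: list[frozenset[str]] = []
        can_dual = "plastid" in required_comps and "mitochondrion" in required_comps
        if can_dual and rng.random() < params.inventory.dual_fraction:
            targets.append(frozenset({"plastid", "mitochondrion"}))
            targets.extend(
                frozenset({c}) for c in required_comps
                if c not in ("plastid", "mitochondrion")
            )
        else:
            targets.extend(frozenset({c}) for c in required_comps)
        index = 0
        for caps in targets:
            if any((aars_type, c) in gaps for c in caps):
                expected_gaps.extend((aars_type, c) for c in sorted(caps))
                continue
            index += 1
            gene = f"{aars_type}{index}"
            rows.append(
                InventoryRow(
                    organism=profile.name, aars_type=aars_type, gene_name=gene,
                    encoding_genome="nucleus", subunit_kind="standard",
                    alternatives=(caps,),
                )
            )
            assignments[gene] = caps
    return rows, InventoryTruth(
        expected_assignments=assignments,
        expected_gaps=tuple(sorted(expected_gaps)),
    )
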