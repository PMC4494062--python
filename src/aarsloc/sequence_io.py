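"""Readers, writers, and domain types shared by the whole pipeline.

Coordinates are 1-based inclusive genomic intervals (GFF3 convention);
protein residue indices are 1-based. Minus-strand CDS segments are stored
in genomic coordinates and iterated in translation order (descending
genomic coordinate); reverse-complementation happens only inside
:func:`conceptual_translate`.
"""

from __future__ import annotations

import json
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")

COMPARTMENTS = ("cytosol", "mitochondrion", "plastid", "ppc")
#: accepted spellings for compartment tokens (case-insensitive)
_COMPARTMENT_TOKENS = {
    "cytosol": "cytosol",
    "mito": "mitochondrion",
    "mitochondrion": "mitochondrion",
    "plastid": "plastid",
    "ppc": "ppc",
}

AMINO_ACIDS = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)
AARS_TYPES = tuple(aa + "RS" for aa in AMINO_ACIDS)
GAT_SUBUNITS = ("gatA", "gatB")
SUBUNIT_KINDS = ("standard", "monomer", "alpha", "beta")
ENCODING_GENOMES = ("nucleus", "plastid", "mitochondrion", "nucleomorph")

#: which translating compartment each organelle genome serves
ORGANELLE_TO_COMPARTMENT = {
    "mitochondrion": "mitochondrion",
    "plastid": "plastid",
    "nucleomorph": "ppc",
}

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_CODON_TABLE.forward_table)
STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)  # TAA, TAG, TGA
START_CODON = "ATG"


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


class InventoryParseError(ValueError):
    """A malformed inventory TSV row; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class GeneModelError(ValueError):
    """An inconsistent gene model (mixed strands, overlapping segments...)."""


class TranslationError(ValueError):
    """Conceptual translation failed; carries the 1-based codon offset."""

    def __init__(self, message: str, codon_offset: int):
        super().__init__(message)
        self.codon_offset = codon_offset


class ProfileError(ValueError):
    """An organism profile violating its structural invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    residues: str
    kind: str  # "protein" | "nucleotide"

    def __post_init__(self):
        if not self.residues:
            raise AlphabetError(f"{self.id}: empty sequence")
        if self.kind == "protein":
            alphabet = PROTEIN_ALPHABET
        elif self.kind == "nucleotide":
            alphabet = NUCLEOTIDE_ALPHABET
        else:
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        bad = set(self.residues) - alphabet
        if bad:
            raise AlphabetError(
                f"{self.id}: characters {sorted(bad)} outside the {self.kind} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """CDS structure of one locus, subject to 5' extension.

    ``cds_segments`` are (start, end) 1-based inclusive genomic intervals in
    translation order: ascending for '+' loci, descending for '-'.
    """

    locus_id: str
    scaffold_id: str
    strand: str  # "+" | "-"
    cds_segments: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise GeneModelError(f"{self.locus_id}: strand must be '+' or '-'")
        if self.phase not in (0, 1, 2):
            raise GeneModelError(f"{self.locus_id}: phase must be 0, 1 or 2")
        if not self.cds_segments:
            raise GeneModelError(f"{self.locus_id}: no CDS segments")
        for start, end in self.cds_segments:
            if start > end:
                raise GeneModelError(f"{self.locus_id}: segment {start}-{end} reversed")
        ordered = sorted(self.cds_segments)
        for (_, e1), (s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise GeneModelError(f"{self.locus_id}: overlapping CDS segments")
        genomic_order = [s for s, _ in self.cds_segments]
        expect = sorted(genomic_order, reverse=self.strand == "-")
        if genomic_order != expect:
            raise GeneModelError(
                f"{self.locus_id}: segments not in translation order for strand {self.strand}"
            )

    @property
    def first_codon_start(self) -> tuple[int, int]:
        """Genomic interval (start, end) of the first (phase-adjusted) codon."""
        s, e = self.cds_segments[0]
        if self.strand == "+":
            return (s + self.phase, s + self.phase + 2)
        return (e - self.phase - 2, e - self.phase)


@dataclass(frozen=True)
class InventoryRow:
    """One gene of the aaRS inventory (one row of the packaged published-prediction fixture).

    ``alternatives`` holds the parsed localization prediction: a tuple of
    alternative compartment capability sets (usually one), or ``None`` when the
    prediction is unknown (incomplete gene model).
    """

    organism: str
    aars_type: str
    gene_name: str
    encoding_genome: str
    subunit_kind: str
    alternatives: tuple[frozenset[str], ...] | None

    @property
    def is_gat(self) -> bool:
        return self.aars_type in GAT_SUBUNITS


@dataclass(frozen=True)
class OrganismProfile:
    """Which compartments translate, and the bookkeeping exceptions.

    ``organelle_trna_presence`` maps an organelle genome to a per-amino-acid
    presence flag; a missing tRNA licenses the charged-tRNA-import hypothesis
    for the served compartment. ``transamidation`` lists compartments where
    both amidotransferase subunits are present, removing the glnRS requirement.
    """

    name: str
    compartments: tuple[str, ...]
    organelle_trna_presence: dict[str, dict[str, bool]] = field(default_factory=dict)
    organelle_encoded_aars: tuple[tuple[str, str, str], ...] = ()
    transamidation: tuple[tuple[str, frozenset[str]], ...] = ()
    remove_asnrs_on_transamidation: bool = False

    def __post_init__(self):
        if "cytosol" not in self.compartments:
            raise ProfileError(f"{self.name}: cytosol must be a compartment")
        for c in self.compartments:
            if c not in COMPARTMENTS:
                raise ProfileError(f"{self.name}: unknown compartment {c!r}")
        for organelle in self.organelle_trna_presence:
            comp = ORGANELLE_TO_COMPARTMENT.get(organelle)
            if comp is None:
                raise ProfileError(f"{self.name}: unknown organelle {organelle!r}")
            if comp not in self.compartments:
                raise ProfileError(
                    f"{self.name}: organelle {organelle!r} serves {comp!r}, "
                    "which is not a translating compartment of this profile"
                )

    @property
    def has_ppc(self) -> bool:
        return "ppc" in self.compartments


def parse_compartment(token: str) -> str:
    norm = _COMPARTMENT_TOKENS.get(token.strip().lower())
    if norm is None:
        raise ValueError(f"unknown compartment label {token!r}")
    return norm


def parse_localization(text: str) -> tuple[frozenset[str], ...] | None:
    """Parse a predicted-localization cell into alternative capability sets.

    '/' joins compartments of one dual capability set, 'or' separates
    alternative sets; '?'-prefixed or 'unknown' cells parse to ``None``.
    """
    text = text.strip()
    if not text or text.startswith("?") or text.lower() == "unknown":
        return None
    alternatives = []
    for alt in text.replace(" OR ", " or ").split(" or "):
        comps = frozenset(parse_compartment(tok) for tok in alt.split("/"))
        alternatives.append(comps)
    return tuple(alternatives)


def format_localization(alternatives: tuple[frozenset[str], ...] | None) -> str:
    if alternatives is None:
        return "unknown"
    order = {c: i for i, c in enumerate(COMPARTMENTS)}
    return " or ".join(
        "/".join(sorted(alt, key=order.__getitem__)) for alt in alternatives
    )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, kind: str = "protein") -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description[len(rec.id):].strip(),
                residues=str(rec.seq).upper(),
                kind=kind,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")  # wraps at 60 columns


# ---------------------------------------------------------------------------
# Inventory TSV

_INVENTORY_COLUMNS = (
    "organism", "aars_type", "gene_name", "encoding_genome",
    "subunit_kind", "predicted_localization",
)


def read_inventory(path: str | Path) -> list[InventoryRow]:
    rows: list[InventoryRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _INVENTORY_COLUMNS:
            raise InventoryParseError(
                f"expected header {list(_INVENTORY_COLUMNS)}, got {header}", line=1
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_INVENTORY_COLUMNS):
                raise InventoryParseError(
                    f"expected {len(_INVENTORY_COLUMNS)} fields, got {len(fields)}",
                    line=lineno,
                )
            organism, aars_type, gene_name, genome, kind, loc = fields
            if aars_type not in AARS_TYPES and aars_type not in GAT_SUBUNITS:
                raise InventoryParseError(
                    f"unknown aars_type {aars_type!r}", line=lineno
                )
            if genome not in ENCODING_GENOMES:
                raise InventoryParseError(
                    f"unknown encoding genome {genome!r}", line=lineno
                )
            if kind not in SUBUNIT_KINDS:
                raise InventoryParseError(
                    f"unknown subunit kind {kind!r}", line=lineno
                )
            try:
                alternatives = parse_localization(loc)
            except ValueError as exc:
                raise InventoryParseError(str(exc), line=lineno) from exc
            rows.append(
                InventoryRow(
                    organism=organism,
                    aars_type=aars_type,
                    gene_name=gene_name,
                    encoding_genome=genome,
                    subunit_kind=kind,
                    alternatives=alternatives,
                )
            )
    return rows


def write_inventory(rows: Iterable[InventoryRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_INVENTORY_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    (
                        r.organism, r.aars_type, r.gene_name, r.encoding_genome,
                        r.subunit_kind, format_localization(r.alternatives),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GFF3 or JSON dialect)

def read_gene_models(path: str | Path) -> list[GeneModel]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_gene_models_json(path)
    return _read_gene_models_gff3(path)


def _read_gene_models_json(path: Path) -> list[GeneModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    models = []
    for entry in payload:
        models.append(
            GeneModel(
                locus_id=entry["locus_id"],
                scaffold_id=entry["scaffold_id"],
                strand=entry["strand"],
                cds_segments=tuple((int(s), int(e)) for s, e in entry["cds_segments"]),
                phase=int(entry.get("phase", 0)),
            )
        )
    return models


def _read_gene_models_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path), tmp.name, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        grouped: dict[str, list] = {}
        for feat in db.features_of_type("CDS", order_by="start"):
            parent = feat.attributes.get("Parent", [feat.id])[0]
            grouped.setdefault(parent, []).append(feat)
    models = []
    for locus_id, feats in grouped.items():
        strands = {f.strand for f in feats}
        if len(strands) != 1 or strands <= {".", "?"}:
            raise GeneModelError(f"{locus_id}: CDS segments on mixed/unknown strands")
        strand = strands.pop()
        feats.sort(key=lambda f: f.start, reverse=strand == "-")
        first = feats[0]
        if first.frame in (".", None):
            logger.warning("%s: missing CDS phase, assuming 0", locus_id)
            phase = 0
        else:
            phase = int(first.frame)
        models.append(
            GeneModel(
                locus_id=locus_id,
                scaffold_id=first.seqid,
                strand=strand,
                cds_segments=tuple((f.start, f.end) for f in feats),
                phase=phase,
            )
        )
    models.sort(key=lambda m: m.locus_id)
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "locus_id": m.locus_id,
                "scaffold_id": m.scaffold_id,
                "strand": m.strand,
                "cds_segments": [[s, e] for s, e in m.cds_segments],
                "phase": m.phase,
            }
            for m in models
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
        return
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            for i, (start, end) in enumerate(m.cds_segments):
                phase = m.phase if i == 0 else _downstream_phase(m, i)
                fh.write(
                    "\t".join(
                        (
                            m.scaffold_id, "aarsloc", "CDS", str(start), str(end),
                            ".", m.strand, str(phase),
                            f"ID=cds-{m.locus_id}-{i};Parent={m.locus_id}",
                        )
                    )
                    + "\n"
                )


def _downstream_phase(model: GeneModel, index: int) -> int:
    consumed = -model.phase
    for start, end in model.cds_segments[:index]:
        consumed += end - start + 1
    return (3 - consumed % 3) % 3


# ---------------------------------------------------------------------------
# Conceptual translation

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def coding_sequence(model: GeneModel, scaffold: SequenceRecord) -> str:
    """Concatenated CDS nucleotides in translation order, phase-trimmed."""
    if scaffold.kind != "nucleotide":
        raise ValueError("scaffold must be a nucleotide record")
    parts = []
    for start, end in model.cds_segments:
        if start < 1 or end > len(scaffold):
            raise GeneModelError(
                f"{model.locus_id}: segment {start}-{end} outside scaffold "
                f"{scaffold.id} (length {len(scaffold)})"
            )
        chunk = scaffold.residues[start - 1:end]
        if model.strand == "-":
            chunk = reverse_complement(chunk)
        parts.append(chunk)
    return "".join(parts)[model.phase:]


def conceptual_translate(model: GeneModel, scaffold: SequenceRecord) -> SequenceRecord:
    """Translate a gene model with the standard genetic code.

    Translation terminates at and excludes a final stop codon; an internal
    stop raises :class:`TranslationError` carrying the 1-based codon offset.
    Codons containing N translate to 'X'.
    """
    cds = coding_sequence(model, scaffold)
    if len(cds) % 3 != 0:
        raise TranslationError(
            f"{model.locus_id}: CDS length {len(cds)} not divisible by 3",
            codon_offset=len(cds) // 3 + 1,
        )
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise TranslationError(
                f"{model.locus_id}: internal stop codon {codon} at codon {i + 1}",
                codon_offset=i + 1,
            )
        if "N" in codon:
            residues.append("X")
        else:
            residues.append(CODON_TO_AA[codon])
    return SequenceRecord(
        id=model.locus_id,
        description="conceptual translation",
        residues="".join(residues),
        kind="protein",
    )


# ---------------------------------------------------------------------------
# Organism profiles

def read_profile(path: str | Path) -> OrganismProfile:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return profile_from_dict(payload)


def profile_from_dict(payload: dict) -> OrganismProfile:
    trna: dict[str, dict[str, bool]] = {}
    for organelle, spec in (payload.get("organelle_trna_presence") or {}).items():
        missing = set(spec.get("missing", []) if isinstance(spec, dict) else spec)
        bad = missing - set(AMINO_ACIDS)
        if bad:
            raise ProfileError(f"unknown amino acids in tRNA table: {sorted(bad)}")
        trna[organelle] = {aa: aa not in missing for aa in AMINO_ACIDS}
    encoded = tuple(
        (e["aars_type"], e.get("subunit_kind", "standard"), e["organelle"])
        for e in payload.get("organelle_encoded_aars") or []
    )
    transam = tuple(
        (e["compartment"], frozenset(e.get("subunits", [])))
        for e in payload.get("transamidation") or []
    )
    return OrganismProfile(
        name=payload["name"],
        compartments=tuple(parse_compartment(c) for c in payload["compartments"]),
        organelle_trna_presence=trna,
        organelle_encoded_aars=encoded,
        transamidation=transam,
        remove_asnrs_on_transamidation=bool(
            payload.get("remove_asnrs_on_transamidation", False)
        ),
    )


def packaged_path(name: str) -> Path:
    """Path of a data file shipped with the package (fixture or profile)."""
    return Path(__file__).parent / "data" / name


def load_packaged_inventory() -> list[InventoryRow]:
    return read_inventory(packaged_path("published_inventory.tsv"))


_PROFILE_FILES = {
    "Guillardia theta": "guillardia_theta.yaml",
    "Phaeodactylum tricornutum": "phaeodactylum_tricornutum.yaml",
    "Thalassiosira pseudonana": "thalassiosira_pseudonana.yaml",
}


def load_packaged_profile(organism: str) -> OrganismProfile:
    try:
        fname = _PROFILE_FILES[organism]
    except KeyError:
        raise KeyError(
            f"no packaged profile for {organism!r}; have {sorted(_PROFILE_FILES)}"
        ) from None
    return read_profile(packaged_path(fname))
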