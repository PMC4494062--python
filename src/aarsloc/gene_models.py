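"""5' gene-model curation: upstream in-frame ATG extension and alternate
N-terminus enumeration.

Gene finders systematically truncate ORFs whose products carry N-terminal
targeting extensions (the extensions are unconserved), so each annotated
start is pushed to the farthest upstream in-frame ATG reachable without
crossing a stop codon. All methionines upstream of the conserved synthetase
domain then define the candidate translation-initiation isoforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

from .sequence_io import (
    START_CODON,
    STOP_CODONS,
    GeneModel,
    GeneModelError,
    SequenceRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

STATUS_EXTENDED = "extended"
STATUS_STOP_ADJACENT = "unchanged_stop_adjacent"
STATUS_NO_UPSTREAM_ATG = "unchanged_no_upstream_atg"
STATUS_SCAFFOLD_EDGE = "unchanged_scaffold_edge"


@dataclass(frozen=True)
class ExtensionResult:
    original: GeneModel
    extended: GeneModel
    codons_added: int
    status: str

    def __post_init__(self):
        if (self.codons_added == 0) != (self.status != STATUS_EXTENDED):
            raise ValueError("codons_added must be 0 iff status is not 'extended'")


@dataclass(frozen=True)
class NTermVariant:
    """A candidate protein isoform starting at one methionine."""

    locus_id: str
    start_residue_index: int  # 1-based within the full-length protein
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


class DomainHit(NamedTuple):
    index: int  # 1-based residue index of the best anchor occurrence
    identity: float  # fraction of matching positions


class DomainNotFoundError(ValueError):
    pass


def _upstream_codon(model: GeneModel, scaffold: SequenceRecord, k: int) -> str | None:
    """The k-th in-frame codon upstream of the annotated first codon.

    Walks on the model's strand (toward lower genomic coordinates for '+',
    higher for '-'); returns None when fewer than 3 nt remain on the scaffold.
    """
    first_start, first_end = model.first_codon_start
    if model.strand == "+":
        start = first_start - 3 * k
        if start < 1:
            return None
        return scaffold.residues[start - 1:start + 2]
    end = first_end + 3 * k
    if end > len(scaffold):
        return None
    return reverse_complement(scaffold.residues[end - 3:end])


def _shift_first_codon(model: GeneModel, k: int) -> GeneModel:
    """Move the annotated start k codons upstream; the result is phase 0."""
    segments = list(model.cds_segments)
    start, end = segments[0]
    if model.strand == "+":
        segments[0] = (start + model.phase - 3 * k, end)
    else:
        segments[0] = (start, end - model.phase + 3 * k)
    return replace(model, cds_segments=tuple(segments), phase=0)


def extend_orf_upstream(model: GeneModel, scaffold: SequenceRecord) -> ExtensionResult:
    """Extend an annotated ORF to the farthest upstream in-frame ATG.

    The walk proceeds codon by codon in the reading frame of the first CDS
    segment, on the model's strand, and stops at the first in-frame stop codon
    or at the scaffold edge (partial codons are never read). The farthest ATG
    seen before stopping becomes the new start; intermediate ATGs are left to
    :func:`enumerate_n_termini`. Annotated introns are never crossed: only
    genomic sequence upstream of the first segment is inspected.
    """
    first_start, first_end = model.first_codon_start
    if first_start < 1 or first_end > len(scaffold):
        raise GeneModelError(
            f"{model.locus_id}: annotated first codon {first_start}-{first_end} "
            f"outside scaffold {scaffold.id}"
        )
    farthest: int | None = None
    k = 1
    first_codon = _upstream_codon(model, scaffold, 1)
    while True:
        codon = _upstream_codon(model, scaffold, k)
        if codon is None or codon in STOP_CODONS:
            break
        if codon == START_CODON:
            farthest = k
        k += 1
    if farthest is not None:
        return ExtensionResult(
            original=model,
            extended=_shift_first_codon(model, farthest),
            codons_added=farthest,
            status=STATUS_EXTENDED,
        )
    if first_codon is None:
        status = STATUS_SCAFFOLD_EDGE
    elif first_codon in STOP_CODONS:
        status = STATUS_STOP_ADJACENT
    else:
        status = STATUS_NO_UPSTREAM_ATG
    return ExtensionResult(original=model, extended=model, codons_added=0, status=status)


def enumerate_n_termini(
    protein: SequenceRecord, domain_start: int
) -> list[NTermVariant]:
    """One variant per methionine strictly upstream of the conserved domain.

    Variants are returned in ascending start order; each sequence is the
    protein suffix from its initiating methionine. A protein without any M
    before ``domain_start`` yields an empty list (the locus is unusable for
    N-terminal analysis) with a logged warning.
    """
    if not 1 <= domain_start <= len(protein):
        raise ValueError(
            f"domain_start {domain_start} outside protein of length {len(protein)}"
        )
    variants = [
        NTermVariant(
            locus_id=protein.id,
            start_residue_index=i + 1,
            sequence=protein.residues[i:],
        )
        for i in range(domain_start - 1)
        if protein.residues[i] == "M"
    ]
    if not variants:
        logger.warning(
            "%s: no methionine before domain start %d; locus unusable for "
            "N-terminal analysis", protein.id, domain_start,
        )
    return variants


def locate_domain_start(
    protein: SequenceRecord, anchor: str, min_identity: float = 0.5
) -> DomainHit:
    """Best ungapped occurrence of a conserved-domain anchor motif.

    Scans every window of ``len(anchor)`` residues, scoring by identity count;
    ties break toward the smallest index. Raises :class:`DomainNotFoundError`
    when no window reaches ``min_identity``.
    """
    if len(anchor) < 6:
        raise ValueError("anchor motif must be at least 6 residues")
    n = len(anchor)
    if n > len(protein):
        raise DomainNotFoundError(
            f"{protein.id}: anchor longer than protein; domain not found"
        )
    best_index, best_score = -1, -1
    seq = protein.residues
    for start in range(len(seq) - n + 1):
        score = sum(a == b for a, b in zip(seq[start:start + n], anchor))
        if score > best_score:
            best_index, best_score = start, score
    identity = best_score / n
    if identity < min_identity:
        raise DomainNotFoundError(
            f"{protein.id}: best anchor identity {identity:.2f} below "
            f"{min_identity:.2f}; domain not found"
        )
    return DomainHit(index=best_index + 1, identity=identity)
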