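"""Collapse per-variant targeting predictions into one locus-level call.

The decision cascade mirrors the published inference logic: a full-length
signal peptide sets the base destination (plastid or PPC by the +1 rule);
mitochondrial capability is added either because the same peptide also scores
as a presequence (ambiguous peptide) or because a downstream-methionine
isoform does (alternate translation start). Under PPC-bearing profiles an
unsignalled downstream isoform additionally licenses a low-confidence
cytosolic capability, since such an isoform needs no N-terminal extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .predictors import PredictorParams, VariantPrediction
from .sequence_io import COMPARTMENTS, OrganismProfile

MECHANISM_NONE = "none"
MECHANISM_AMBIGUOUS = "ambiguous_peptide"
MECHANISM_ALTERNATE = "alternate_start"
MECHANISM_BOTH = "both"


@dataclass(frozen=True)
class LocalizationCall:
    """Locus-level compartment capability set and dual-targeting mechanism.

    ``capabilities`` is the primary capability set; when the evidence cannot
    distinguish alternatives (e.g. plastid-or-PPC with an uncertain cleavage
    site), ``alternatives`` carries every candidate set and ``capabilities``
    equals the first.
    """

    locus_id: str
    capabilities: frozenset[str]
    alternatives: tuple[frozenset[str], ...]
    mechanism: str
    confidence: str  # high | low
    evidence: tuple[str, ...]

    @property
    def is_ambiguous(self) -> bool:
        return len(self.alternatives) > 1


@dataclass(frozen=True)
class CallResult:
    locus_id: str
    call: LocalizationCall | None
    status: str  # ok | failed
    error: str = ""


def _fmt_compartments(comps: frozenset[str]) -> str:
    order = {c: i for i, c in enumerate(COMPARTMENTS)}
    return "/".join(sorted(comps, key=order.__getitem__)) if comps else "-"


def call_locus(
    predictions: Sequence[VariantPrediction],
    profile: OrganismProfile,
    params: PredictorParams = PredictorParams(),
) -> LocalizationCall:
    """Decide one locus from its variant predictions (full-length first)."""
    if not predictions:
        raise ValueError("empty prediction list")
    full = predictions[0]
    downstream = predictions[1:]
    locus_id = full.variant.locus_id
    evidence: list[str] = []
    for p in predictions:
        bits = [
            f"M{p.variant.start_residue_index}",
            f"signal={p.signal.score:.4f}{'+' if p.signal.has_signal else '-'}",
            f"mito={p.mito.score:.4f}{'+' if p.mito.has_presequence else '-'}",
        ]
        if p.tpl is not None:
            bits.append(f"tpl={p.tpl.category}(+1={p.tpl.plus_one_residue or '?'})")
        evidence.append(" ".join(bits))

    high = params.high_confidence

    if full.signal.has_signal:
        tpl = full.tpl
        low_confidence = full.signal.score < high
        if tpl.category == "plastid":
            base_options = [frozenset({"plastid"})]
        elif tpl.category == "ppc":
            base_options = [frozenset({"ppc"})]
        elif tpl.low_confidence_plastid:
            # diatom-style profile: signal-bearing proteins are treated as
            # plastid-targeted even without an aromatic/leucine +1
            base_options = [frozenset({"plastid"})]
            low_confidence = True
            evidence.append("non-aromatic +1: low-confidence plastid")
        elif profile.has_ppc:
            # signal present but cleavage context unresolved: carry both routes
            base_options = [frozenset({"plastid"}), frozenset({"ppc"})]
            low_confidence = True
            evidence.append("TPL undetermined: plastid-or-ppc alternatives")
        else:
            base_options = [frozenset({"plastid"})]
            low_confidence = True

        mech_ambiguous = full.mito.has_presequence
        mito_down = [p for p in downstream if p.mito.has_presequence]
        mech_alternate = bool(mito_down)
        add_mito = mech_ambiguous or mech_alternate
        if mech_ambiguous and mech_alternate:
            mechanism = MECHANISM_BOTH
        elif mech_ambiguous:
            mechanism = MECHANISM_AMBIGUOUS
        elif mech_alternate:
            mechanism = MECHANISM_ALTERNATE
        else:
            mechanism = MECHANISM_NONE
        if add_mito:
            base_options = [opt | {"mitochondrion"} for opt in base_options]
            scores = [full.mito.score] if mech_ambiguous else []
            scores += [p.mito.score for p in mito_down]
            if max(scores) < high:
                low_confidence = True

        options = list(base_options)
        unsignalled_down = [
            p for p in downstream
            if not p.signal.has_signal and not p.mito.has_presequence
        ]
        if profile.has_ppc and unsignalled_down:
            # an isoform without any N-terminal extension could stay cytosolic
            options = options + [opt | {"cytosol"} for opt in base_options]
            low_confidence = True
            evidence.append(
                "unsignalled downstream isoform: cytosol possible (low confidence)"
            )
        return LocalizationCall(
            locus_id=locus_id,
            capabilities=options[0],
            alternatives=tuple(options) if len(options) > 1 else (options[0],),
            mechanism=mechanism,
            confidence="low" if low_confidence else "high",
            evidence=tuple(evidence),
        )

    if full.mito.has_presequence:
        return LocalizationCall(
            locus_id=locus_id,
            capabilities=frozenset({"mitochondrion"}),
            alternatives=(frozenset({"mitochondrion"}),),
            mechanism=MECHANISM_NONE,
            confidence="high" if full.mito.score >= high else "low",
            evidence=tuple(evidence),
        )

    confidence = "high"
    for p in downstream:
        if p.signal.has_signal or p.mito.has_presequence:
            # downstream-only positives are noted but, absent any full-length
            # targeting information, the locus is still called cytosolic
            evidence.append(
                f"downstream-only positive at M{p.variant.start_residue_index}"
            )
            confidence = "low"
    return LocalizationCall(
        locus_id=locus_id,
        capabilities=frozenset({"cytosol"}),
        alternatives=(frozenset({"cytosol"}),),
        mechanism=MECHANISM_NONE,
        confidence=confidence,
        evidence=tuple(evidence),
    )


def call_all(
    loci_predictions: Sequence[tuple[str, Sequence[VariantPrediction]]],
    profile: OrganismProfile,
    params: PredictorParams = PredictorParams(),
) -> list[CallResult]:
    """Order-preserving map of :func:`call_locus`; per-locus failures are
    isolated into a status column instead of aborting the batch."""
    results = []
    for locus_id, predictions in loci_predictions:
        try:
            call = call_locus(predictions, profile, params)
            results.append(CallResult(locus_id=locus_id, call=call, status="ok"))
        except ValueError as exc:
            results.append(
                CallResult(locus_id=locus_id, call=None, status="failed", error=str(exc))
            )
    return results


def calls_to_rows(results: Sequence[CallResult]) -> list[dict]:
    """Flatten call results for TSV output (stable column order and text)."""
    rows = []
    for res in results:
        if res.call is None:
            rows.append(
                {
                    "locus_id": res.locus_id, "status": res.status,
                    "capabilities": "-", "alternatives": "-", "mechanism": "-",
                    "confidence": "-", "evidence": res.error,
                }
            )
            continue
        call = res.call
        rows.append(
            {
                "locus_id": res.locus_id,
                "status": res.status,
                "capabilities": _fmt_compartments(call.capabilities),
                "alternatives": " or ".join(
                    _fmt_compartments(a) for a in call.alternatives
                ),
                "mechanism": call.mechanism,
                "confidence": call.confidence,
                "evidence": "; ".join(call.evidence),
            }
        )
    return rows
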