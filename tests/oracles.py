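"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives its quantity from first principles with deliberately
naive code (explicit loops, no shared helpers with the package), so that an
agreement test is a genuine dual-route check.
"""

from __future__ import annotations

import itertools
import math

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}

_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}
_EIS = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08, "X": 0.0,
}


def upstream_codons_oracle(scaffold: str, strand: str, first_start: int,
                           first_end: int) -> list[str]:
    """All in-frame codons upstream of the annotated first codon, nearest
    first, stopping at the scaffold edge."""
    codons = []
    if strand == "+":
        pos = first_start - 3
        while pos >= 1:
            codons.append(scaffold[pos - 1:pos + 2])
            pos -= 3
    else:
        pos = first_end + 3
        while pos <= len(scaffold):
            raw = scaffold[pos - 3:pos]
            codons.append("".join(_COMPLEMENT[b] for b in reversed(raw)))
            pos += 3
    return codons


def extension_oracle(scaffold: str, strand: str, first_start: int,
                     first_end: int) -> tuple[str, int]:
    """(status, codons_added) by exhaustive scan of every upstream in-frame
    position."""
    codons = upstream_codons_oracle(scaffold, strand, first_start, first_end)
    farthest = 0
    for k, codon in enumerate(codons, start=1):
        if codon in _STOPS:
            break
        if codon == "ATG":
            farthest = k
    if farthest:
        return ("extended", farthest)
    if not codons:
        return ("unchanged_scaffold_edge", 0)
    if codons[0] in _STOPS:
        return ("unchanged_stop_adjacent", 0)
    return ("unchanged_no_upstream_atg", 0)


def hydrophobic_moment_oracle(window: str, delta_deg: float = 100.0) -> float:
    """Two-pass explicit vector sum, pure python."""
    s = 0.0
    for k, residue in enumerate(window):
        s_k = _EIS[residue] * math.sin(math.radians(delta_deg) * k)
        s += s_k
    c = 0.0
    for k, residue in enumerate(window):
        c += _EIS[residue] * math.cos(math.radians(delta_deg) * k)
    return math.sqrt(s * s + c * c) / len(window)


def cleavage_oracle(seq: str, lo: int = 15, hi: int = 40, small: str = "AGSCTV",
                    window: int = 8, gap: int = 3) -> int | None:
    """Exhaustive scan over the admissible cleavage window."""
    best, best_score = None, None
    for i in range(lo, min(hi, len(seq)) + 1):
        if seq[i - 1] not in small or seq[i - 3] not in small:
            continue
        end = i - gap
        start = end - window + 1
        if start < 1:
            continue
        score = sum(_KD[r] for r in seq[start - 1:end]) / window
        if best_score is None or score > best_score:
            best, best_score = i, score
    return best


def assignment_oracle(suppliers: list[tuple[str, tuple[frozenset, ...]]],
                      required: frozenset) -> tuple[int, int, int]:
    """Optimal (gaps, multi-locus count, total assignments) by plain
    itertools.product over every per-supplier (alternative, served-subset)
    combination."""
    per_unit = []
    for _, alternatives in suppliers:
        options = []
        for alt in alternatives:
            usable = sorted(alt & required)
            for size in range(len(usable) + 1):
                for combo in itertools.combinations(usable, size):
                    options.append(frozenset(combo))
        per_unit.append(options or [frozenset()])
    best = (len(required), 0, 0)
    for combo in itertools.product(*per_unit):
        covered = frozenset().union(*combo) if combo else frozenset()
        cost = (
            len(required - covered),
            sum(len(s) > 1 for s in combo),
            sum(len(s) for s in combo),
        )
        if cost < best:
            best = cost
    return best
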