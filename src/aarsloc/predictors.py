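"""Transparent rule-based scorers for N-terminal targeting peptides.

Three signal classes are scored from their stated physicochemical
characteristics rather than by opaque trained models:

* secretory signal peptide — positively charged n-region, hydrophobic
  h-region (Kyte–Doolittle hydropathy), polar c-region whose cleavage site
  obeys the (-3,-1) small-residue rule;
* mitochondrial presequence — net positive charge plus an amphipathic
  alpha-helix, quantified by the hydrophobic moment muH at 100 deg per
  residue on the Eisenberg consensus scale;
* transit-peptide-like (TPL) discrimination — the residue immediately after
  signal cleavage decides plastid stroma (aromatic or leucine) versus
  periplastid-compartment retention.

All constants live in :class:`PredictorParams`; scores are computed in double
precision and only rounded (4 decimals) in tabular output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .gene_models import NTermVariant
from .sequence_io import OrganismProfile

#: Kyte & Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

#: Eisenberg consensus hydrophobicity scale
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08, "X": 0.0,
}

#: residue charges at physiological pH; histidine is treated as uncharged
CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

SMALL_RESIDUES = frozenset("AGSCTV")  # the (-3,-1) rule pool
AROMATIC_PLUS_LEU = "FWYL"


@dataclass(frozen=True)
class PredictorParams:
    """All tunable constants of the three scorers.

    The logistic weights and thresholds were calibrated once against the
    synthetic peptide generator (see ``analysis/01_calibrate_predictors.py``)
    and frozen; windows and search ranges follow the stated peptide anatomy.
    """

    # signal peptide
    n_region_end: int = 5            # n-region = residues 1..5
    h_window: int = 8                # h-region window length (residues)
    h_search_start: int = 3          # h-region searched within residues 3..20
    h_search_end: int = 20
    cleavage_min: int = 15           # cleavage site searched in residues 15..40
    cleavage_max: int = 40
    cleavage_score_gap: int = 3      # scoring window ends this far upstream
    signal_w0: float = -4.5
    signal_w_charge: float = 0.45
    signal_w_hydropathy: float = 1.6
    signal_threshold: float = 0.5
    min_signal_length: int = 15

    # mitochondrial presequence
    mu_window: int = 18              # one ~5-turn helix
    mu_search_end: int = 40          # helix searched within residues 1..40
    mu_delta_deg: float = 100.0      # alpha-helical twist per residue
    charge_n: int = 20               # net charge over residues 1..20
    acidic_n: int = 40               # acidic count over residues 1..40
    mito_w0: float = -7.0
    mito_w_charge: float = 0.6
    mito_w_mu: float = 8.0
    mito_w_acidic: float = -0.1
    mito_threshold: float = 0.5
    min_mito_length: int = 18

    # TPL discrimination and confidence
    leucine_plus_one: bool = True    # L joins F/W/Y in the plastid pool
    high_confidence: float = 0.8

    @property
    def plastid_plus_one(self) -> frozenset[str]:
        return frozenset(AROMATIC_PLUS_LEU if self.leucine_plus_one else "FWY")


def params_from_yaml(path) -> PredictorParams:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    return PredictorParams(**payload)


@dataclass(frozen=True)
class SignalPrediction:
    score: float
    has_signal: bool
    cleavage_site: int | None        # cleavage between residue i and i+1
    n_region_net_charge: float
    h_region_max_hydropathy: float
    c_region_motif_ok: bool
    reason: str = ""


@dataclass(frozen=True)
class MitoPrediction:
    score: float
    has_presequence: bool
    net_charge_n20: float
    max_hydrophobic_moment: float
    acidic_count_n40: int
    reason: str = ""


@dataclass(frozen=True)
class TplClass:
    category: str                    # plastid | ppc | undetermined
    plus_one_residue: str | None
    low_confidence_plastid: bool = False
    reason: str = ""


@dataclass(frozen=True)
class VariantPrediction:
    variant: NTermVariant
    signal: SignalPrediction
    mito: MitoPrediction
    tpl: TplClass | None             # populated only when signal.has_signal


def net_charge(seq: str) -> float:
    return sum(CHARGE.get(r, 0.0) for r in seq)


def _sigmoid(z: float) -> float:
    z = max(-60.0, min(60.0, z))  # avoid overflow on degenerate configs
    return 1.0 / (1.0 + math.exp(-z))


def max_window_mean_hydropathy(
    seq: str, window: int, lo: int, hi: int
) -> tuple[float, int]:
    """Max mean Kyte-Doolittle hydropathy over windows inside residues lo..hi.

    Returns ``(mean, start_index)`` of the best window (1-based start, ties
    to the smallest index).
    """
    hi = min(hi, len(seq))
    if hi - lo + 1 < window:
        return (-math.inf, 0)
    values = np.array([KYTE_DOOLITTLE[r] for r in seq[lo - 1:hi]])
    means = np.convolve(values, np.ones(window), mode="valid") / window
    best = int(np.argmax(means))
    return (float(means[best]), lo + best)


def hydrophobic_moment(window: str, delta_deg: float = 100.0) -> float:
    """muH of one window: magnitude of the hydrophobicity vector sum per residue.

    muH = (1/N) * sqrt[(sum h_k sin(delta*k))^2 + (sum h_k cos(delta*k))^2]
    with the Eisenberg consensus scale. A single-residue window gives |h|.
    """
    h = np.array([EISENBERG[r] for r in window])
    angles = np.deg2rad(delta_deg) * np.arange(len(window))
    s = float(h @ np.sin(angles))
    c = float(h @ np.cos(angles))
    return math.hypot(s, c) / len(window)


def max_hydrophobic_moment(
    seq: str, window: int, search_end: int, delta_deg: float = 100.0
) -> float:
    """Max muH over all ``window``-residue windows inside residues 1..search_end."""
    end = min(search_end, len(seq))
    if end < window:
        return 0.0
    return max(
        hydrophobic_moment(seq[start:start + window], delta_deg)
        for start in range(end - window + 1)
    )


def signal_score_from_features(
    n_charge: float, h_max: float, params: PredictorParams = PredictorParams()
) -> float:
    """Logistic combination of the signal-peptide features."""
    return _sigmoid(
        params.signal_w0
        + params.signal_w_charge * n_charge
        + params.signal_w_hydropathy * h_max
    )


def mito_score_from_features(
    charge20: float, mu: float, acidic: int,
    params: PredictorParams = PredictorParams(),
) -> float:
    """Logistic combination of the presequence features."""
    return _sigmoid(
        params.mito_w0
        + params.mito_w_charge * charge20
        + params.mito_w_mu * mu
        + params.mito_w_acidic * acidic
    )


def find_cleavage_site(seq: str, params: PredictorParams) -> int | None:
    """Best admissible signal-cleavage position, or None.

    A position i (cleavage between residues i and i+1) is admissible when the
    -1 residue (position i) and the -3 residue (position i-2) are both small
    per the von Heijne rule. Among admissible positions in the configured
    window, the one whose upstream 8-residue context (ending
    ``cleavage_score_gap`` residues before i) is most hydrophobic wins; ties
    break toward the smallest index.
    """
    best_site, best_score = None, -math.inf
    hi = min(params.cleavage_max, len(seq))
    for i in range(params.cleavage_min, hi + 1):
        if seq[i - 1] not in SMALL_RESIDUES or seq[i - 3] not in SMALL_RESIDUES:
            continue
        ctx_end = i - params.cleavage_score_gap          # residue index, 1-based
        ctx_start = ctx_end - params.h_window + 1
        if ctx_start < 1:
            continue
        ctx = seq[ctx_start - 1:ctx_end]
        score = sum(KYTE_DOOLITTLE[r] for r in ctx) / len(ctx)
        if score > best_score:
            best_site, best_score = i, score
    return best_site


def score_signal_peptide(
    variant: NTermVariant, params: PredictorParams = PredictorParams()
) -> SignalPrediction:
    seq = variant.sequence
    if len(seq) < params.min_signal_length:
        return SignalPrediction(
            score=0.0, has_signal=False, cleavage_site=None,
            n_region_net_charge=net_charge(seq[:params.n_region_end]),
            h_region_max_hydropathy=0.0, c_region_motif_ok=False,
            reason="too short",
        )
    n_charge = net_charge(seq[:params.n_region_end])
    h_max, _ = max_window_mean_hydropathy(
        seq, params.h_window, params.h_search_start, params.h_search_end
    )
    site = find_cleavage_site(seq, params)
    score = signal_score_from_features(n_charge, h_max, params)
    return SignalPrediction(
        score=score,
        has_signal=score >= params.signal_threshold and site is not None,
        cleavage_site=site,
        n_region_net_charge=n_charge,
        h_region_max_hydropathy=h_max,
        c_region_motif_ok=site is not None,
    )


def score_mito_presequence(
    variant: NTermVariant, params: PredictorParams = PredictorParams()
) -> MitoPrediction:
    seq = variant.sequence
    charge20 = net_charge(seq[:params.charge_n])
    acidic = sum(seq[i] in "DE" for i in range(min(params.acidic_n, len(seq))))
    if len(seq) < params.min_mito_length:
        return MitoPrediction(
            score=0.0, has_presequence=False, net_charge_n20=charge20,
            max_hydrophobic_moment=0.0, acidic_count_n40=acidic,
            reason="too short",
        )
    mu = max_hydrophobic_moment(
        seq, params.mu_window, params.mu_search_end, params.mu_delta_deg
    )
    score = mito_score_from_features(charge20, mu, acidic, params)
    # presequences are positively charged; a non-positive N-terminus never
    # qualifies regardless of amphipathicity
    has = score >= params.mito_threshold and charge20 > 0
    return MitoPrediction(
        score=score,
        has_presequence=has,
        net_charge_n20=charge20,
        max_hydrophobic_moment=mu,
        acidic_count_n40=acidic,
    )


def classify_tpl(
    variant: NTermVariant,
    signal: SignalPrediction,
    profile: OrganismProfile,
    params: PredictorParams = PredictorParams(),
) -> TplClass:
    """Plastid-vs-PPC discrimination by the +1 rule.

    The residue immediately after the signal cleavage site routes the protein
    across the innermost membrane pair (aromatic or leucine -> plastid stroma)
    or retains it in the PPC. Profiles without a PPC (diatoms) cannot emit
    ``ppc``: a non-aromatic +1 there is flagged as a low-confidence plastid
    candidate instead.
    """
    if not signal.has_signal or signal.cleavage_site is None:
        raise ValueError("classify_tpl requires a positive signal prediction")
    seq = variant.sequence
    if signal.cleavage_site >= len(seq):
        return TplClass(
            category="undetermined", plus_one_residue=None,
            reason="cleavage at final residue",
        )
    plus_one = seq[signal.cleavage_site]
    if plus_one in params.plastid_plus_one:
        return TplClass(category="plastid", plus_one_residue=plus_one)
    if profile.has_ppc:
        return TplClass(category="ppc", plus_one_residue=plus_one)
    return TplClass(
        category="undetermined", plus_one_residue=plus_one,
        low_confidence_plastid=True,
        reason="signal without aromatic/leucine +1 in a PPC-less profile",
    )


def predict_variants(
    variants: Sequence[NTermVariant],
    profile: OrganismProfile,
    params: PredictorParams = PredictorParams(),
) -> list[VariantPrediction]:
    """Score every candidate N-terminus of one locus, in input order."""
    out = []
    for variant in variants:
        signal = score_signal_peptide(variant, params)
        mito = score_mito_presequence(variant, params)
        tpl = (
            classify_tpl(variant, signal, profile, params)
            if signal.has_signal
            else None
        )
        out.append(VariantPrediction(variant=variant, signal=signal, mito=mito, tpl=tpl))
    return out
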