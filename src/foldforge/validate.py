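"""Computational validation and selection of design candidates.

Designed sequences are re-predicted through one or more oracles (4
recycling iterations; binder tasks carry the target template and
initialise recycling with the designed complex), scored for
self-consistency (scRMSD, scTM) and confidence, classified against the
lax (pLDDT > 70, scRMSD < 2 A) and strict (pLDDT > 80, scRMSD < 1 A,
ipAE < 10 A) success tiers with strict inequalities exactly as printed,
and filtered through the likelihood / confidence-product / solubility
cascade used for in vivo candidate selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .codon import codon_optimize  # re-exported: part of this module's surface
from .fitness import mean_interface_pae
from .oracle import OracleRequest, Template
from .structcore import ChainedSequence, Prediction, Structure, kabsch_rmsd, tm_score

__all__ = [
    "BenchmarkRecord", "SuccessCriteria", "CascadeThresholds", "FilterDecision",
    "self_consistency", "classify_success", "combine_success", "select_best",
    "filter_cascade", "codon_optimize",
]


class IncompleteRecordError(ValueError):
    """A record is missing a field the requested tier needs."""


@dataclass
class BenchmarkRecord:
    """Self-consistency metrics for one (design, oracle) pair."""

    design_id: str
    oracle: str
    scrmsd: float
    sctm: float
    mean_plddt: float
    mean_pae: float
    ptm: float
    ipae: float | None = None
    state: str = "default"

    def __post_init__(self) -> None:
        if self.scrmsd < 0:
            raise ValueError("scRMSD must be >= 0")
        if not 0.0 < self.sctm <= 1.0:
            raise ValueError("scTM must lie in (0, 1]")


@dataclass(frozen=True)
class SuccessCriteria:
    """Published success thresholds; all strict inequalities, overridable."""

    lax_plddt: float = 70.0
    lax_scrmsd: float = 2.0
    strict_plddt: float = 80.0
    strict_scrmsd: float = 1.0
    strict_ipae: float = 10.0


def self_consistency(
    raw: Structure,
    sequence: ChainedSequence,
    oracles: Mapping[str, object],
    design_id: str = "design",
    templates: Sequence[tuple[str, Template]] = (),
    designed_chains: Sequence[str] | None = None,
    target_chains: Sequence[str] | None = None,
    recycle_count: int = 4,
    init_with_raw: bool = True,
    state: str = "default",
) -> list[BenchmarkRecord]:
    """Re-predict a designed sequence and measure self-consistency.

    scRMSD/scTM compare the raw (design-time) structure with each
    oracle's re-prediction under the identity residue mapping.  For
    complexes the interface pAE between designed and target chains is
    also recorded.  Oracle failures are recorded per oracle, not fatal.
    """
    if sequence.length != raw.n_residues:
        raise ValueError("sequence does not match raw structure length")
    records: list[BenchmarkRecord] = []
    req = OracleRequest(
        sequence,
        templates=tuple(templates),
        recycle_count=recycle_count,
        init_structure=raw if init_with_raw else None,
    )
    for name, oracle in oracles.items():
        try:
            pred: Prediction = oracle.predict(req)
        except Exception:  # per-oracle failure is data, not a crash
            continue
        ipae = None
        if len(sequence.chains) > 1:
            ids = sequence.chain_ids
            x_ids = tuple(designed_chains) if designed_chains else ids[:1]
            t_ids = tuple(target_chains) if target_chains else tuple(
                c for c in ids if c not in x_ids
            )
            x = np.concatenate([np.arange(*sequence.intervals[ids.index(c)]) for c in x_ids])
            t = np.concatenate([np.arange(*sequence.intervals[ids.index(c)]) for c in t_ids])
            ipae = mean_interface_pae(pred, x, t)
        records.append(
            BenchmarkRecord(
                design_id=design_id,
                oracle=name,
                scrmsd=kabsch_rmsd(raw, pred.structure),
                sctm=tm_score(raw, pred.structure),
                mean_plddt=float(np.mean(pred.plddt)),
                mean_pae=float(np.mean(pred.pae)),
                ptm=pred.ptm,
                ipae=ipae,
                state=state,
            )
        )
    return records


def classify_success(
    rec: BenchmarkRecord, crit: SuccessCriteria = SuccessCriteria()
) -> dict[str, bool]:
    """Lax and strict success flags; boundary values fail (strict <, >)."""
    lax = rec.mean_plddt > crit.lax_plddt and rec.scrmsd < crit.lax_scrmsd
    if rec.ipae is None:
        return {"lax": lax, "strict": False, "strict_evaluable": False}
    strict = (
        rec.mean_plddt > crit.strict_plddt
        and rec.scrmsd < crit.strict_scrmsd
        and rec.ipae < crit.strict_ipae
    )
    return {"lax": lax, "strict": strict, "strict_evaluable": True}


def combine_success(
    records: Sequence[BenchmarkRecord],
    crit: SuccessCriteria = SuccessCriteria(),
    tier: str = "lax",
) -> bool:
    """Multi-state combination: every state/oracle record must pass."""
    if not records:
        return False
    flags = [classify_success(r, crit) for r in records]
    if tier == "strict" and any(not f["strict_evaluable"] for f in flags):
        raise IncompleteRecordError("strict tier needs ipAE on every record")
    return all(f[tier] for f in flags)


def select_best(
    records: Sequence[BenchmarkRecord],
    crit: SuccessCriteria = SuccessCriteria(),
    tier: str = "lax",
) -> tuple[BenchmarkRecord | None, list[dict]]:
    """Threshold first, then sort by scRMSD; smallest passing record wins.

    Returns (chosen record or None, per-record report with failure
    reasons).  The outcome is invariant to input order: ties in scRMSD
    break on design id then oracle name.
    """
    if not records:
        raise ValueError("select_best needs at least one record")
    report, passing = [], []
    for rec in records:
        flags = classify_success(rec, crit)
        reasons = []
        if tier == "strict" and not flags["strict_evaluable"]:
            reasons.append("ipae_missing")
        elif not flags[tier]:
            if rec.mean_plddt <= (crit.lax_plddt if tier == "lax" else crit.strict_plddt):
                reasons.append("plddt")
            if rec.scrmsd >= (crit.lax_scrmsd if tier == "lax" else crit.strict_scrmsd):
                reasons.append("scrmsd")
            if tier == "strict" and rec.ipae is not None and rec.ipae >= crit.strict_ipae:
                reasons.append("ipae")
        report.append({"design_id": rec.design_id, "oracle": rec.oracle,
                       "pass": not reasons and flags[tier], "reasons": reasons})
        if flags.get(tier):
            passing.append(rec)
    if not passing:
        return None, report
    chosen = min(passing, key=lambda r: (r.scrmsd, r.design_id, r.oracle))
    return chosen, report


@dataclass(frozen=True)
class CascadeThresholds:
    """Candidate-selection gates, applied in the listed order."""

    min_likelihood: float = -0.1   # nats/residue, drop if strictly below
    min_conf_product: float = 0.5  # pLDDT (0-1 scale) x pTM
    min_solubility: float = 1.0    # external predictor score, optional


@dataclass
class FilterDecision:
    keep: bool
    reasons: list[str]
    gates: dict[str, str]  # gate -> "pass" | "fail" | "not evaluated"


def filter_cascade(
    mean_log_likelihood: float,
    plddt: float,
    ptm: float,
    solubility: float | None = None,
    thresholds: CascadeThresholds = CascadeThresholds(),
) -> FilterDecision:
    """Likelihood, confidence-product and solubility gates, in that order.

    ``plddt`` is on the [0, 1] scale here (a 0-100 pLDDT would make the
    0.5 confidence-product threshold vacuous).  A missing solubility
    score skips that gate and records it as not evaluated.
    """
    gates: dict[str, str] = {}
    reasons: list[str] = []
    if mean_log_likelihood < thresholds.min_likelihood:
        gates["likelihood"] = "fail"
        reasons.append(
            f"mean log-likelihood {mean_log_likelihood:.4f} < {thresholds.min_likelihood}"
        )
    else:
        gates["likelihood"] = "pass"
    if plddt * ptm < thresholds.min_conf_product:
        gates["confidence_product"] = "fail"
        reasons.append(
            f"pLDDT*pTM {plddt * ptm:.4f} < {thresholds.min_conf_product}"
        )
    else:
        gates["confidence_product"] = "pass"
    if solubility is None:
        gates["solubility"] = "not evaluated"
    elif solubility < thresholds.min_solubility:
        gates["solubility"] = "fail"
        reasons.append(f"solubility {solubility} < {thresholds.min_solubility}")
    else:
        gates["solubility"] = "pass"
    return FilterDecision(keep=not reasons, reasons=reasons, gates=gates)
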