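"""Confidence- and geometry-based fitness terms for hallucination design.

Every term maps one or more predictor outputs to a scalar.  Confidence
terms live in [0, 1] (1 = perfect); geometric penalties are >= 0 and are
subtracted by the composites.  pLDDT is normalised to [0, 1] before it is
mixed with the pAE term so the combined confidence stays in [0, 1].

Composites (alpha defaults to 0.7 for the de novo and binder tasks):

    L_denovo = 2 (a L_conf(X1:...:XN) + (1-a) mean_i L_conf(Xi)) - L_R
    L_bind   = a L_ipAE(X, T) + (1-a) L_conf(X)
    L_change = a L_conf(X:Y) + (1-a) L_conf(X) - ReLU(L_TM - TM_max)
    L_binder = L_bind(a=0.7) - L_site(r=6 A) - L_R
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .structcore import Prediction, Structure, StructuralMismatchError


class PartitionError(ValueError):
    """Overlapping or empty residue partitions."""


class IncompleteTaskError(ValueError):
    """A composite was asked to run without all its prediction states."""


@dataclass(frozen=True)
class FitnessSpec:
    """Declarative description of one design objective.

    Parameters
    ----------
    task:
        ``denovo`` | ``binder`` | ``change`` | ``custom``.
    alpha:
        Mixing weight between the interaction/global term and the
        per-chain confidence term.
    r:
        Site-distance threshold in angstroms (binder task).
    radius:
        Radius-of-gyration threshold R in angstroms; ``None`` uses the
        globular scaling 2.2 N^0.38.
    tm_max:
        TM ceiling for the conformational-change penalty.
    site:
        Target-site residue indices (within the target part).
    designed_chains / target_chains:
        Chain ids of the designed part X and the fixed part T (or partner
        Y for change tasks).
    f_squared:
        Use the canonical squared weight 1/(1+(d/d0)^2) inside L_TM
        instead of the default 1/(1+d/d0).
    """

    task: str = "denovo"
    alpha: float = 0.7
    r: float = 6.0
    radius: float | None = None
    tm_max: float = 0.5
    pae_max: float = 31.75
    site: tuple[int, ...] = ()
    designed_chains: tuple[str, ...] = ()
    target_chains: tuple[str, ...] = ()
    f_squared: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius threshold must be positive")
        if not 0.0 <= self.tm_max <= 1.0:
            raise ValueError("tm_max must lie in [0, 1]")


def default_radius(n_residues: int) -> float:
    """Empirical compactness target for globular proteins, 2.2 N^0.38 A."""
    return 2.2 * n_residues**0.38


def _as_index(part: Sequence[int]) -> np.ndarray:
    idx = np.asarray(part, dtype=int)
    if idx.size == 0:
        raise PartitionError("empty residue part")
    return idx


def confidence_terms(
    p: Prediction, part: Sequence[int] | None = None
) -> dict[str, float]:
    """L_pAE, L_pLDDT and their mean L_conf over a residue subset.

    l_pae = 1 - mean(pAE over part x part) / pae_max
    l_plddt = mean(pLDDT over part) / 100
    l_conf = (l_pae + l_plddt) / 2
    """
    if part is None:
        part = np.arange(p.structure.n_residues)
    idx = _as_index(part)
    block = p.pae[np.ix_(idx, idx)]
    if np.any(block > p.pae_max + 1e-9):
        raise ValueError("pAE values exceed pae_max")
    l_pae = 1.0 - float(block.mean()) / p.pae_max
    l_plddt = float(p.plddt[idx].mean()) / 100.0
    return {"l_pae": l_pae, "l_plddt": l_plddt, "l_conf": 0.5 * (l_pae + l_plddt)}


def ipae_term(
    p: Prediction, x_part: Sequence[int], y_part: Sequence[int]
) -> float:
    """Interface confidence: 1 - mean of both cross blocks / pae_max."""
    xi, yi = _as_index(x_part), _as_index(y_part)
    if np.intersect1d(xi, yi).size:
        raise PartitionError("x_part and y_part overlap")
    both = np.concatenate(
        [p.pae[np.ix_(xi, yi)].ravel(), p.pae[np.ix_(yi, xi)].ravel()]
    )
    return 1.0 - float(both.mean()) / p.pae_max


def mean_interface_pae(
    p: Prediction, x_part: Sequence[int], y_part: Sequence[int]
) -> float:
    """Raw mean interface pAE in angstroms (the ipAE reported by benchmarks)."""
    xi, yi = _as_index(x_part), _as_index(y_part)
    both = np.concatenate(
        [p.pae[np.ix_(xi, yi)].ravel(), p.pae[np.ix_(yi, xi)].ravel()]
    )
    return float(both.mean())


def _local_frames(structure: Structure, idx: np.ndarray) -> np.ndarray:
    """Backbone frames (rotation matrices, columns = axes) per residue."""
    n_at = structure.backbone[idx, 0]
    ca = structure.backbone[idx, 1]
    c_at = structure.backbone[idx, 2]
    e1 = c_at - ca
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    v = n_at - ca
    v -= np.sum(v * e1, axis=1, keepdims=True) * e1
    e2 = v / np.linalg.norm(v, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=2)


def aligned_error_matrix(
    a: Structure, b: Structure, part: Sequence[int]
) -> np.ndarray:
    """AE_ij between two conformations of the same chain part.

    Residue i's CA is expressed in the local backbone frame of residue j
    in each structure; AE_ij is the distance between the two local
    positions.  This generalises the predicted-aligned-error geometry to a
    pair of realised structures.  Returns shape (j, i).
    """
    idx = _as_index(part)
    frames_a, frames_b = _local_frames(a, idx), _local_frames(b, idx)
    ca_a, ca_b = a.ca[idx], b.ca[idx]
    diff_a = ca_a[None, :, :] - ca_a[:, None, :]   # (j, i, 3)
    diff_b = ca_b[None, :, :] - ca_b[:, None, :]
    loc_a = np.einsum("jid,jdk->jik", diff_a, frames_a)
    loc_b = np.einsum("jid,jdk->jik", diff_b, frames_b)
    return np.linalg.norm(loc_a - loc_b, axis=-1)


def approx_tm_term(
    p_x: Prediction,
    p_xy: Prediction,
    x_part_mono: Sequence[int] | None = None,
    x_part_cplx: Sequence[int] | None = None,
    f_squared: bool = False,
) -> float:
    """Approximate template-matching score between two conformations of X.

    max_j mean_i f(AE_ij) with f(d) = 1/(1 + d/d0) by default (as
    printed), or the canonical squared form; d0 follows the TM-score
    normalisation with the short-chain floor at max(L, 19).
    """
    xm = np.arange(p_x.structure.n_residues) if x_part_mono is None else _as_index(x_part_mono)
    xc = xm if x_part_cplx is None else _as_index(x_part_cplx)
    if xm.size != xc.size:
        raise StructuralMismatchError("X parts differ in residue count")
    # express the complex part in its own frame; indices are part-relative
    sub_a = p_x.structure.subset(xm)
    sub_b = p_xy.structure.subset(xc)
    ae = aligned_error_matrix(sub_a, sub_b, np.arange(xm.size))
    d0 = 1.24 * (max(xm.size, 19) - 15) ** (1.0 / 3.0) - 1.8
    d0 = max(d0, 0.5)
    f = 1.0 / (1.0 + (ae / d0) ** 2) if f_squared else 1.0 / (1.0 + ae / d0)
    return float(np.max(np.mean(f, axis=1)))


def site_distance_penalty(
    p: Prediction,
    binder_part: Sequence[int],
    target_site: Sequence[int],
    r: float = 6.0,
) -> float:
    """Thresholded minimum CA-CA distance from the binder to the site.

    max(r, min_i d(X_i, T_s)) - r: zero while any binder residue is within
    r angstroms of the site, then grows linearly.
    """
    bi, si = _as_index(binder_part), _as_index(target_site)
    ca = p.structure.ca
    d = np.linalg.norm(ca[bi][:, None, :] - ca[si][None, :, :], axis=-1)
    return max(r, float(d.min())) - r


def radius_penalty(
    p: Prediction, part: Sequence[int] | None = None, radius: float | None = None
) -> float:
    """Radius-of-gyration penalty (max(R, Rg) - R) / R over CA atoms."""
    if part is None:
        part = np.arange(p.structure.n_residues)
    idx = _as_index(part)
    if radius is None:
        radius = default_radius(idx.size)
    if radius <= 0:
        raise ValueError("radius threshold must be positive")
    ca = p.structure.ca[idx]
    rg = float(np.sqrt(np.mean(np.sum((ca - ca.mean(axis=0)) ** 2, axis=1))))
    return (max(radius, rg) - radius) / radius


# ---------------------------------------------------------------------------
# Composites
# ---------------------------------------------------------------------------


def _parts(pred: Prediction, seq_ids: Sequence[str], chain_ids: Sequence[str]) -> np.ndarray:
    sel = []
    for cid in chain_ids:
        i = list(seq_ids).index(cid)
        a, b = pred.chain_intervals[i]
        sel.extend(range(a, b))
    return np.asarray(sel, dtype=int)


def composite_fitness(
    spec: FitnessSpec,
    predictions: Mapping[str, Prediction],
    chain_ids: Sequence[str] | None = None,
) -> float:
    """Evaluate the task composite from its required prediction states.

    ``predictions`` supplies ``"complex"`` (all tasks) and additionally
    ``"monomer"`` for the conformational-change task.  ``chain_ids`` names
    the chains of the complex prediction in order (defaults to A, B, ...).
    """
    if "complex" not in predictions:
        raise IncompleteTaskError("missing 'complex' prediction state")
    p = predictions["complex"]
    n_chain = len(p.chain_intervals)
    ids = tuple(chain_ids) if chain_ids else tuple(
        chr(ord("A") + i) for i in range(n_chain)
    )

    if spec.task == "denovo":
        whole = confidence_terms(p)["l_conf"]
        per_chain = [
            confidence_terms(p, np.arange(a, b))["l_conf"]
            for a, b in p.chain_intervals
        ]
        pen = radius_penalty(p, radius=spec.radius)
        return (
            2.0 * (spec.alpha * whole + (1 - spec.alpha) * float(np.mean(per_chain)))
            - pen
        )

    if spec.task in ("binder", "bind"):
        x_ids = spec.designed_chains or ids[:1]
        t_ids = spec.target_chains or ids[1:]
        if not t_ids:
            raise IncompleteTaskError("binder task needs a target chain")
        x = _parts(p, ids, x_ids)
        t = _parts(p, ids, t_ids)
        l_bind = spec.alpha * ipae_term(p, x, t) + (1 - spec.alpha) * confidence_terms(p, x)["l_conf"]
        if spec.task == "bind":
            return l_bind
        site = _parts(p, ids, t_ids)[list(spec.site)] if spec.site else t
        return (
            l_bind
            - site_distance_penalty(p, x, site, spec.r)
            - radius_penalty(p, x, spec.radius)
        )

    if spec.task == "change":
        if "monomer" not in predictions:
            raise IncompleteTaskError("change task needs a 'monomer' prediction")
        p_x = predictions["monomer"]
        x_ids = spec.designed_chains or ids[:1]
        x = _parts(p, ids, x_ids)
        l_tm = approx_tm_term(
            p_x, p, x_part_cplx=x, f_squared=spec.f_squared
        )
        return (
            spec.alpha * confidence_terms(p)["l_conf"]
            + (1 - spec.alpha) * confidence_terms(p_x)["l_conf"]
            - max(l_tm - spec.tm_max, 0.0)
        )

    raise ValueError(f"unknown task {spec.task!r}")
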