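"""Domain types for sequences, structures and predictions, plus the
geometry primitives every other module consumes.

Residue indexing is 0-based and contiguous over concatenated chains;
chain boundaries are carried as half-open ``(start, stop)`` intervals so
that per-chain slices of the pAE matrix are plain numpy slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

#: Canonical 20 amino acids, one-letter code, alphabetical.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

#: Default design alphabet: the 20 standard residues minus cysteine,
#: which is excluded by default because disulfide formation interferes
#: with soluble expression of designed proteins.
AA19_NO_CYS: str = AA20.replace("C", "")

#: Sentinel for a masked (not yet decided) position during redesign.
MASK: str = "_"

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructuralMismatchError(ValueError):
    """Two structures that must share residues do not."""


class DegenerateInputError(ValueError):
    """Too few atoms/snapshots for the requested operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainedSequence:
    """An ordered multi-chain amino-acid sequence.

    Parameters
    ----------
    chains:
        One string of one-letter residue codes per chain.
    chain_ids:
        Labels, one per chain (defaults to ``A``, ``B``, ...).
    alphabet:
        Allowed residue set; the mask sentinel is always tolerated.
    """

    chains: tuple[str, ...]
    chain_ids: tuple[str, ...] = ()
    alphabet: frozenset[str] = frozenset(AA20)

    def __post_init__(self) -> None:
        chains = tuple(self.chains)
        object.__setattr__(self, "chains", chains)
        ids = tuple(self.chain_ids) or tuple(
            chr(ord("A") + i) for i in range(len(chains))
        )
        object.__setattr__(self, "chain_ids", ids)
        if len(ids) != len(chains):
            raise ValueError("chain_ids and chains length mismatch")
        if self.length < 1:
            raise ValueError("total sequence length must be >= 1")
        allowed = set(self.alphabet) | {MASK}
        for chain in chains:
            bad = set(chain) - allowed
            if bad:
                raise ValueError(f"residues outside alphabet: {sorted(bad)}")

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def concatenated(self) -> str:
        return "".join(self.chains)

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        """Half-open index intervals of each chain in the concatenation."""
        out, start = [], 0
        for chain in self.chains:
            out.append((start, start + len(chain)))
            start += len(chain)
        return tuple(out)

    def chain_slice(self, chain_id: str) -> slice:
        i = self.chain_ids.index(chain_id)
        a, b = self.intervals[i]
        return slice(a, b)


@dataclass
class Structure:
    """Backbone (and optionally side-chain) coordinates for a chained sequence.

    ``backbone`` has shape ``(L, 4, 3)`` with atoms ordered N, CA, C, O in
    angstroms.  ``sidechain`` maps residue index to an ``(k, 3)`` array of
    side-chain heavy atoms when present.
    """

    backbone: np.ndarray
    chain_intervals: tuple[tuple[int, int], ...]
    sidechain: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, dtype=float)
        if self.backbone.ndim != 3 or self.backbone.shape[1:] != (4, 3):
            raise ValueError("backbone must have shape (L, 4, 3)")
        if not np.all(np.isfinite(self.backbone)):
            raise ValueError("non-finite coordinates")
        stops = [b for _, b in self.chain_intervals]
        if not self.chain_intervals or stops[-1] != self.n_residues:
            raise ValueError("chain intervals do not partition the residues")

    @property
    def n_residues(self) -> int:
        return self.backbone.shape[0]

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, shape (L, 3)."""
        return self.backbone[:, 1, :]

    def heavy_atoms(self, i: int) -> np.ndarray:
        """All heavy atoms of residue i (backbone + side chain)."""
        parts = [self.backbone[i]]
        if i in self.sidechain:
            parts.append(self.sidechain[i])
        return np.concatenate(parts, axis=0)

    def chain_of(self, i: int) -> int:
        for c, (a, b) in enumerate(self.chain_intervals):
            if a <= i < b:
                return c
        raise IndexError(i)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply a rigid motion ``x -> x R^T + t`` to every atom."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        bb = self.backbone @ rot.T + t
        sc = {i: xyz @ rot.T + t for i, xyz in self.sidechain.items()}
        return Structure(bb, self.chain_intervals, sc)

    def subset(self, indices: Sequence[int]) -> "Structure":
        """Extract residues, re-packed as a single chain."""
        idx = np.asarray(indices, dtype=int)
        bb = self.backbone[idx]
        sc = {
            k: self.sidechain[i]
            for k, i in enumerate(idx)
            if int(i) in self.sidechain
        }
        return Structure(bb, ((0, len(idx)),), sc)


@dataclass
class Prediction:
    """A structure-predictor output: coordinates plus confidence.

    pLDDT is per-residue on the 0-100 scale; pAE is the residue-pair
    predicted aligned error in angstroms, bounded by ``pae_max``; pTM is
    the global template-modelling confidence in [0, 1].
    """

    structure: Structure
    plddt: np.ndarray
    pae: np.ndarray
    ptm: float
    pae_max: float = 31.75

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = self.structure.n_residues
        if self.plddt.shape != (n,):
            raise ValueError("plddt length must equal residue count")
        if self.pae.shape != (n, n):
            raise ValueError("pae must be square with side = residue count")
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError("plddt outside [0, 100]")
        if np.any(self.pae < 0) or np.any(self.pae > self.pae_max + 1e-9):
            raise ValueError("pae outside [0, pae_max]")
        if not 0.0 <= self.ptm <= 1.0:
            raise ValueError("ptm outside [0, 1]")

    @property
    def chain_intervals(self) -> tuple[tuple[int, int], ...]:
        return self.structure.chain_intervals


@dataclass
class Ensemble:
    """Ordered structures over identical residues (trajectory snapshots)."""

    members: list[Structure]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ensemble")
        ref = self.members[0]
        for m in self.members[1:]:
            if m.n_residues != ref.n_residues or m.chain_intervals != ref.chain_intervals:
                raise StructuralMismatchError("ensemble members differ in residues")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def _select_atoms(s: Structure, atom_set: str) -> np.ndarray:
    """Flatten the requested atom selection into an (n_atoms, 3) array."""
    if atom_set == "ca":
        return s.ca
    if atom_set == "backbone":
        return s.backbone.reshape(-1, 3)
    if atom_set == "heavy":
        return np.concatenate(
            [s.heavy_atoms(i) for i in range(s.n_residues)], axis=0
        )
    raise ValueError(f"unknown atom set {atom_set!r}")


def superpose(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of point sets (no reflection).

    Returns ``(moved, rotation, translation)`` such that
    ``moved = (moving - centroid_m) @ R.T + centroid_t`` minimises the RMSD
    to ``target``.  The rotation is proper (det = +1): chirality is physical
    and mirror images must not superpose to zero.
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape:
        raise StructuralMismatchError("point sets differ in shape")
    if moving.shape[0] < 2:
        raise DegenerateInputError("need >= 2 atoms for superposition")
    cm, ct = moving.mean(axis=0), target.mean(axis=0)
    with warnings.catch_warnings():
        # scipy warns when the optimal rotation is not unique (collinear
        # or two-point sets); any optimum attains the same RMSD
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(target - ct, moving - cm)
    rmat = rot.as_matrix()
    moved = (moving - cm) @ rmat.T + ct
    return moved, rmat, ct - cm @ rmat.T


def kabsch_rmsd(a: Structure, b: Structure, atom_set: str = "ca") -> float:
    """Minimal RMSD between two structures over rigid superposition.

    The default selection is CA atoms, the field convention for design
    self-consistency (scRMSD); pass ``atom_set="backbone"`` for all four
    backbone atoms.
    """
    if a.n_residues != b.n_residues:
        raise StructuralMismatchError(
            f"residue counts differ: {a.n_residues} vs {b.n_residues}"
        )
    pa, pb = _select_atoms(a, atom_set), _select_atoms(b, atom_set)
    moved, _, _ = superpose(pa, pb)
    return float(np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1))))


def tm_d0(length: int) -> float:
    """Standard TM-score normalisation d0(L) = 1.24 (L - 15)^(1/3) - 1.8.

    Clamped to >= 0.5 A so that very short chains keep a positive scale.
    """
    d0 = 1.24 * max(length - 15, 0) ** (1.0 / 3.0) - 1.8
    return max(d0, 0.5)


def tm_score(a: Structure, b: Structure, max_iter: int = 20) -> float:
    """TM-score between equal-length structures under identity mapping.

    The superposition maximising the score is found iteratively: start
    from the full-length Kabsch superposition, then repeatedly re-superpose
    on the residue subset currently within the inclusion cutoff and keep
    the best score seen.  Per-pair weight is 1/(1 + (d_i/d0)^2).
    """
    if a.n_residues != b.n_residues:
        raise StructuralMismatchError("residue counts differ")
    ca_a, ca_b = a.ca, b.ca
    n = a.n_residues
    d0 = tm_d0(n)

    def score_for(moved: np.ndarray) -> tuple[float, np.ndarray]:
        d = np.linalg.norm(moved - ca_b, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d

    moved, _, _ = superpose(ca_a, ca_b)
    best, d = score_for(moved)
    cutoff = max(d0, 1.0)
    for _ in range(max_iter):
        keep = d < cutoff
        if keep.sum() < 3:
            break
        _, rmat, t = superpose(ca_a[keep], ca_b[keep])
        moved = ca_a @ rmat.T + t
        s, d_new = score_for(moved)
        if s <= best + 1e-12:
            break
        best, d = s, d_new
    return best


def radius_of_gyration(s: Structure, atom_set: str = "ca") -> float:
    """Root-mean-square distance of the selected atoms to their centroid."""
    pts = _select_atoms(s, atom_set)
    if pts.shape[0] < 1:
        raise DegenerateInputError("empty atom selection")
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def contact_count(
    s: Structure, partition: str = "intra", threshold: float = 4.0
) -> int:
    """Number of residue pairs with any heavy-atom pair within threshold.

    ``partition="intra"`` counts sequence-non-adjacent pairs within one
    chain; ``"interface"`` counts cross-chain pairs.  The 4 A heavy-atom
    cutoff is the conventional contact definition for trajectory analysis.
    """
    if partition not in ("intra", "interface"):
        raise ValueError(f"unknown partition {partition!r}")
    n = s.n_residues
    atoms = [s.heavy_atoms(i) for i in range(n)]
    count = 0
    for i in range(n):
        ci = s.chain_of(i)
        for j in range(i + 1, n):
            cj = s.chain_of(j)
            if partition == "intra" and (ci != cj or j - i < 2):
                continue
            if partition == "interface" and ci == cj:
                continue
            dmin = np.min(
                np.linalg.norm(atoms[i][:, None, :] - atoms[j][None, :, :], axis=-1)
            )
            if dmin < threshold:
                count += 1
    return count


def rmsf(e: Ensemble, atom_set: str = "ca", align: bool = True) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the ensemble mean.

    Each snapshot is superposed (on the selected atoms) onto the running
    mean structure in two passes, which is enough for the mean to
    stabilise; fluctuation is then the RMS CA deviation per residue.
    """
    if len(e) < 2:
        raise DegenerateInputError("RMSF needs >= 2 snapshots")
    coords = np.stack([_select_atoms(m, atom_set) for m in e.members])
    if align:
        mean = coords[0]
        for _ in range(2):  # two-pass mean alignment
            aligned = np.empty_like(coords)
            for k in range(coords.shape[0]):
                aligned[k], _, _ = superpose(coords[k], mean)
            mean = aligned.mean(axis=0)
            coords = aligned
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
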