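"""The structure-predictor contract and a deterministic synthetic predictor.

Design loops treat structure prediction as an oracle: sequence in,
coordinates + confidence out.  The :class:`SyntheticFolder` implements
that contract with a smooth, seeded sequence-propensity landscape so the
whole pipeline runs at desk scale with no neural network.  Adapters for
real predictors can implement the same ``predict``/``predict_many``
surface and be registered by name.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structcore import (
    AA20,
    ChainedSequence,
    Prediction,
    Structure,
    tm_d0,
)


class UnsupportedResidueError(ValueError):
    """A residue outside the oracle's alphabet was submitted."""


class InvalidBudgetError(ValueError):
    """A template crop budget smaller than the binding site."""


@dataclass(frozen=True)
class Template:
    """A cropped sequence+structure fragment pinned during prediction.

    ``index_map`` holds the source residue index (within the chain the
    template is attached to) of each template residue, strictly increasing.
    """

    sequence: str
    structure: Structure
    index_map: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != self.structure.n_residues:
            raise ValueError("template sequence/structure length mismatch")
        if len(self.index_map) != len(self.sequence):
            raise ValueError("index map length mismatch")
        if any(b <= a for a, b in zip(self.index_map, self.index_map[1:])):
            raise ValueError("index map must be strictly increasing")


@dataclass(frozen=True)
class OracleRequest:
    """One prediction request: sequence, optional templates, recycling."""

    sequence: ChainedSequence
    templates: tuple[tuple[str, Template], ...] = ()
    recycle_count: int = 2
    init_structure: Structure | None = None

    def __post_init__(self) -> None:
        if self.recycle_count < 0:
            raise ValueError("recycle_count must be >= 0")
        for cid, _ in self.templates:
            if cid not in self.sequence.chain_ids:
                raise ValueError(f"template chain {cid!r} not in sequence")

    def cache_key(self) -> tuple:
        """Canonical hash key: templates enter via a coordinate digest."""
        tdig = tuple(
            (cid, t.sequence, t.index_map,
             zlib.crc32(np.ascontiguousarray(t.structure.backbone).tobytes()))
            for cid, t in self.templates
        )
        return (self.sequence.chains, self.sequence.chain_ids, tdig,
                self.recycle_count)


def crop_target(
    structure: Structure,
    sequence: str,
    site: Sequence[int],
    budget: int,
) -> Template:
    """Crop a target structure to ``budget`` residues around a binding site.

    Keeps the ``budget`` residues whose CA atoms are nearest to the site
    centroid; site residues are always included and the original residue
    indices are preserved in the template's index map.
    """
    site = sorted(set(int(i) for i in site))
    n = structure.n_residues
    if any(i < 0 or i >= n for i in site):
        raise IndexError("site index out of range")
    if budget < len(site):
        raise InvalidBudgetError(
            f"budget {budget} smaller than site size {len(site)}"
        )
    budget = min(budget, n)
    centroid = structure.ca[site].mean(axis=0)
    dist = np.linalg.norm(structure.ca - centroid, axis=1)
    dist[site] = -1.0  # site residues sort first
    order = np.argsort(dist, kind="stable")[:budget]
    keep = np.sort(order)
    frag = structure.subset(keep)
    return Template(
        sequence="".join(sequence[i] for i in keep),
        structure=frag,
        index_map=tuple(int(i) for i in keep),
    )


# ---------------------------------------------------------------------------
# Synthetic folder
# ---------------------------------------------------------------------------

# idealised alpha-helix CA trace parameters
_HELIX_RADIUS = 2.3       # A
_HELIX_RISE = 1.5         # A per residue
_HELIX_TURN = np.deg2rad(100.0)
_CHAIN_SPACING = 18.0     # A between chain trace origins


@dataclass
class SyntheticFolder:
    """Deterministic stand-in structure predictor.

    The landscape assigns every residue type a fixed "fold propensity" in
    [0, 1] (a seeded permutation of an evenly spaced grid, so one residue
    attains exactly 1).  Per-residue pLDDT is 100 times the windowed mean
    propensity, sharpened slightly by recycling; pAE grows with sequence
    separation and shrinks with the pairwise-min pLDDT; coordinates follow
    an idealised helix trace perturbed by seeded coil noise whose amplitude
    shrinks as confidence rises.  Everything is a pure function of
    (sequence, templates, recycle_count, seed).
    """

    seed: int = 0
    pae_max: float = 31.75
    window: int = 5
    coil_scale: float = 5.0
    pair_tau: float = 10.0
    template_plddt: float = 90.0
    alphabet: str = AA20

    n_calls: int = 0
    cache_hits: int = 0
    _cache: dict = field(default_factory=dict, repr=False)
    _propensity: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        values = rng.permutation(np.linspace(0.0, 1.0, len(self.alphabet)))
        self._propensity = dict(zip(self.alphabet, values))

    # -- landscape introspection (used by tests and the consistent model) --

    @property
    def propensity(self) -> dict[str, float]:
        return dict(self._propensity)

    @property
    def best_residue(self) -> str:
        return max(self._propensity, key=self._propensity.get)

    # -- prediction ---------------------------------------------------------

    def predict(self, req: OracleRequest) -> Prediction:
        key = req.cache_key()
        if key in self._cache:
            self.cache_hits += 1
            return self._cache[key]
        self.n_calls += 1
        pred = self._predict_uncached(req)
        self._cache[key] = pred
        return pred

    def predict_many(self, reqs: Sequence[OracleRequest]) -> list[Prediction]:
        return [self.predict(r) for r in reqs]

    def _plddt(self, seq: ChainedSequence, recycle_count: int) -> np.ndarray:
        smooth = []
        for chain in seq.chains:
            prop = np.array([self._prop_of(c) for c in chain])
            w = min(self.window, len(prop))
            kernel = np.ones(w)
            num = np.convolve(prop, kernel, mode="same")
            den = np.convolve(np.ones_like(prop), kernel, mode="same")
            smooth.append(num / den)
        s = np.concatenate(smooth)
        # recycling sharpens confidence; exponent keeps the fixed points 0, 1
        gain = 1.0 / (1.0 + 0.1 * min(recycle_count, 4))
        return 100.0 * np.power(s, gain)

    def _prop_of(self, residue: str) -> float:
        try:
            return self._propensity[residue]
        except KeyError:
            raise UnsupportedResidueError(
                f"residue {residue!r} outside oracle alphabet"
            ) from None

    def _coords(self, seq: ChainedSequence, plddt: np.ndarray) -> Structure:
        backbones = []
        for ci, (chain, (start, stop)) in enumerate(
            zip(seq.chains, seq.intervals)
        ):
            L = len(chain)
            i = np.arange(L)
            theta = i * _HELIX_TURN
            ca = np.stack(
                [
                    _HELIX_RADIUS * np.cos(theta) + ci * _CHAIN_SPACING,
                    _HELIX_RADIUS * np.sin(theta),
                    _HELIX_RISE * i,
                ],
                axis=1,
            )
            # seeded coil noise, amplitude shrinking with confidence
            crc = zlib.crc32(chain.encode())
            rng = np.random.default_rng([self.seed, crc])
            noise = rng.normal(size=(L, 3))
            amp = self.coil_scale * (1.0 - plddt[start:stop] / 100.0)
            ca = ca + noise * amp[:, None]
            # backbone atoms in a tangent frame along the trace
            tang = np.gradient(ca, axis=0) if L > 1 else np.array([[0, 0, 1.0]])
            tang = tang / np.maximum(
                np.linalg.norm(tang, axis=1, keepdims=True), 1e-9
            )
            ref = np.array([0.0, 0.0, 1.0])
            u = np.cross(tang, ref)
            bad = np.linalg.norm(u, axis=1) < 1e-6
            u[bad] = np.array([1.0, 0.0, 0.0])
            u = u / np.linalg.norm(u, axis=1, keepdims=True)
            v = np.cross(tang, u)
            bb = np.empty((L, 4, 3))
            bb[:, 1] = ca
            bb[:, 0] = ca - 0.73 * tang + 1.23 * u          # N
            bb[:, 2] = ca + 0.74 * tang + 1.20 * u + 0.3 * v  # C
            bb[:, 3] = bb[:, 2] + 0.62 * v - 1.0 * u          # O
            backbones.append(bb)
        return Structure(np.concatenate(backbones), seq.intervals)

    def _predict_uncached(self, req: OracleRequest) -> Prediction:
        seq = req.sequence
        plddt = self._plddt(seq, req.recycle_count)

        # template pinning lifts confidence of pinned residues
        pinned: dict[int, np.ndarray] = {}
        for cid, tmpl in req.templates:
            offset = seq.chain_slice(cid).start
            for k, src in enumerate(tmpl.index_map):
                gi = offset + src
                pinned[gi] = tmpl.structure.backbone[k]
                plddt[gi] = max(plddt[gi], self.template_plddt)

        structure = self._coords(seq, plddt)
        for gi, bb in pinned.items():
            structure.backbone[gi] = bb

        n = seq.length
        sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        conf = np.minimum(plddt[:, None], plddt[None, :]) / 100.0
        pae = self.pae_max * (1.0 - conf) * (sep / (sep + self.pair_tau))

        d0 = tm_d0(n)
        ptm = float(np.max(np.mean(1.0 / (1.0 + (pae / d0) ** 2), axis=0)))
        return Prediction(structure, plddt, pae, ptm, pae_max=self.pae_max)

    # -- landscape-consistent sequence model --------------------------------

    def consistent_sequence_model(self, sharpness: float = 8.0):
        """A structure-conditioned sequence model matched to this landscape.

        Acts as the stand-in for a trained sequence-design network: its
        per-position distributions put mass on residues in proportion to
        exp(sharpness * propensity), so sampling recovers sequences the
        folder predicts with high confidence.
        """
        return PropensitySequenceModel(self.propensity, sharpness)


@dataclass
class PropensitySequenceModel:
    """Categorical sequence model derived from a propensity landscape."""

    propensity: dict[str, float]
    sharpness: float = 8.0
    alphabet: str = AA20

    def _base_probs(self) -> np.ndarray:
        logits = np.array(
            [self.sharpness * self.propensity.get(a, -1.0) for a in self.alphabet]
        )
        p = np.exp(logits - logits.max())
        return p / p.sum()

    def profile(self, masked_sequence: str, structure: Structure) -> np.ndarray:
        base = self._base_probs()
        return np.tile(base, (len(masked_sequence), 1))

    def log_likelihood(self, sequence: str, structure: Structure) -> np.ndarray:
        base = np.log(self._base_probs())
        idx = [self.alphabet.index(c) for c in sequence]
        return base[idx]


def synthetic_folder_config(seed: int = 0, **landscape) -> SyntheticFolder:
    """Factory for a configured synthetic predictor instance."""
    return SyntheticFolder(seed=seed, **landscape)


#: registry of oracle factories discoverable by name from run configs
ORACLES = {"synthetic": synthetic_folder_config}
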