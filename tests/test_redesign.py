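"""The masked autoregressive sampler, likelihood scoring and the
built-in profile model."""

import numpy as np
import pytest
from scipy import stats

from foldforge.redesign import (
    RedesignConstraints,
    UnsatisfiableConstraintError,
    redesign_batch,
    reference_profile_model,
    sample_sequence,
    score_likelihood,
)
from foldforge.structcore import AA20

from conftest import random_rigid, random_structure


class ToyModel:
    """Position-independent categorical toy model over a small alphabet."""

    def __init__(self, probs, alphabet):
        self.probs = np.asarray(probs, dtype=float)
        self.alphabet = alphabet

    def profile(self, masked_sequence, structure):
        return np.tile(self.probs, (len(masked_sequence), 1))

    def log_likelihood(self, sequence, structure):
        idx = [self.alphabet.index(c) for c in sequence]
        with np.errstate(divide="ignore"):
            return np.log(self.probs)[idx]


class TestSampler:
    def test_one_hot_model_is_deterministic(self, rng):
        s = random_structure(rng, 6)
        probs = np.zeros(len(AA20))
        probs[AA20.index("K")] = 1.0
        model = ToyModel(probs, AA20)
        for seed in range(5):
            seq, _ = sample_sequence(model, s, seed=seed)
            assert seq == "K" * 6

    def test_forbidden_residue_never_sampled(self, rng):
        s = random_structure(rng, 3)
        model = ToyModel([0.5, 0.5], "AC")
        constraints = RedesignConstraints(forbidden=frozenset("C"))
        gen = np.random.default_rng(0)
        for _ in range(10_000 // 3 + 1):
            seq, _ = sample_sequence(model, s, constraints, rng=gen)
            assert "C" not in seq

    def test_all_forbidden_raises(self, rng):
        s = random_structure(rng, 3)
        model = ToyModel([1.0], "C")
        with pytest.raises(UnsatisfiableConstraintError):
            sample_sequence(model, s, RedesignConstraints(forbidden=frozenset("C")))

    def test_inverse_temperature_sharpening(self, rng):
        # two outcomes (0.6, 0.4) at beta 10 -> 0.6^10/(0.6^10+0.4^10)
        s = random_structure(rng, 1)
        model = ToyModel([0.6, 0.4], "AV")
        expected = 0.6**10 / (0.6**10 + 0.4**10)
        gen = np.random.default_rng(1)
        n = 10_000
        hits = 0
        for _ in range(n):
            seq, _ = sample_sequence(model, s, rng=gen)
            hits += seq == "A"
        freq = hits / n
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(freq - expected) < 3 * sigma

    def test_product_distribution_chi_square(self, rng):
        # 3 positions x 3 letters: empirical counts vs the temperature-10
        # adjusted product distribution (chi-square GoF, p > 0.01)
        s = random_structure(rng, 3)
        base = np.array([0.36, 0.33, 0.31])
        model = ToyModel(base, "ADE")
        sharp = base**10 / np.sum(base**10)
        gen = np.random.default_rng(2)
        n = 10_000
        counts: dict[str, int] = {}
        for _ in range(n):
            seq, _ = sample_sequence(model, s, rng=gen)
            counts[seq] = counts.get(seq, 0) + 1
        outcomes = [a + b + c for a in "ADE" for b in "ADE" for c in "ADE"]
        observed = np.array([counts.get(o, 0) for o in outcomes])
        probs = np.array(
            [sharp["ADE".index(o[0])] * sharp["ADE".index(o[1])] *
             sharp["ADE".index(o[2])] for o in outcomes]
        )
        _, p = stats.chisquare(observed, n * probs)
        assert p > 0.01

    def test_tied_positions_always_identical(self, rng):
        s = random_structure(rng, 6)
        model = ToyModel(np.full(4, 0.25), "ADEG")
        constraints = RedesignConstraints(tied=((0, 2, 4), (1, 5)))
        gen = np.random.default_rng(3)
        for _ in range(200):
            seq, _ = sample_sequence(model, s, constraints, rng=gen)
            assert seq[0] == seq[2] == seq[4]
            assert seq[1] == seq[5]

    def test_frozen_region_kept(self, rng):
        s = random_structure(rng, 8)
        model = ToyModel(np.full(4, 0.25), "ADEG")
        constraints = RedesignConstraints(frozen=frozenset(range(4)))
        seq, _ = sample_sequence(
            model, s, constraints, start_sequence="GGGGAAAA", seed=4
        )
        assert seq[:4] == "GGGG"

    def test_infinite_beta_equals_argmax(self, rng):
        s = random_structure(rng, 10)
        base = np.random.default_rng(7).dirichlet(np.ones(4))
        model = ToyModel(base, "ADEG")
        argmax = "ADEG"[int(np.argmax(base))] * 10
        for seed in range(5):
            seq, _ = sample_sequence(model, s, inv_temperature=1e6, seed=seed)
            assert seq == argmax


class TestLikelihood:
    def test_uniform_model_closed_form(self, rng):
        s = random_structure(rng, 20)
        model = ToyModel(np.full(len(AA20), 1 / len(AA20)), AA20)
        got = score_likelihood(model, "A" * 20, s)
        assert got == pytest.approx(-np.log(20), abs=1e-12)

    def test_one_hot_scores_own_argmax_at_zero(self, rng):
        s = random_structure(rng, 5)
        probs = np.zeros(len(AA20))
        probs[AA20.index("W")] = 1.0
        model = ToyModel(probs, AA20)
        assert score_likelihood(model, "W" * 5, s) == 0.0

    def test_zero_probability_gives_neg_inf(self, rng):
        s = random_structure(rng, 4)
        probs = np.zeros(len(AA20))
        probs[AA20.index("W")] = 1.0
        model = ToyModel(probs, AA20)
        assert score_likelihood(model, "WAWW", s) == -np.inf


class TestRedesignBatch:
    def test_ranking_non_increasing_and_deduplicated(self, rng):
        s = random_structure(rng, 5)
        model = ToyModel(np.array([0.4, 0.3, 0.2, 0.1]), "ADEG")
        ranked = redesign_batch(model, s, n_samples=50, inv_temperature=2.0,
                                seed=5)
        liks = [r.likelihood for r in ranked]
        assert liks == sorted(liks, reverse=True)
        assert len({r.sequence for r in ranked}) == len(ranked)

    def test_frozen_target_identical_across_samples(self, rng):
        s = random_structure(rng, 8)
        model = ToyModel(np.full(4, 0.25), "ADEG")
        constraints = RedesignConstraints(frozen=frozenset(range(3)))
        ranked = redesign_batch(
            model, s, n_samples=30, constraints=constraints,
            start_sequence="EEEAAAAA", seed=6,
        )
        assert all(r.sequence[:3] == "EEE" for r in ranked)

    def test_peaked_model_top_rank_is_argmax(self, rng):
        s = random_structure(rng, 6)
        model = ToyModel(np.array([0.7, 0.1, 0.1, 0.1]), "ADEG")
        hits = 0
        for seed in range(20):
            ranked = redesign_batch(model, s, n_samples=20, seed=seed)
            hits += ranked[0].sequence == "A" * 6
        assert hits >= 19


class TestReferenceProfileModel:
    def _burial_structure(self, rng):
        # residue 0 densely surrounded -> buried; far residue exposed
        n = 12
        ca = rng.normal(scale=3.0, size=(n, 3))
        ca[0] = 0.0
        ca[-1] = [40.0, 0, 0]
        bb = np.empty((n, 4, 3))
        bb[:, 1] = ca
        bb[:, 0] = ca + [1.0, 0, 0]
        bb[:, 2] = ca + [0, 1.0, 0]
        bb[:, 3] = ca + [0, 0, 1.0]
        from foldforge.structcore import Structure

        return Structure(bb, ((0, n),))

    def test_buried_prefers_hydrophobic(self, rng):
        s = self._burial_structure(rng)
        model = reference_profile_model(s)
        prof = model.profile("_" * 12, s)
        hydro = [AA20.index(a) for a in "AFILMVWY"]
        polar = [AA20.index(a) for a in "DEHKNQRST"]
        assert prof[0, hydro].sum() > prof[0, polar].sum()
        assert prof[-1, polar].sum() > prof[-1, hydro].sum()

    def test_rows_sum_to_one(self, rng):
        s = random_structure(rng, 9)
        prof = reference_profile_model(s).profile("_" * 9, s)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)
        assert prof.min() > 0

    def test_rigid_motion_invariance(self, rng):
        s = random_structure(rng, 10)
        rot, t = random_rigid(rng)
        p1 = reference_profile_model(s).profile("_" * 10, s)
        moved = s.transformed(rot, t)
        p2 = reference_profile_model(moved).profile("_" * 10, moved)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
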