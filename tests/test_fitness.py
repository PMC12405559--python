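"""The fitness algebra: analytic extremes, hand-computed composites,
pair-enumeration oracles and monotonicity."""

import numpy as np
import pytest

from foldforge.fitness import (
    FitnessSpec,
    IncompleteTaskError,
    PartitionError,
    approx_tm_term,
    composite_fitness,
    confidence_terms,
    default_radius,
    ipae_term,
    radius_penalty,
    site_distance_penalty,
)
from foldforge.structcore import Prediction, Structure
from foldforge.workbench import ideal_helix, make_prediction_fixture

from conftest import random_rigid, random_structure

PAE_MAX = 31.75


def _pred(structure, plddt, pae, ptm=0.8):
    return Prediction(structure, plddt, pae, ptm, pae_max=PAE_MAX)


def _uniform_pred(rng, n, plddt_val, pae_val, n_chains=1):
    s = random_structure(rng, n, n_chains=n_chains)
    return _pred(s, np.full(n, plddt_val), np.full((n, n), pae_val))


class TestConfidenceTerms:
    def test_perfect_extreme(self, rng):
        t = confidence_terms(_uniform_pred(rng, 10, 100.0, 0.0))
        assert t == {"l_pae": 1.0, "l_plddt": 1.0, "l_conf": 1.0}

    def test_zero_extreme(self, rng):
        t = confidence_terms(_uniform_pred(rng, 10, 0.0, PAE_MAX))
        assert t["l_pae"] == pytest.approx(0.0)
        assert t["l_plddt"] == pytest.approx(0.0)
        assert t["l_conf"] == pytest.approx(0.0)

    def test_hand_computed_mixture(self, rng):
        t = confidence_terms(_uniform_pred(rng, 8, 80.0, PAE_MAX / 2))
        assert t["l_conf"] == pytest.approx(0.65, abs=1e-12)

    def test_empty_part_raises(self, rng):
        with pytest.raises(PartitionError):
            confidence_terms(_uniform_pred(rng, 4, 50.0, 1.0), [])


class TestIpae:
    def test_extremes(self, rng):
        p = _uniform_pred(rng, 10, 90.0, 0.0, n_chains=2)
        assert ipae_term(p, range(5), range(5, 10)) == pytest.approx(1.0)
        p2 = _uniform_pred(rng, 10, 90.0, PAE_MAX, n_chains=2)
        assert ipae_term(p2, range(5), range(5, 10)) == pytest.approx(0.0)

    def test_asymmetric_blocks_match_enumeration(self, rng):
        n = 9
        s = random_structure(rng, n, n_chains=2)
        pae = rng.uniform(0, PAE_MAX, (n, n))
        p = _pred(s, np.full(n, 70.0), pae)
        x, y = list(range(4)), list(range(4, 9))
        pairs = [pae[i, j] for i in x for j in y] + [pae[j, i] for i in x for j in y]
        expected = 1.0 - np.mean(pairs) / PAE_MAX
        assert ipae_term(p, x, y) == pytest.approx(expected, abs=1e-12)

    def test_overlap_raises(self, rng):
        p = _uniform_pred(rng, 6, 50.0, 1.0)
        with pytest.raises(PartitionError):
            ipae_term(p, [0, 1, 2], [2, 3])


class TestApproxTm:
    def test_identical_conformations(self, rng):
        s = random_structure(rng, 20)
        p = _pred(s, np.full(20, 80.0), np.zeros((20, 20)))
        assert approx_tm_term(p, p) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_motion_of_one_state(self, rng):
        # aligned error is frame-local, so a rigid motion changes nothing
        s = random_structure(rng, 15)
        rot, t = random_rigid(rng)
        pa = _pred(s, np.full(15, 80.0), np.zeros((15, 15)))
        pb = _pred(s.transformed(rot, t), np.full(15, 80.0), np.zeros((15, 15)))
        assert approx_tm_term(pa, pb) == pytest.approx(1.0, abs=1e-6)

    def test_d0_uses_short_chain_floor(self):
        # d0 = 1.24 (max(L,19) - 15)^(1/3) - 1.8; at L=50: ~2.256
        d0 = 1.24 * (50 - 15) ** (1 / 3) - 1.8
        assert d0 == pytest.approx(2.2558, abs=1e-3)

    def test_f_of_d0_is_half(self, rng):
        # any AE exactly d0 contributes f = 1/(1 + d0/d0) = 1/2
        s = random_structure(rng, 20)
        ae = np.full((20, 20), 1.0)
        d0 = 1.24 * (20 - 15) ** (1 / 3) - 1.8
        f = 1.0 / (1.0 + (d0 / d0))
        assert f == 0.5


class TestPenalties:
    def test_site_inside_threshold(self, rng):
        ca = np.zeros((4, 3))
        ca[2] = [3.0, 0, 0]  # binder residue 3 A from site
        bb = np.stack([np.tile(c, (4, 1)) for c in ca])
        s = Structure(bb, ((0, 2), (2, 4)))
        p = _pred(s, np.full(4, 80.0), np.zeros((4, 4)))
        assert site_distance_penalty(p, [2, 3], [0], r=6.0) == 0.0

    def test_site_outside_threshold(self, rng):
        ca = np.zeros((4, 3))
        ca[2] = [10.0, 0, 0]
        ca[3] = [14.0, 0, 0]
        bb = np.stack([np.tile(c, (4, 1)) for c in ca])
        s = Structure(bb, ((0, 2), (2, 4)))
        p = _pred(s, np.full(4, 80.0), np.zeros((4, 4)))
        assert site_distance_penalty(p, [2, 3], [0], r=6.0) == pytest.approx(4.0)

    def test_site_matches_brute_force(self, rng):
        s = random_structure(rng, 12, n_chains=2)
        p = _pred(s, np.full(12, 80.0), np.zeros((12, 12)))
        binder, site = list(range(6)), [7, 9]
        brute = min(
            np.linalg.norm(s.ca[i] - s.ca[j]) for i in binder for j in site
        )
        expected = max(6.0, brute) - 6.0
        assert site_distance_penalty(p, binder, site) == pytest.approx(expected)

    def test_radius_no_penalty_inside(self, rng):
        p = _uniform_pred(rng, 10, 80.0, 1.0)
        assert radius_penalty(p, radius=1e6) == 0.0

    def test_radius_forced_arithmetic(self):
        # Rg = 2R gives penalty exactly 1
        ca = np.array([[-2.0, 0, 0], [2.0, 0, 0]])
        bb = np.stack([np.tile(c, (4, 1)) for c in ca])
        s = Structure(bb, ((0, 2),))
        p = _pred(s, np.full(2, 80.0), np.zeros((2, 2)))
        assert radius_penalty(p, radius=1.0) == pytest.approx(1.0)

    def test_compact_vs_elongated(self):
        helix = ideal_helix(30)
        stretched = Structure(
            helix.backbone * np.array([1.0, 1.0, 3.0]), helix.chain_intervals
        )
        p1 = _pred(helix, np.full(30, 80.0), np.zeros((30, 30)))
        p2 = _pred(stretched, np.full(30, 80.0), np.zeros((30, 30)))
        assert radius_penalty(p1) <= radius_penalty(p2)

    def test_default_radius_scaling(self):
        assert default_radius(100) == pytest.approx(2.2 * 100**0.38)


class TestComposites:
    def test_denovo_perfect_extreme(self):
        p = make_prediction_fixture(20, plddt=100.0, mean_pae=0.0, n_chains=2)
        spec = FitnessSpec(task="denovo", radius=1e6)
        assert composite_fitness(spec, {"complex": p}) == pytest.approx(2.0)

    def test_denovo_zero_extreme(self):
        p = make_prediction_fixture(20, plddt=0.0, mean_pae=PAE_MAX, n_chains=2)
        spec = FitnessSpec(task="denovo", radius=1e6)
        assert composite_fitness(spec, {"complex": p}) == pytest.approx(0.0)

    def test_binder_hand_computed(self, rng):
        # L_ipAE = 0.8, L_conf(X) = 0.6, site within r, Rg below R
        n = 10
        s = random_structure(rng, n, n_chains=2, spread=2.0)
        pae = np.zeros((n, n))
        pae[:5, 5:] = pae[5:, :5] = 0.2 * PAE_MAX   # l_ipae = 0.8
        pae[:5, :5] = 0.6 * PAE_MAX                 # l_pae(X) = 0.4
        p = _pred(s, np.full(n, 80.0), pae)         # l_conf(X) = 0.6
        spec = FitnessSpec(task="binder", radius=1e6)
        got = composite_fitness(spec, {"complex": p})
        assert got == pytest.approx(0.7 * 0.8 + 0.3 * 0.6, abs=1e-9)

    def test_change_relu_dead_zone(self, rng):
        s = random_structure(rng, 12, n_chains=2)
        p_cplx = _pred(s, np.full(12, 90.0), np.zeros((12, 12)))
        mono = s.subset(range(6))
        p_mono = _pred(mono, np.full(6, 90.0), np.zeros((6, 6)))
        # identical X conformation: L_TM = 1 > tm_max -> penalty active
        spec = FitnessSpec(task="change", tm_max=0.5)
        with_pen = composite_fitness(spec, {"complex": p_cplx, "monomer": p_mono})
        # tm_max = 1 -> ReLU dead zone, penalty exactly 0
        spec_free = FitnessSpec(task="change", tm_max=1.0)
        free = composite_fitness(spec_free, {"complex": p_cplx, "monomer": p_mono})
        assert free == pytest.approx(with_pen + 0.5, abs=1e-6)

    def test_missing_state_raises(self):
        spec = FitnessSpec(task="change")
        p = make_prediction_fixture(10)
        with pytest.raises(IncompleteTaskError):
            composite_fitness(spec, {"complex": p})

    def test_monotone_in_confidence_and_penalty(self, rng):
        # raise pLDDT -> fitness non-decreasing; raise pAE -> non-increasing
        def fit(plddt, pae_val):
            p = make_prediction_fixture(16, plddt=plddt, mean_pae=pae_val)
            return composite_fitness(FitnessSpec(task="denovo"), {"complex": p})

        base = fit(70.0, 10.0)
        assert fit(80.0, 10.0) >= base
        assert fit(70.0, 20.0) <= base


def test_every_table_term_reachable():
    """Coverage: each published fitness component maps to one operation."""
    from foldforge import fitness as F

    mapping = {
        "L_pAE": F.confidence_terms, "L_pLDDT": F.confidence_terms,
        "L_conf": F.confidence_terms, "L_ipAE": F.ipae_term,
        "L_bind": F.composite_fitness, "L_TM": F.approx_tm_term,
        "L_site": F.site_distance_penalty, "L_R": F.radius_penalty,
        "L_denovo": F.composite_fitness, "L_change": F.composite_fitness,
        "L_binder": F.composite_fitness,
    }
    assert all(callable(op) for op in mapping.values())
    assert len(mapping) == 11
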