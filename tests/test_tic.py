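"""Colony-screen statistics: preprocessing arithmetic, normalisation,
effect ratios, the Welch test against a textbook-formula oracle, and the
simulator round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foldforge.tic import (
    EmptyPlateError,
    N_COLS,
    N_ROWS,
    Plate,
    ScreenDesign,
    analyze_screen,
    blocker_effect,
    frame_to_plates,
    normalize_fitness,
    plates_to_frame,
    preprocess_plate,
    simulate_screen,
    welch_ttest,
)


def textbook_welch(a, b):
    """Independent Welch implementation from the printed formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def _flat_plate(value=100.0, condition="none", bio_rep=1):
    opacity = np.full((N_ROWS, N_COLS), value)
    strain = np.empty((N_ROWS, N_COLS), dtype=object)
    strain[:] = "blocker_001"
    # 32 GFP controls: 16 units x 2 technical replicates
    lib = np.ones((N_ROWS, N_COLS), dtype=int)
    tech = np.ones((N_ROWS, N_COLS), dtype=int)
    k = 0
    for unit in range(1, 17):
        for t in (1, 2):
            r, c = divmod(k, N_COLS)
            strain[r + 4, c] = f"GFP_{unit:02d}"
            lib[r + 4, c] = 0
            tech[r + 4, c] = t
            k += 1
    return Plate(opacity, strain, lib, tech, condition, bio_rep)


class TestPreprocess:
    def test_edge_correction_arithmetic(self):
        p = _flat_plate(100.0)
        p.opacity[p.edge] = 125.0
        p.opacity[0, 0] = 150.0
        out = preprocess_plate(p)
        # 150 x (median interior 100 / median edge 125) = 120
        assert out.opacity[0, 0] == pytest.approx(120.0)

    def test_no_edge_bias_no_change(self):
        p = _flat_plate(100.0)
        out = preprocess_plate(p)
        np.testing.assert_allclose(out.opacity, 100.0)

    def test_zero_opacity_marked_missing(self):
        p = _flat_plate(100.0)
        p.opacity[5, 5] = 0.0
        out = preprocess_plate(p)
        assert out.missing[5, 5]

    def test_all_zero_plate_raises(self):
        p = _flat_plate(0.0)
        with pytest.raises(EmptyPlateError):
            preprocess_plate(p)


class TestNormalize:
    def test_gfp_mean_normalisation(self):
        p = _flat_plate(1000.0)
        strain_mask = p.strain == "blocker_001"
        p.opacity[strain_mask] = 1200.0
        fit = normalize_fitness(p)
        blocker = fit[fit.strain == "blocker_001"]["fitness"].iloc[0]
        assert blocker == pytest.approx(1.2)

    def test_gfp_self_normalisation(self):
        p = _flat_plate(800.0)
        fit = normalize_fitness(p)
        gfp = fit[fit.strain.str.startswith("GFP")]["fitness"]
        assert gfp.mean() == pytest.approx(1.0)

    def test_technical_replicates_averaged(self):
        p = _flat_plate(1000.0)
        # give the two tech replicates of GFP_01 fitness 1.2 and 1.4
        pos = [(r, c) for r in range(N_ROWS) for c in range(N_COLS)
               if p.strain[r, c] == "GFP_01"]
        gfp_mask = np.char.startswith(p.strain.astype(str), "GFP")
        base = p.opacity[gfp_mask].mean()
        p.opacity[pos[0]] = 1.2 * base
        p.opacity[pos[1]] = 1.4 * base
        mean_gfp = p.opacity[gfp_mask].mean()
        fit = normalize_fitness(p)
        got = fit[fit.strain == "GFP_01"]["fitness"].iloc[0]
        expected = (1.2 * base / mean_gfp + 1.4 * base / mean_gfp) / 2
        assert got == pytest.approx(expected)


class TestEffects:
    def test_ratio_arithmetic(self):
        fitness = pd.DataFrame(
            [
                ("b1", 1, 1, "both", 0.9),
                ("b1", 1, 1, "ara", 0.3),
            ],
            columns=["strain", "lib_rep", "bio_rep", "condition", "fitness"],
        )
        eff = blocker_effect(fitness)
        assert eff["effect"].iloc[0] == pytest.approx(3.0)

    def test_identical_conditions_neutral(self):
        fitness = pd.DataFrame(
            [("b1", 1, 1, "both", 0.5), ("b1", 1, 1, "ara", 0.5)],
            columns=["strain", "lib_rep", "bio_rep", "condition", "fitness"],
        )
        assert blocker_effect(fitness)["effect"].iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        fitness = pd.DataFrame(
            [("b1", 1, 1, "both", 0.5), ("b1", 1, 1, "ara", 0.0)],
            columns=["strain", "lib_rep", "bio_rep", "condition", "fitness"],
        )
        eff = blocker_effect(fitness)
        assert eff["undefined"].iloc[0]


class TestWelch:
    def test_matches_textbook_formula(self, rng):
        for _ in range(1000):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=int(rng.integers(3, 20)))
            b = rng.normal(0, 1, size=int(rng.integers(3, 20)))
            t1, p1 = welch_ttest(a, b)
            t2, p2 = textbook_welch(a, b)
            assert t1 == pytest.approx(t2, abs=1e-10)
            assert p1 == pytest.approx(p2, abs=1e-10)

    def test_degenerate_tie(self):
        t, p = welch_ttest([1.0, 1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)
        t, p = welch_ttest([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0


class TestSimulatorAndPipeline:
    def test_null_identity_not_a_hit(self):
        design = ScreenDesign(n_blockers=12)
        plates, _ = simulate_screen(design, seed=1)
        res = analyze_screen(plates)
        assert len(res) == 12
        # effect sizes hover near 1 under the null
        assert res["effect_size"].mean() == pytest.approx(1.0, abs=0.05)

    def test_planted_effect_recovered(self):
        design = ScreenDesign(
            n_blockers=12, planted_effects=(("blocker_001", 1.5),)
        )
        plates, truth = simulate_screen(design, seed=2)
        res = analyze_screen(plates)
        row = res[res.strain == "blocker_001"].iloc[0]
        assert row["hit"]
        assert row["effect_size"] == pytest.approx(1.5, abs=0.15)

    def test_effect_size_unbiased(self):
        estimates = []
        for seed in range(30):
            design = ScreenDesign(
                n_blockers=8, planted_effects=(("blocker_001", 1.5),)
            )
            plates, _ = simulate_screen(design, seed=seed)
            res = analyze_screen(plates)
            estimates.append(
                res[res.strain == "blocker_001"]["effect_size"].iloc[0]
            )
        assert np.mean(estimates) == pytest.approx(1.5, abs=0.05)

    def test_small_effect_below_cutoff_not_hit(self):
        # printed cutoff semantics: significant but small effects are not hits
        design = ScreenDesign(
            n_blockers=12, planted_effects=(("blocker_001", 1.05),),
            noise_sigma=0.005,
        )
        plates, _ = simulate_screen(design, seed=3)
        res = analyze_screen(plates, effect_cutoff=1.1)
        row = res[res.strain == "blocker_001"].iloc[0]
        assert row["p_value"] < 0.01 and not row["hit"]

    def test_leaky_and_toxic_flags(self):
        design = ScreenDesign(
            n_blockers=12,
            planted_effects=(("blocker_001", 1.5), ("blocker_002", 1.0)),
            leaky=frozenset({"blocker_001"}),
            toxic=frozenset({"blocker_002"}),
        )
        plates, _ = simulate_screen(design, seed=4)
        res = analyze_screen(plates).set_index("strain")
        assert res.loc["blocker_001", "leaky"]
        assert res.loc["blocker_002", "toxic"]
        assert not res.loc["blocker_003", "leaky"]
        assert not res.loc["blocker_003", "toxic"]

    def test_edge_correction_closes_gap(self):
        design = ScreenDesign(n_blockers=12, edge_factor=1.25, miss_rate=0.0)
        plates, _ = simulate_screen(design, seed=5)
        p = preprocess_plate(plates[0])
        edge = np.median(p.opacity[p.edge & ~p.missing])
        interior = np.median(p.opacity[~p.edge & ~p.missing])
        assert edge / interior == pytest.approx(1.0, abs=0.01)

    def test_whole_plate_scale_invariance(self):
        design = ScreenDesign(
            n_blockers=12, planted_effects=(("blocker_001", 1.5),)
        )
        plates, _ = simulate_screen(design, seed=6)
        res1 = analyze_screen(plates)
        rng = np.random.default_rng(0)
        scaled = [
            Plate(p.opacity * rng.uniform(0.5, 5.0), p.strain, p.lib_rep,
                  p.tech_rep, p.condition, p.bio_rep)
            for p in plates
        ]
        res2 = analyze_screen(scaled)
        pd.testing.assert_frame_equal(res1, res2, rtol=1e-9)

    def test_csv_round_trip(self, tmp_path):
        design = ScreenDesign(n_blockers=6)
        plates, _ = simulate_screen(design, seed=7)
        df = plates_to_frame(plates)
        path = tmp_path / "screen.csv"
        df.to_csv(path, index=False)
        back = frame_to_plates(pd.read_csv(path))
        assert len(back) == len(plates)
        np.testing.assert_allclose(back[0].opacity, plates[0].opacity)
        assert back[3].condition == plates[3].condition
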