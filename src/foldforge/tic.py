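"""Toxin-inhibition-conjugation (TIC) colony-screen statistics.

A blocker library is arrayed as 384-colony plates (16 x 24) under four
induction conditions (none, arabinose = toxin only, IPTG = blocker only,
both), across plate-level biological replicates.  One array carries two
library (biological) replicates x two technical replicates of each
blocker plus 32 GFP control colonies (16 control units x 2 technical).

Analysis: zero-opacity colonies are pinning misses; outer-edge colonies
are multiplicatively corrected to the interior median; opacities are
normalised per plate by the mean of the GFP controls; technical
replicates are averaged; each blocker's effect is the ratio of its
normalised fitness under double induction to toxin-only induction; hits
are called by a two-sided Welch's t-test against the pooled GFP effects
plus an effect-size cutoff.  A seeded plate simulator with planted
effects provides ground truth for end-to-end testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_ROWS, N_COLS = 16, 24
CONDITIONS = ("none", "ara", "iptg", "both")


class EmptyPlateError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class Plate:
    """One 384-position colony-opacity array with layout metadata."""

    opacity: np.ndarray            # (16, 24) float, >= 0
    strain: np.ndarray             # (16, 24) str labels; GFP_* are controls
    lib_rep: np.ndarray            # (16, 24) int library biological replicate
    tech_rep: np.ndarray           # (16, 24) int technical replicate
    condition: str                 # none | ara | iptg | both
    bio_rep: int                   # plate-level biological replicate
    missing: np.ndarray = None     # (16, 24) bool

    def __post_init__(self) -> None:
        self.opacity = np.asarray(self.opacity, dtype=float)
        if self.opacity.shape != (N_ROWS, N_COLS):
            raise ValueError(f"plate grid must be {N_ROWS}x{N_COLS}")
        if np.any(self.opacity < 0):
            raise ValueError("opacities must be >= 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.missing is None:
            self.missing = np.zeros((N_ROWS, N_COLS), dtype=bool)

    @property
    def edge(self) -> np.ndarray:
        e = np.zeros((N_ROWS, N_COLS), dtype=bool)
        e[0, :] = e[-1, :] = True
        e[:, 0] = e[:, -1] = True
        return e

    @property
    def n_gfp(self) -> int:
        return int(np.sum(np.char.startswith(self.strain.astype(str), "GFP")))


def preprocess_plate(p: Plate) -> Plate:
    """Mark pinning misses and correct the outer-edge opacity bias.

    Zero-opacity colonies are flagged missing.  Edge colonies are scaled
    by median(interior) / median(edge) so the two medians agree.
    """
    missing = p.missing | (p.opacity == 0)
    if missing.all():
        raise EmptyPlateError("all positions missing")
    opacity = p.opacity.copy()
    edge = p.edge
    interior_vals = opacity[~edge & ~missing]
    edge_vals = opacity[edge & ~missing]
    if interior_vals.size and edge_vals.size:
        factor = np.median(interior_vals) / np.median(edge_vals)
        opacity[edge & ~missing] *= factor
    return Plate(
        opacity, p.strain, p.lib_rep, p.tech_rep, p.condition, p.bio_rep,
        missing=missing,
    )


def normalize_fitness(p: Plate) -> pd.DataFrame:
    """Per-strain normalised fitness on one plate.

    Each colony's opacity is divided by the plate's mean GFP-control
    opacity, then technical replicates of each (strain, library replicate)
    are averaged.  Returns columns: strain, lib_rep, condition, bio_rep,
    fitness.
    """
    strain = p.strain.astype(str)
    is_gfp = np.char.startswith(strain, "GFP")
    gfp_vals = p.opacity[is_gfp & ~p.missing]
    if gfp_vals.size == 0:
        raise NormalizationError("no valid GFP controls on plate")
    norm = p.opacity / gfp_vals.mean()
    rows = []
    for r in range(N_ROWS):
        for c in range(N_COLS):
            if p.missing[r, c]:
                continue
            rows.append(
                (strain[r, c], int(p.lib_rep[r, c]), int(p.tech_rep[r, c]),
                 norm[r, c])
            )
    df = pd.DataFrame(rows, columns=["strain", "lib_rep", "tech_rep", "fitness"])
    out = (
        df.groupby(["strain", "lib_rep"], as_index=False)["fitness"].mean()
    )
    out["condition"] = p.condition
    out["bio_rep"] = p.bio_rep
    return out


def blocker_effect(fitness: pd.DataFrame) -> pd.DataFrame:
    """Effect = fitness(both inducers) / fitness(toxin only), per replicate.

    Computed for every (strain, lib_rep, bio_rep) with both conditions
    present; a zero or missing denominator leaves the effect undefined
    (dropped with an ``undefined`` flag).
    """
    wide = fitness.pivot_table(
        index=["strain", "lib_rep", "bio_rep"], columns="condition",
        values="fitness", aggfunc="mean",
    )
    rows = []
    for (strain, lib_rep, bio_rep), row in wide.iterrows():
        both = row.get("both", np.nan)
        ara = row.get("ara", np.nan)
        undefined = not np.isfinite(both) or not np.isfinite(ara) or ara == 0
        rows.append(
            (strain, lib_rep, bio_rep,
             np.nan if undefined else both / ara, undefined)
        )
    return pd.DataFrame(
        rows, columns=["strain", "lib_rep", "bio_rep", "effect", "undefined"]
    )


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch's unequal-variance t-test; degenerate-safe.

    When both samples have zero variance the test is an exact tie: p = 1
    if the means agree, p = 0 otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test needs >= 2 values per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _gfp_null_effects(effects: pd.DataFrame) -> np.ndarray:
    """GFP control effects averaged over plate biological replicates."""
    gfp = effects[effects["strain"].str.startswith("GFP") & ~effects["undefined"]]
    pooled = gfp.groupby(["strain", "lib_rep"])["effect"].mean()
    return pooled.to_numpy()


def test_blockers(
    effects: pd.DataFrame,
    fitness: pd.DataFrame,
    effect_cutoff: float = 1.1,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Hit/leaky/toxic calls for every blocker.

    hit: Welch p < p_cutoff against the GFP effects and effect size
    (mean blocker effect / mean GFP effect) strictly above the cutoff.
    leaky: toxin-only fitness above mean + 2 SD of GFP in that condition.
    toxic: blocker-only fitness below mean - 2 SD of GFP in that condition.
    """
    gfp_eff = _gfp_null_effects(effects)
    if gfp_eff.size < 2:
        raise NormalizationError("need >= 2 GFP effect values")
    gfp_mean_eff = gfp_eff.mean()

    def gfp_band(condition: str) -> tuple[float, float]:
        vals = fitness[
            fitness["strain"].str.startswith("GFP")
            & (fitness["condition"] == condition)
        ]["fitness"].to_numpy()
        return vals.mean(), vals.std(ddof=1)

    ara_mean, ara_sd = gfp_band("ara")
    iptg_mean, iptg_sd = gfp_band("iptg")

    results = []
    blockers = sorted(
        s for s in effects["strain"].unique()
        if not s.startswith("GFP") and s != "filler"
    )
    for strain in blockers:
        vals = effects[(effects["strain"] == strain) & ~effects["undefined"]][
            "effect"
        ].to_numpy()
        if vals.size < 2:
            continue
        t, p = welch_ttest(vals, gfp_eff)
        effect_size = vals.mean() / gfp_mean_eff
        f_ara = fitness[
            (fitness["strain"] == strain) & (fitness["condition"] == "ara")
        ]["fitness"].mean()
        f_iptg = fitness[
            (fitness["strain"] == strain) & (fitness["condition"] == "iptg")
        ]["fitness"].mean()
        results.append(
            {
                "strain": strain,
                "n_effects": int(vals.size),
                "mean_effect": vals.mean(),
                "effect_size": effect_size,
                "t_stat": t,
                "p_value": p,
                "hit": bool(p < p_cutoff and effect_size > effect_cutoff),
                "leaky": bool(f_ara > ara_mean + 2 * ara_sd),
                "toxic": bool(f_iptg < iptg_mean - 2 * iptg_sd),
            }
        )
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# Synthetic screen simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenDesign:
    """Layout and generative parameters of a synthetic TIC screen.

    Defaults mirror the screen's replicate structure: 88 blockers x 2
    library x 2 technical replicates + 16 GFP units x 2 technical = 384
    positions; 4 conditions x 3 plate-level biological replicates; mild
    log-normal opacity noise, inflated edges, and occasional pinning
    misses.
    """

    n_blockers: int = 88
    gfp_units: int = 16
    lib_reps: int = 2
    tech_reps: int = 2
    bio_reps: int = 3
    planted_effects: tuple[tuple[str, float], ...] = ()
    leaky: frozenset[str] = frozenset()
    toxic: frozenset[str] = frozenset()
    toxin_suppression: float = 0.3
    noise_sigma: float = 0.1
    edge_factor: float = 1.25
    miss_rate: float = 0.005
    base_opacity: float = 1000.0

    def __post_init__(self) -> None:
        if self.noise_sigma <= 0:
            raise ValueError("noise sigma must be positive")
        slots = (
            self.n_blockers * self.lib_reps * self.tech_reps
            + self.gfp_units * self.tech_reps
        )
        if slots > N_ROWS * N_COLS:
            raise ValueError("layout exceeds 384 positions")

    def blocker_names(self) -> list[str]:
        return [f"blocker_{i + 1:03d}" for i in range(self.n_blockers)]

    def effect_of(self, strain: str) -> float:
        return dict(self.planted_effects).get(strain, 1.0)


def simulate_screen(
    design: ScreenDesign, seed: int = 0
) -> tuple[list[Plate], pd.DataFrame]:
    """Generate all condition x biological-replicate plates plus truth.

    Opacities are log-normal around condition-dependent means: the toxin
    suppresses growth under arabinose, planted blockers multiply the
    double-induction fitness by their effect, leaky blockers rescue the
    toxin-only condition, toxic blockers impair blocker-only growth.
    The colony layout is randomised once per screen and shared by every
    plate.
    """
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, int, int]] = []  # (strain, lib_rep, tech_rep)
    for strain in design.blocker_names():
        for lib in range(1, design.lib_reps + 1):
            for tech in range(1, design.tech_reps + 1):
                entries.append((strain, lib, tech))
    for unit in range(1, design.gfp_units + 1):
        for tech in range(1, design.tech_reps + 1):
            entries.append((f"GFP_{unit:02d}", 0, tech))
    while len(entries) < N_ROWS * N_COLS:
        entries.append(("filler", 0, 1))
    order = rng.permutation(len(entries))

    strain_grid = np.empty((N_ROWS, N_COLS), dtype=object)
    lib_grid = np.zeros((N_ROWS, N_COLS), dtype=int)
    tech_grid = np.zeros((N_ROWS, N_COLS), dtype=int)
    for flat, k in enumerate(order):
        r, c = divmod(flat, N_COLS)
        strain_grid[r, c], lib_grid[r, c], tech_grid[r, c] = entries[k]

    def mean_multiplier(strain: str, condition: str) -> float:
        is_control = strain.startswith("GFP") or strain == "filler"
        leaky = strain in design.leaky
        toxic = strain in design.toxic
        effect = 1.0 if is_control else design.effect_of(strain)
        if condition == "none":
            return 1.0
        if condition == "iptg":
            return design.toxin_suppression if toxic else 1.0
        if condition == "ara":
            return 1.0 if leaky else design.toxin_suppression
        m = design.toxin_suppression * effect
        if toxic:
            m *= design.toxin_suppression
        return min(m, 1.2)

    plates = []
    edge = Plate(
        np.ones((N_ROWS, N_COLS)), strain_grid, lib_grid, tech_grid, "none", 1
    ).edge
    for bio in range(1, design.bio_reps + 1):
        for condition in CONDITIONS:
            mult = np.empty((N_ROWS, N_COLS))
            for r in range(N_ROWS):
                for c in range(N_COLS):
                    mult[r, c] = mean_multiplier(strain_grid[r, c], condition)
            noise = np.exp(rng.normal(0.0, design.noise_sigma, (N_ROWS, N_COLS)))
            opacity = design.base_opacity * mult * noise
            opacity[edge] *= design.edge_factor
            opacity[rng.random((N_ROWS, N_COLS)) < design.miss_rate] = 0.0
            plates.append(
                Plate(opacity, strain_grid.copy(), lib_grid.copy(),
                      tech_grid.copy(), condition, bio)
            )
    truth = pd.DataFrame(
        {
            "strain": design.blocker_names(),
            "effect": [design.effect_of(s) for s in design.blocker_names()],
            "leaky": [s in design.leaky for s in design.blocker_names()],
            "toxic": [s in design.toxic for s in design.blocker_names()],
        }
    )
    return plates, truth


def analyze_screen(
    plates: Sequence[Plate],
    effect_cutoff: float = 1.1,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Full pipeline: preprocess, normalise, effects, Welch tests."""
    fitness = pd.concat(
        [normalize_fitness(preprocess_plate(p)) for p in plates],
        ignore_index=True,
    )
    effects = blocker_effect(fitness)
    return test_blockers(effects, fitness, effect_cutoff, p_cutoff)


# ---------------------------------------------------------------------------
# Long-format CSV interchange (Iris-style)
# ---------------------------------------------------------------------------

_CSV_COLS = ["plate", "row", "col", "strain", "condition", "bio_rep",
             "lib_rep", "tech_rep", "opacity"]


def plates_to_frame(plates: Sequence[Plate]) -> pd.DataFrame:
    rows = []
    for k, p in enumerate(plates):
        for r in range(N_ROWS):
            for c in range(N_COLS):
                rows.append(
                    (k, r, c, str(p.strain[r, c]), p.condition, p.bio_rep,
                     int(p.lib_rep[r, c]), int(p.tech_rep[r, c]),
                     p.opacity[r, c])
                )
    return pd.DataFrame(rows, columns=_CSV_COLS)


def frame_to_plates(df: pd.DataFrame) -> list[Plate]:
    plates = []
    for _, group in df.groupby("plate", sort=True):
        opacity = np.zeros((N_ROWS, N_COLS))
        strain = np.empty((N_ROWS, N_COLS), dtype=object)
        lib = np.zeros((N_ROWS, N_COLS), dtype=int)
        tech = np.zeros((N_ROWS, N_COLS), dtype=int)
        for _, row in group.iterrows():
            r, c = int(row["row"]), int(row["col"])
            opacity[r, c] = row["opacity"]
            strain[r, c] = row["strain"]
            lib[r, c] = int(row["lib_rep"])
            tech[r, c] = int(row["tech_rep"])
        plates.append(
            Plate(opacity, strain, lib, tech,
                  str(group["condition"].iloc[0]), int(group["bio_rep"].iloc[0]))
        )
    return plates
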