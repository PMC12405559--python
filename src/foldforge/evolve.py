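"""Evolutionary sequence search against a structure-predictor oracle.

An elitist (mu + lambda) scheme in the greedy-with-exploration family:
a pool of sequences is kept, parents are drawn from the fitness band
within ``suboptimality`` of the current best, children are point mutants,
and survivors are the top ``population_size`` of parents plus children.
Every oracle evaluation is cached, and the whole run is a deterministic
function of (config, seed, oracle seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .fitness import FitnessSpec, composite_fitness
from .oracle import OracleRequest, Template
from .structcore import AA19_NO_CYS, ChainedSequence, Prediction

Chains = tuple[str, ...]
#: evaluate(chains) -> (fitness, prediction states)
Evaluator = Callable[[Chains], tuple[float, Mapping[str, Prediction]]]


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EvolveConfig:
    """Hyperparameters of the design loop.

    ``population_size`` 10 and ``suboptimality`` 0.1 are the published
    operating point for binder design; cysteine is excluded from the
    default alphabet because it interferes with soluble expression.
    """

    population_size: int = 10
    suboptimality: float = 0.1
    mutation_rate: float = 1.0
    alphabet: str = AA19_NO_CYS
    fitness_threshold: float = float("inf")
    max_evaluations: int = 10_000
    children_per_step: int = 10
    recycle_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise InvalidConfigError("population_size must be >= 1")
        if not 0.0 <= self.suboptimality <= 1.0:
            raise InvalidConfigError("suboptimality must lie in [0, 1]")
        if self.mutation_rate <= 0:
            raise InvalidConfigError("mutation_rate must be positive")
        if not self.alphabet:
            raise InvalidConfigError("empty alphabet")


@dataclass
class Member:
    chains: Chains
    fitness: float | None = None
    parent: Chains | None = None
    generation: int = 0


@dataclass
class PoolState:
    """The evolving population plus its evaluation cache and RNG streams."""

    members: list[Member]
    generation: int = 0
    n_evaluations: int = 0
    best: Member | None = None
    eval_cache: dict[Chains, float] = field(default_factory=dict)
    payloads: dict[Chains, Mapping[str, Prediction]] = field(default_factory=dict)
    rng_mutation: np.random.Generator = None
    rng_selection: np.random.Generator = None

    @property
    def best_fitness(self) -> float:
        return -np.inf if self.best is None else self.best.fitness


def init_pool(cfg: EvolveConfig, lengths: int | Sequence[int]) -> PoolState:
    """Seed the pool with i.i.d. uniform sequences over the alphabet."""
    if isinstance(lengths, int):
        lengths = (lengths,)
    if any(l < 1 for l in lengths):
        raise InvalidConfigError("chain lengths must be >= 1")
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_mut, rng_sel = (np.random.default_rng(s) for s in ss.spawn(3))
    letters = np.array(list(cfg.alphabet))
    members = []
    for _ in range(cfg.population_size):
        chains = tuple(
            "".join(rng_init.choice(letters, size=l)) for l in lengths
        )
        members.append(Member(chains=chains))
    state = PoolState(members=members)
    state.rng_mutation = rng_mut
    state.rng_selection = rng_sel
    return state


def _eligible_parents(state: PoolState, cfg: EvolveConfig) -> list[Member]:
    scored = [m for m in state.members if m.fitness is not None]
    if not scored:
        return list(state.members)
    best = max(m.fitness for m in scored)
    floor = best - cfg.suboptimality * abs(best)
    return [m for m in scored if m.fitness >= floor]


def _mutate(chains: Chains, cfg: EvolveConfig, rng: np.random.Generator) -> Chains:
    concat = list("".join(chains))
    n = len(concat)
    k = 0
    while k == 0:  # Poisson(rate) conditioned on >= 1 substitution
        k = rng.poisson(cfg.mutation_rate)
    k = min(k, n)
    positions = rng.choice(n, size=k, replace=False)
    for pos in positions:
        options = [a for a in cfg.alphabet if a != concat[pos]]
        concat[pos] = options[rng.integers(len(options))]
    out, start = [], 0
    for chain in chains:
        out.append("".join(concat[start : start + len(chain)]))
        start += len(chain)
    return tuple(out)


def propose_children(state: PoolState, cfg: EvolveConfig) -> list[Member]:
    """Point mutants of parents drawn from the suboptimality band."""
    parents = _eligible_parents(state, cfg)
    rng = state.rng_mutation
    children = []
    for _ in range(cfg.children_per_step):
        parent = parents[state.rng_selection.integers(len(parents))]
        children.append(
            Member(
                chains=_mutate(parent.chains, cfg, rng),
                parent=parent.chains,
                generation=state.generation + 1,
            )
        )
    return children


def _evaluate_members(
    members: list[Member], state: PoolState, cfg: EvolveConfig, evaluate: Evaluator
) -> None:
    for m in members:
        if m.fitness is not None:
            continue
        if m.chains in state.eval_cache:
            m.fitness = state.eval_cache[m.chains]
            continue
        if state.n_evaluations >= cfg.max_evaluations:
            m.fitness = -np.inf
            continue
        fit, payload = evaluate(m.chains)
        state.eval_cache[m.chains] = fit
        state.payloads[m.chains] = payload
        state.n_evaluations += 1
        m.fitness = fit


def step(state: PoolState, cfg: EvolveConfig, evaluate: Evaluator) -> PoolState:
    """One generation: evaluate, propose, evaluate children, select."""
    _evaluate_members(state.members, state, cfg, evaluate)
    children = propose_children(state, cfg)
    _evaluate_members(children, state, cfg, evaluate)
    merged: dict[Chains, Member] = {}
    for m in state.members + children:  # dedupe, keep first (elitist parents)
        if m.chains not in merged:
            merged[m.chains] = m
    survivors = sorted(
        merged.values(), key=lambda m: (-(m.fitness), m.generation)
    )[: cfg.population_size]
    while len(survivors) < cfg.population_size:
        survivors.append(survivors[0])
    state.members = survivors
    state.generation += 1
    top = survivors[0]
    if state.best is None or top.fitness > state.best.fitness:
        state.best = replace(top)
    return state


@dataclass
class DesignCandidate:
    """A sequence whose fitness cleared the design threshold."""

    chains: Chains
    fitness: float
    predictions: Mapping[str, Prediction]

    @property
    def raw_structure(self):
        return self.predictions["complex"].structure


@dataclass
class RunResult:
    candidates: list[DesignCandidate]
    status: str  # "success" | "budget_exhausted"
    pool: PoolState
    trace: list[dict]
    manifest: dict


def make_evaluator(
    oracle,
    spec: FitnessSpec,
    designed_ids: Sequence[str] = ("A",),
    fixed: Sequence[tuple[str, str]] = (),
    templates: Sequence[tuple[str, Template]] = (),
    recycle_count: int = 2,
) -> Evaluator:
    """Bind an oracle and a fitness spec into an ``evaluate`` callable.

    Designed chains come first, fixed (target) chains after, so the EA
    mutates only the designed part.  For conformational-change tasks the
    designed chains are additionally predicted alone as the monomer state.
    """
    designed_ids = tuple(designed_ids)
    fixed = tuple(fixed)
    templates = tuple(templates)
    ids = designed_ids + tuple(cid for cid, _ in fixed)

    def evaluate(chains: Chains):
        all_chains = tuple(chains) + tuple(seq for _, seq in fixed)
        cs = ChainedSequence(all_chains, ids)
        pred = oracle.predict(
            OracleRequest(cs, templates=templates, recycle_count=recycle_count)
        )
        preds = {"complex": pred}
        if spec.task == "change":
            mono = ChainedSequence(tuple(chains), designed_ids)
            preds["monomer"] = oracle.predict(
                OracleRequest(mono, recycle_count=recycle_count)
            )
        return composite_fitness(spec, preds, ids), preds

    return evaluate


def run_design(
    cfg: EvolveConfig,
    lengths: int | Sequence[int],
    oracle=None,
    spec: FitnessSpec | None = None,
    evaluate: Evaluator | None = None,
    max_steps: int = 100_000,
    **evaluator_kwargs,
) -> RunResult:
    """Run the design loop until the fitness threshold or the budget.

    Returns every pool member at or above the threshold, each with its
    raw prediction, plus a manifest (config + seed + trace) sufficient to
    re-run the search bit-identically.
    """
    if evaluate is None:
        if oracle is None or spec is None:
            raise InvalidConfigError("need either evaluate or (oracle, spec)")
        evaluate = make_evaluator(
            oracle, spec, recycle_count=cfg.recycle_count, **evaluator_kwargs
        )
    state = init_pool(cfg, lengths)
    trace: list[dict] = []

    def winners() -> list[DesignCandidate]:
        seen, out = set(), []
        for m in state.members:
            if m.fitness is None or m.fitness < cfg.fitness_threshold:
                continue
            if m.chains in seen:
                continue
            seen.add(m.chains)
            out.append(
                DesignCandidate(m.chains, m.fitness, state.payloads[m.chains])
            )
        return out

    # initial evaluation round, so a vacuous threshold returns immediately
    _evaluate_members(state.members, state, cfg, evaluate)
    state.best = max(state.members, key=lambda m: m.fitness)
    for step_i in range(max_steps):
        trace.append(
            {
                "generation": state.generation,
                "best_fitness": state.best_fitness,
                "n_evaluations": state.n_evaluations,
            }
        )
        if state.best_fitness >= cfg.fitness_threshold:
            break
        if state.n_evaluations >= cfg.max_evaluations:
            break
        step(state, cfg, evaluate)

    cands = winners()
    status = "success" if cands else "budget_exhausted"
    manifest = {
        "config": {
            k: getattr(cfg, k)
            for k in (
                "population_size", "suboptimality", "mutation_rate", "alphabet",
                "fitness_threshold", "max_evaluations", "children_per_step",
                "recycle_count", "seed",
            )
        },
        "lengths": list(lengths) if not isinstance(lengths, int) else [lengths],
        "n_evaluations": state.n_evaluations,
        "generations": state.generation,
        "status": status,
        "best_fitness": state.best_fitness,
    }
    return RunResult(cands, status, state, trace, manifest)
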