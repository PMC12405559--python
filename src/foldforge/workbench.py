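"""Supporting engineering: fixtures, run manifests and the staged pipeline.

Every pipeline stage (design -> redesign -> validate) is a function over
a plain config mapping; each writes its artifacts plus a JSON manifest
recording the config snapshot, seeds, software version and SHA-256
digests of every output, so deterministic stages can be re-run and
checked bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codon import codon_optimize
from .evolve import EvolveConfig, run_design
from .fitness import FitnessSpec
from .oracle import ORACLES
from .redesign import (
    RedesignConstraints,
    redesign_batch,
    reference_profile_model,
)
from .structcore import ChainedSequence, Structure
from .structio import write_fasta, write_pdb
from .tic import ScreenDesign, plates_to_frame, simulate_screen
from .validate import (
    SuccessCriteria,
    classify_success,
    filter_cascade,
    select_best,
    self_consistency,
)

# idealised helix trace parameters shared with the synthetic folder
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)


def ideal_helix(length: int, offset: float = 0.0) -> Structure:
    """An ideal alpha-helix CA trace with synthetic backbone atoms."""
    i = np.arange(length)
    theta = i * _HELIX_TURN
    ca = np.stack(
        [
            _HELIX_RADIUS * np.cos(theta) + offset,
            _HELIX_RADIUS * np.sin(theta),
            _HELIX_RISE * i,
        ],
        axis=1,
    )
    bb = np.empty((length, 4, 3))
    bb[:, 1] = ca
    bb[:, 0] = ca + np.array([-0.5, 1.3, 0.0])
    bb[:, 2] = ca + np.array([1.4, 0.4, 0.3])
    bb[:, 3] = ca + np.array([2.0, -0.6, 0.5])
    return Structure(bb, ((0, length),))


def analytic_helix_rg(length: int) -> float:
    """Closed-form radius of gyration of the ideal helix CA trace.

    The z spread of an arithmetic progression has variance
    rise^2 (n^2 - 1)/12; the xy circle contributes close to radius^2 once
    the turns average out.
    """
    z_var = _HELIX_RISE**2 * (length**2 - 1) / 12.0
    return float(np.sqrt(_HELIX_RADIUS**2 + z_var))


def make_prediction_fixture(
    length: int, plddt: float = 80.0, mean_pae: float = 10.0,
    ptm: float = 0.8, pae_max: float = 31.75, n_chains: int = 1,
):
    """A Prediction with prescribed constant confidence values."""
    from .structcore import Prediction

    per = length // n_chains
    intervals = tuple((k * per, (k + 1) * per) for k in range(n_chains))
    intervals = intervals[:-1] + ((intervals[-1][0], length),)
    helix = ideal_helix(length)
    structure = Structure(helix.backbone, intervals)
    return Prediction(
        structure,
        np.full(length, plddt),
        np.full((length, length), mean_pae),
        ptm,
        pae_max=pae_max,
    )


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a stage and check its outputs."""

    stage: str
    config: dict
    seeds: dict
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    timing_s: float = 0.0
    extra: dict = field(default_factory=dict)

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=str))
        return path


def _digest_outputs(out_dir: Path, names: list[str]) -> dict:
    return {n: sha256_file(Path(out_dir) / n) for n in names}


def _build_oracle(cfg: dict):
    ocfg = dict(cfg.get("oracle", {}))
    name = ocfg.pop("name", "synthetic")
    return ORACLES[name](**ocfg)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def run_design_stage(cfg: dict, out_dir: Path) -> dict:
    """Evolutionary candidate generation; writes FASTA/PDB/trace/manifest."""
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dcfg = dict(cfg.get("design", {}))
    length = dcfg.pop("length", 30)
    task = dcfg.pop("task", "denovo")
    seed = int(cfg.get("seed", 0))
    evolve_cfg = EvolveConfig(seed=seed, **dcfg)
    oracle = _build_oracle(cfg)
    spec = FitnessSpec(task=task)
    result = run_design(evolve_cfg, length, oracle=oracle, spec=spec)

    cands = sorted(result.candidates, key=lambda c: -c.fitness)
    top = cands[: cfg.get("max_candidates", 3)]
    seqs = {}
    outputs = []
    for k, cand in enumerate(top):
        name = f"candidate_{k}"
        cs = ChainedSequence(cand.chains)
        seqs[name] = cs
        write_pdb(out_dir / f"{name}.pdb", cand.raw_structure, cs)
        outputs.append(f"{name}.pdb")
    write_fasta(out_dir / "candidates.fasta", seqs)
    pd.DataFrame(result.trace).to_csv(out_dir / "trace.csv", index=False)
    outputs += ["candidates.fasta", "trace.csv"]
    manifest = RunManifest(
        stage="design",
        config=cfg,
        seeds={"run": seed, "oracle": cfg.get("oracle", {}).get("seed", 0)},
        output_digests=_digest_outputs(out_dir, outputs),
        timing_s=time.perf_counter() - t0,
        extra=result.manifest,
    )
    manifest.write(out_dir)
    return {"result": result, "candidates": top, "manifest": manifest}


def run_redesign_stage(cfg: dict, out_dir: Path, candidates) -> dict:
    """Sequence redesign per candidate; writes ranked FASTA + manifest."""
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rcfg = dict(cfg.get("redesign", {}))
    n_samples = rcfg.get("n_samples", 100)
    inv_temp = rcfg.get("inv_temperature", 10.0)
    model_name = rcfg.get("model", "oracle_consistent")
    seed = int(cfg.get("seed", 0))
    oracle = _build_oracle(cfg)
    constraints = RedesignConstraints(
        forbidden=frozenset(rcfg.get("forbidden", "C"))
    )
    records = []
    for k, cand in enumerate(candidates):
        structure = cand.raw_structure
        if model_name == "oracle_consistent":
            model = oracle.consistent_sequence_model()
        else:
            model = reference_profile_model(structure)
        ranked = redesign_batch(
            model, structure, n_samples=n_samples, constraints=constraints,
            inv_temperature=inv_temp, seed=seed + k,
        )
        for rank, r in enumerate(ranked):
            records.append(
                {"candidate": k, "rank": rank, "sequence": r.sequence,
                 "likelihood": r.likelihood}
            )
    df = pd.DataFrame(records)
    df.to_csv(out_dir / "redesigns.csv", index=False)
    seqs = {
        f"cand{row.candidate}_rank{row.rank}|lik={row.likelihood:.4f}":
            ChainedSequence((row.sequence,))
        for row in df.itertuples() if row.rank == 0
    }
    write_fasta(out_dir / "redesigned.fasta", seqs)
    manifest = RunManifest(
        stage="redesign",
        config=cfg,
        seeds={"run": seed},
        output_digests=_digest_outputs(out_dir, ["redesigns.csv", "redesigned.fasta"]),
        timing_s=time.perf_counter() - t0,
    )
    manifest.write(out_dir)
    return {"table": df, "manifest": manifest}


def run_validate_stage(cfg: dict, out_dir: Path, candidates, redesigns: pd.DataFrame) -> dict:
    """Self-consistency benchmark, selection, cascade and codon output."""
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcfg = dict(cfg.get("validate", {}))
    recycle_count = vcfg.get("recycle_count", 4)
    oracle = _build_oracle(cfg)
    model = oracle.consistent_sequence_model()
    crit = SuccessCriteria()
    rows, selected = [], {}
    for k, cand in enumerate(candidates):
        raw = cand.raw_structure
        sub = redesigns[redesigns["candidate"] == k]
        recs = []
        for row in sub.itertuples():
            cs = ChainedSequence((row.sequence,))
            for rec in self_consistency(
                raw, cs, {"synthetic": oracle},
                design_id=f"cand{k}_rank{row.rank}",
                recycle_count=recycle_count,
            ):
                flags = classify_success(rec, crit)
                decision = filter_cascade(
                    row.likelihood, rec.mean_plddt / 100.0, rec.ptm
                )
                rows.append(
                    {"design_id": rec.design_id, "candidate": k,
                     "sequence": row.sequence, "scrmsd": rec.scrmsd,
                     "sctm": rec.sctm, "mean_plddt": rec.mean_plddt,
                     "ptm": rec.ptm, "lax": flags["lax"],
                     "cascade_keep": decision.keep,
                     "cascade_reasons": ";".join(decision.reasons)}
                )
                recs.append((rec, row.sequence))
        if recs:
            chosen, _ = select_best([r for r, _ in recs], crit, tier="lax")
            if chosen is not None:
                seq = next(s for r, s in recs if r.design_id == chosen.design_id)
                selected[chosen.design_id] = ChainedSequence((seq,))
    bench = pd.DataFrame(rows)
    bench.to_csv(out_dir / "benchmark.csv", index=False)
    write_fasta(out_dir / "selected.fasta", selected)
    dna = {
        f"{name}_dna": ChainedSequence(
            (codon_optimize(cs.concatenated, seed=int(cfg.get("seed", 0))),),
            alphabet=frozenset("ACGT"),
        )
        for name, cs in selected.items()
    }
    write_fasta(out_dir / "selected_dna.fasta", dna)
    manifest = RunManifest(
        stage="validate",
        config=cfg,
        seeds={"run": int(cfg.get("seed", 0))},
        output_digests=_digest_outputs(
            out_dir, ["benchmark.csv", "selected.fasta", "selected_dna.fasta"]
        ),
        timing_s=time.perf_counter() - t0,
        extra={"n_selected": len(selected)},
    )
    manifest.write(out_dir)
    return {"benchmark": bench, "selected": selected, "manifest": manifest}


def run_pipeline(cfg: dict, out_dir: Path) -> dict:
    """design -> redesign -> validate on one config; returns a summary."""
    out_dir = Path(out_dir)
    design = run_design_stage(cfg, out_dir / "design")
    redesign = run_redesign_stage(cfg, out_dir / "redesign", design["candidates"])
    validate = run_validate_stage(
        cfg, out_dir / "validate", design["candidates"], redesign["table"]
    )
    summary = {
        "n_candidates": len(design["candidates"]),
        "n_selected": len(validate["selected"]),
        "n_lax_pass": int(validate["benchmark"]["lax"].sum())
        if len(validate["benchmark"])
        else 0,
        "digests": {
            "design": design["manifest"].output_digests,
            "redesign": redesign["manifest"].output_digests,
            "validate": validate["manifest"].output_digests,
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_fixtures(kind: str, seed: int = 0, out_dir: Path = Path("fixtures")) -> list[Path]:
    """Generate deterministic on-disk fixtures for a given kind."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "toy-monomer":
        length = 30
        structure = ideal_helix(length)
        seq = ChainedSequence(("A" * length,))
        write_pdb(out_dir / "monomer.pdb", structure, seq)
        write_fasta(out_dir / "monomer.fasta", {"monomer": seq})
        written += [out_dir / "monomer.pdb", out_dir / "monomer.fasta"]
    elif kind == "toy-complex":
        a, b = ideal_helix(20), ideal_helix(15, offset=8.0)
        bb = np.concatenate([a.backbone, b.backbone])
        structure = Structure(bb, ((0, 20), (20, 35)))
        seq = ChainedSequence(("A" * 20, "G" * 15))
        write_pdb(out_dir / "complex.pdb", structure, seq)
        write_fasta(out_dir / "complex.fasta", {"complex": seq})
        written += [out_dir / "complex.pdb", out_dir / "complex.fasta"]
    elif kind == "tic-screen":
        design = ScreenDesign(
            planted_effects=(("blocker_001", 1.5), ("blocker_002", 2.0)),
        )
        plates, truth = simulate_screen(design, seed=seed)
        plates_to_frame(plates).to_csv(out_dir / "screen.csv", index=False)
        truth.to_csv(out_dir / "truth.csv", index=False)
        written += [out_dir / "screen.csv", out_dir / "truth.csv"]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
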