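"""Constraint-based reverse translation for E. coli expression.

Codons are drawn toward the host usage table while excluding rare codons
(relative family usage below 10% by default), keeping global GC within
35-65%, and avoiding tandem pentanucleotide repeats and hairpin-forming
complementary stems (>= 10 nt within a 60 nt window).  A seeded repair
loop resamples codons overlapping any violation until all constraints
hold or a bounded retry budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

_CODE = CodonTable.unambiguous_dna_by_id[1]

#: E. coli K-12 relative codon usage within each amino-acid family.
ECOLI_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16},
    "R": {"CGC": 0.40, "CGT": 0.38, "CGG": 0.10, "CGA": 0.06, "AGA": 0.04, "AGG": 0.02},
    "N": {"AAC": 0.55, "AAT": 0.45},
    "D": {"GAT": 0.63, "GAC": 0.37},
    "C": {"TGC": 0.55, "TGT": 0.45},
    "Q": {"CAG": 0.65, "CAA": 0.35},
    "E": {"GAA": 0.68, "GAG": 0.32},
    "G": {"GGC": 0.40, "GGT": 0.34, "GGG": 0.15, "GGA": 0.11},
    "H": {"CAT": 0.57, "CAC": 0.43},
    "I": {"ATT": 0.51, "ATC": 0.42, "ATA": 0.07},
    "L": {"CTG": 0.50, "TTA": 0.13, "TTG": 0.13, "CTC": 0.10, "CTT": 0.10, "CTA": 0.04},
    "K": {"AAA": 0.76, "AAG": 0.24},
    "M": {"ATG": 1.0},
    "F": {"TTT": 0.57, "TTC": 0.43},
    "P": {"CCG": 0.52, "CCA": 0.19, "CCT": 0.16, "CCC": 0.13},
    "S": {"AGC": 0.28, "TCT": 0.15, "TCC": 0.15, "TCG": 0.15, "AGT": 0.15, "TCA": 0.12},
    "T": {"ACC": 0.44, "ACG": 0.27, "ACT": 0.17, "ACA": 0.13},
    "W": {"TGG": 1.0},
    "Y": {"TAT": 0.57, "TAC": 0.43},
    "V": {"GTG": 0.37, "GTT": 0.26, "GTC": 0.22, "GTA": 0.15},
}


class ConstraintFailureError(RuntimeError):
    """Constraints could not be satisfied within the retry budget."""

    def __init__(self, violations: list[str]):
        super().__init__(f"unsatisfied constraints: {violations}")
        self.violations = violations


def gc_content(dna: str) -> float:
    return sum(c in "GC" for c in dna) / len(dna)


def find_tandem_pentamer(dna: str) -> int | None:
    """First index where a 5-mer is immediately repeated, else None."""
    for i in range(len(dna) - 9):
        if dna[i : i + 5] == dna[i + 5 : i + 10]:
            return i
    return None


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def find_hairpin(dna: str, stem: int = 10, window: int = 60) -> tuple[int, int] | None:
    """First reverse-complement stem pair within the window, else None."""
    n = len(dna)
    for i in range(n - stem + 1):
        jmax = min(i + window, n - stem)
        for j in range(i + stem, jmax + 1):
            if dna[j : j + stem] == _revcomp(dna[i : i + stem]):
                return i, j
    return None


@dataclass(frozen=True)
class CodonConstraints:
    gc_min: float = 0.35
    gc_max: float = 0.65
    rare_threshold: float = 0.10
    hairpin_stem: int = 10
    hairpin_window: int = 60


def _allowed_codons(
    usage: dict[str, dict[str, float]], rare_threshold: float
) -> dict[str, list[tuple[str, float]]]:
    out = {}
    for aa, table in usage.items():
        kept = [(c, f) for c, f in table.items() if f >= rare_threshold]
        if not kept:  # never empty a family
            best = max(table.items(), key=lambda cf: cf[1])
            kept = [best]
        total = sum(f for _, f in kept)
        out[aa] = [(c, f / total) for c, f in kept]
    return out


def codon_optimize(
    protein: str,
    usage: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    constraints: CodonConstraints = CodonConstraints(),
    max_rounds: int = 400,
) -> str:
    """Reverse-translate a protein into constraint-satisfying DNA.

    The output always translates back exactly to the input protein;
    determinism is guaranteed given (sequence, seed).
    """
    usage = usage or ECOLI_USAGE
    bad = set(protein) - set(usage)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    allowed = _allowed_codons(usage, constraints.rare_threshold)
    rng = np.random.default_rng(seed)

    def draw(aa: str, prefer_gc: int = 0) -> str:
        options = allowed[aa]
        if prefer_gc:
            scored = sorted(
                options, key=lambda cf: prefer_gc * gc_content(cf[0]), reverse=True
            )
            return scored[0][0]
        codons = [c for c, _ in options]
        probs = np.array([f for _, f in options])
        return codons[rng.choice(len(codons), p=probs)]

    codons = [draw(aa) for aa in protein]

    for _ in range(max_rounds):
        dna = "".join(codons)
        gc = gc_content(dna)
        if gc < constraints.gc_min or gc > constraints.gc_max:
            pos = int(rng.integers(len(codons)))
            codons[pos] = draw(protein[pos], prefer_gc=1 if gc < constraints.gc_min else -1)
            continue
        rep = find_tandem_pentamer(dna)
        if rep is not None:
            pos = min(rep // 3 + int(rng.integers(4)), len(codons) - 1)
            codons[pos] = draw(protein[pos])
            continue
        hp = find_hairpin(dna, constraints.hairpin_stem, constraints.hairpin_window)
        if hp is not None:
            stem_start = hp[int(rng.integers(2))]
            pos = min(
                stem_start // 3
                + int(rng.integers(constraints.hairpin_stem // 3 + 1)),
                len(codons) - 1,
            )
            codons[pos] = draw(protein[pos])
            continue
        return dna

    dna = "".join(codons)
    violations = []
    if not constraints.gc_min <= gc_content(dna) <= constraints.gc_max:
        violations.append("gc_content")
    if find_tandem_pentamer(dna) is not None:
        violations.append("tandem_pentamer")
    if find_hairpin(dna, constraints.hairpin_stem, constraints.hairpin_window):
        violations.append("hairpin")
    raise ConstraintFailureError(violations)


def translate(dna: str) -> str:
    return str(Seq(dna).translate(table=1))
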