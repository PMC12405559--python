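# Methods

## The design problem

`foldforge` treats protein design as hallucination: search sequence space
for inputs that a structure predictor folds with high confidence, using
the predictor purely as a black-box oracle.  The oracle returns, for any
(multi-chain) amino-acid sequence, backbone coordinates, a per-residue
pLDDT vector (0–100), a residue-pair predicted-aligned-error (pAE)
matrix in ångströms bounded by `pae_max`, and a global pTM scalar.
Confidence terms and geometric constraints are composed into a scalar
fitness; an evolutionary algorithm maximises it; a structure-conditioned
sequence model then redesigns each candidate backbone; re-prediction of
the redesigned sequences closes the self-consistency loop.

## Fitness algebra

With pLDDT normalised to [0, 1] and pAE normalised by `pae_max`
(default 31.75 Å, the conventional predictor bin ceiling):

- `L_pAE(X) = 1 − mean(pAE over X×X)/pae_max`
- `L_pLDDT(X) = mean(pLDDT over X)/100`
- `L_conf = (L_pAE + L_pLDDT)/2`
- `L_ipAE(X,Y) = 1 − mean(pAE over both off-diagonal blocks)/pae_max`
- `L_TM(X,X′) = max_j mean_i f(AE_ij)`, `f(d) = 1/(1 + d/d0)`,
  `d0 = 1.24·(max(L,19) − 15)^{1/3} − 1.8` (floored at 0.5 Å)
- `L_site = max(r, min CA–CA distance binder→site) − r` (r = 6 Å default)
- `L_R = (max(R, R_g) − R)/R`, with `R = 2.2·N^0.38 Å` unless set

Composites (`α = 0.7` for de novo and binder tasks):

```
L_denovo = 2(α·L_conf(X¹:…:X^N) + (1−α)·mean_i L_conf(X^i)) − L_R
L_bind   = α·L_ipAE(X,T) + (1−α)·L_conf(X)
L_change = α·L_conf(X:Y) + (1−α)·L_conf(X) − ReLU(L_TM − TM_max)
L_binder = L_bind(α=0.7) − L_site(r=6 Å) − L_R
```

pLDDT is divided by 100 before entering `L_conf`: mixing a 0–100 score
additively with a [0, 1] score would let pLDDT swamp the pAE term, and
normalisation is the only reading that keeps `L_conf` in [0, 1].

`AE_ij` between two conformations of the same chain is defined by
expressing residue *i*'s CA in the local backbone frame (N, CA, C
Gram–Schmidt) of residue *j* in each structure and taking the distance
between the two local positions.  This generalises the predicted-aligned
-error geometry to a pair of realised structures; it reduces to the
predictor's own pTM construction when one structure is the prediction
target.  An alternative reading (distance-matrix difference) exists but
is not frame-local; the frame-local form is the default and only
implementation.  `f(d)` is implemented exactly in its linear printed
form, with `f_squared=True` switching to the canonical
`1/(1+(d/d0)²)` weight.

## Geometry primitives

Superposition is least-squares with a proper rotation (det = +1)
enforced — mirror images must not superpose to zero because chirality
is physical.  Two points suffice for a well-defined minimal RMSD (used
by a closed-form test); a single point is rejected.  `tm_score` uses the
standard `d0(L)` normalisation and the identity residue mapping (equal
lengths are required; there is no alignment search), maximising the
score by iterative re-superposition on the subset of residues inside
the inclusion cutoff.  scRMSD defaults to CA atoms — the field
convention for design self-consistency — with the atom set overridable.
Ensemble RMSF aligns snapshots to the running mean in two passes before
measuring per-residue fluctuation.  Contacts count residue pairs with
any heavy-atom pair within 4 Å (sequence-non-adjacent within a chain,
or cross-chain for interfaces).

## The synthetic oracle

`SyntheticFolder` makes the whole pipeline runnable with no neural
network while preserving the contracts design code depends on:

- every residue type gets a fixed "fold propensity" in [0, 1] — a seeded
  permutation of an evenly spaced grid, so exactly one residue attains
  1.0 and landscapes differ across oracle seeds;
- pLDDT is 100 × the window-5 mean propensity, sharpened slightly by
  recycling (fixed points 0 and 1 are preserved, so the perfect extreme
  stays exact);
- pAE(i, j) grows with sequence separation and shrinks with
  min(pLDDT_i, pLDDT_j), bounded by `pae_max`, zero on the diagonal;
- coordinates follow an idealised α-helix trace perturbed by seeded coil
  noise whose amplitude is `5 Å × (1 − pLDDT/100)`, so confident
  sequences re-fold reproducibly and unconfident ones do not;
- templates pin the submitted coordinates exactly and floor the pinned
  residues' pLDDT at 90;
- pTM is computed from the pAE matrix with the standard transform.

Every output is a pure function of (sequence, templates, recycle count,
oracle seed); requests are cached on a canonical key and the cache-hit
counter is part of the contract.  The landscape is smooth (window
averaging bounds the fitness change of any single substitution) and
admits hill-climbing, which is what makes it a non-degenerate test bed
for the evolutionary loop.  What it does *not* emulate: epistasis,
realistic secondary-structure diversity, adversarial high-confidence
artefacts, or any correlation between burial and residue identity —
passing tests therefore demonstrate the machinery, not transferability
of any particular design to real predictors.

## Evolutionary loop

Elitist (μ+λ) with a greedy-with-exploration parent rule: parents are
drawn uniformly from members whose fitness is within
`suboptimality × |best|` of the current best (the fitness-band reading
of suboptimality); children are point mutants with a Poisson(mutation
rate) substitution count conditioned on ≥ 1; survivors are the top
`population_size` of parents plus children.  Defaults: population 10,
suboptimality 0.1, mutation rate 1, cysteine excluded from the design
alphabet (it interferes with soluble expression), 2 recycling steps
during design and 4 during validation.  One RNG stream per run is split
into init/mutation/selection sub-streams, so runs are bit-reproducible
given (config, seed, oracle seed).  Recombination is off by default; the
selection skeleton is pinned by the published hyperparameters and the
cited algorithm family, everything else is explicit config.

## Redesign sampler

Starting from a fully masked sequence (frozen regions — e.g. a binder
target — keep their residues), the sampler repeats: pick a masked
position uniformly at random, query the model's categorical
distribution there (recomputed after every commit — fully
autoregressive), zero forbidden residues, renormalise, raise to the
inverse temperature β = 10 and renormalise (`p^β`; identical to logit
scaling), sample, and write the residue to the position and all tied
positions (homooligomer/repeat constraints).  Batches of 100 are
de-duplicated and ranked by one-shot mean log-likelihood (nats/residue);
chain-rule path scoring is available separately.  Ties break by sample
order for reproducibility.

Two built-in models implement the `SequenceModel` contract:

- `ReferenceProfileModel`: a deterministic structure-conditioned profile
  from backbone features — burial (CA neighbour count within 10 Å)
  pushes positions toward hydrophobic residues, exposure toward
  polar/charged ones, local curvature adds a mild helix-former
  preference; smoothed to full support and invariant under rigid motion.
- the oracle's `consistent_sequence_model()`: distributions proportional
  to `exp(sharpness × propensity)`.  The full pipeline uses this one by
  default because the burial-based profile cannot know a synthetic
  landscape's arbitrary propensity map; with a real predictor and a
  trained inverse-folding model the two roles coincide and either plugs
  into the same interface.

## Validation and selection

Re-prediction uses 4 recycling iterations; binder tasks supply the
target template and initialise recycling with the designed complex.
Success tiers use strict inequalities exactly as printed — lax:
pLDDT > 70 and scRMSD < 2 Å; strict: pLDDT > 80, scRMSD < 1 Å and
ipAE < 10 Å — so boundary values fail.  Multi-state records combine by
conjunction (every state must pass), the conservative reading.
Selection filters to passing records and takes minimum scRMSD, with
deterministic tie-breaks.  The candidate cascade drops a design if its
mean log-likelihood is below −0.1 nats/residue, then if
pLDDT × pTM < 0.5 (pLDDT on the [0, 1] scale — a 0–100 scale would make
the threshold vacuous), then, when a solubility score is supplied by an
external predictor hook, if it is below 1; a missing solubility score
is recorded as "not evaluated", never as a pass or fail.

## Codon optimisation

Reverse translation draws codons from an inline E. coli K-12 usage
table, excluding rare codons (relative family usage < 10%), then runs a
seeded repair loop until global GC lies in [35%, 65%], no 5-mer is
immediately repeated, and no reverse-complement stem of ≥ 10 nt occurs
within a 60 nt window (the hairpin proxy; stem and window are config).
Outputs always translate back exactly; an unsatisfiable constraint set
raises with the violated constraints listed after a bounded number of
repair rounds.

## Colony-screen statistics

One 384-colony array (16 × 24) carries 88 blockers × 2 library
(biological) × 2 technical replicates plus 16 GFP control units × 2
technical replicates (32 control colonies); four induction conditions
(none, toxin-only, blocker-only, both) × 3 plate-level biological
replicates.  Zero-opacity colonies are pinning misses; outer-edge
colonies are multiplicatively corrected to the interior median (a single
per-plate factor from the two medians); every colony is normalised by
the plate's mean GFP opacity, and technical replicates are averaged
(n = 12 fitness values per blocker).  A blocker's effect is the ratio of
its normalised fitness under double induction to toxin-only induction
(n = 6 per blocker); the GFP null sample is the 16 control-unit effects
averaged over plate replicates.  Hits require a two-sided Welch test
p < 0.01 against the GFP effects *and* effect size (mean blocker effect
/ mean GFP effect) strictly above the cutoff (1.1 default).  Leaky:
toxin-only fitness above the GFP mean + 2 SD in that condition; toxic:
blocker-only fitness below the GFP mean − 2 SD.  Degenerate-variance
ties return p = 1 when means agree.

The simulator draws opacities log-normal (σ = 0.1 default) around
condition-dependent means: the toxin suppresses growth to 0.3×, planted
blockers multiply double-induction fitness by their effect, leaky
blockers rescue the toxin-only condition, toxic blockers impair
blocker-only growth; edges are inflated 1.25× and a small fraction of
colonies are misses.  It does not emulate spatial gradients beyond the
edge ring, plate-to-plate batch effects, or colony-size/opacity
nonlinearity — calibration results on it bound the statistics, not the
assay.

## Problem sizes and numerical choices

Test and acceptance workloads use 20–30-residue designs, 200-step /
2,000-evaluation searches, 10,000-draw sampler calibrations and
50-screen Monte-Carlo studies — sizes chosen so the whole suite runs in
about a minute on one core while keeping every statistical check
well-powered.  Tolerances: exact arithmetic claims at 1e-9, geometry
against the rotation-grid oracle at 1e-3 Å, rigid-motion invariance at
1e-6, Welch against the textbook formula at 1e-10.  Degenerate inputs
(empty selections, single snapshots, all-zero plates, all-forbidden
positions) raise typed errors rather than returning silent values.

## Known limitations

- The synthetic landscape is separable up to window smoothing; search
  performance on it says nothing about epistatic real landscapes.
- `tm_score`'s iterative superposition is a heuristic for the
  score-maximising superposition; it is exact for identical structures
  and monotone under noise, but is not a certified global optimum.
- The hairpin constraint is a reverse-complement stem proxy, not a
  thermodynamic folding model.
- Real-predictor adapters (external processes) are an optional plugin
  namespace; nothing in the test suite requires them.
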