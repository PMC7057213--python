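# Methods

## Overview

The package studies one mechanism: encoding per-residue coordinate-error
estimates of a protein model into its B-factor column and measuring the
resulting change in a molecular-replacement-style log-likelihood gain (LLG).
Everything else — synthetic structures, decoys, emulated predictors, a
simplified likelihood — exists to make that mechanism measurable on a
desktop, end to end, with known ground truth.

## Local quality transform

S(d) = 1/(1 + (d/d₀)²), d₀ = 3.0 Å. The scale parameter is the
half-quality point: S(d₀) = 1/2, and the transform is most sensitive near
d₀. The inverse d(S) = d₀√(1/S − 1) is capped at 15 Å; qualities below
1/(1+(15/3)²) ≈ 0.0385 all collapse onto the cap, which is intentional — a
predictor reporting "worse than 15 Å" carries no further positional
information. Global model quality is the unweighted mean of the per-residue
S values, keeping the score in (0, 1] independent of chain length. In
float64 the inverse pair is exact to 1e-9 for d ≥ 1e-6 Å; below ~1e-7 Å
the only representable S is 1.0 and the round trip returns 0.

## Error → B-factor policy

B = 8π²⟨u²⟩ with the per-residue error d treated as a total isotropic RMS
displacement, ⟨u²⟩ = d²/3, hence B = 8π²d²/3. This is the standard
Debye–Waller convention; it is a pluggable policy (any callable d → B) since
likelihood programs differ in the exact convention. B values are kept
numeric in memory (d = 15 Å gives B ≈ 5922 Å², beyond the PDB field);
clamping to 999.99 happens only when writing fixed-column files, with a
logged warning, so file output never silently changes in-memory results.
The B column is interpreted as absolute smearing, not an increment over
existing B factors.

## Structures and I/O

CA-level chains, one atom per residue, index-matched between model and
target (the synthetic generator produces 1:1 correspondences, so no
alignment machinery exists). PDB ATOM records are read and written with the
fixed-column subset this needs; parse errors name the offending line.
Multi-chain bookkeeping, mmCIF, altlocs and anisotropic B are out of scope.

## Superposition and quality metrics

Kabsch least-squares superposition via SVD, optionally weighted, rejecting
reflections (det = +1) and degenerate (collinear/coincident) inputs. The
"true" per-residue error of a decoy is the CA–CA distance after one global
unweighted superposition — deliberately a single fit, matching how
predicted-vs-actual error curves are drawn.

GDT_TS approximates the full LGA search deterministically: superpositions
are seeded from every contiguous window of lengths 4, 8, 16 and the whole
chain; for each of the 1/2/4/8 Å thresholds, each seed is refined by
refitting on the residues currently under the threshold until a fixed point
(≤ 10 rounds); each seed contributes the larger of its initial-fit fraction
and its converged fraction, and the score is the mean over thresholds of the
per-threshold maxima. Transient mid-iteration fractions are discarded: they
can transiently "capture" single residues sitting exactly on a threshold
boundary, which no stable superposition supports. Ties between seeds
resolve to first-encountered order, so the value is reproducible. Against
implementations of the full LGA search, differences of a few hundredths are
expected.

## Synthetic data

`make_target` grows a self-avoiding CA trace with bond length 3.8 ± 0.04 Å,
minimum non-consecutive separation 3.5 Å, and a centroid pull (coefficient
1.4, engaged outside 0.9 of the target radius) calibrated so the radius of
gyration tracks the globular scaling 2.2·n^0.38 Å within 30%.

`make_decoy` adds a displacement field: i.i.d. Gaussian 3-vectors smoothed
along the chain with a 5-residue triangular kernel, then rescaled per
segment so each segment's realized RMS displacement equals its class value
(core 0.5 Å, loop 2.5 Å, unreliable 6.0 Å by default). Smoothing makes
errors spatially correlated — whole loops go bad together — which is what
makes B-factor smearing productive; white noise would not resemble homology
-model error. Random segment layouts (55% core / 30% loop / 15% unreliable
stretches of 4–30 residues) give the default ensemble a GDT_TS spread with
median ≈ 0.9 and tail to ≈ 0.7.

`emulate_predictor` degrades true errors multiplicatively:
d_pred = clamp(0.25, 15, d_true·exp(ε)), ε ~ N(0, σ_log²). The log-normal
form scales noise with error magnitude, mimicking real quality predictors'
compression of small errors; the 0.25 Å floor keeps predicted qualities
strictly below 1. Two presets ship: a noisier one (σ_log = 0.55) and a
tighter one (σ_log = 0.35), ordered to emulate an older predictor and its
deep-learning successor; they are calibrated to fidelity order only, not to
any specific program's accuracy.

What the generator does **not** emulate: side chains, alignment-shift error
modes (where a model is locally wrong by a sequence register, not a smooth
displacement), template-coverage truncation, and any dependence of predictor
noise on structural context. Passing benchmarks here therefore demonstrate
the smearing mechanism under spatially correlated, magnitude-proportional
error — not performance on real homology models.

## The LLG engine

P1 orthorhombic cell, unit point scatterers at CA positions, direct
summation F(h) = Σⱼ exp(−Bⱼs²/4)·exp(2πi h·x_frac,j) over the Friedel
half-sphere between d_min = 2.5 Å and d_max = 20 Å. "Observed" amplitudes
are |F| of the target with 5% multiplicative Gaussian noise by default;
model placement is assumed optimal (models are already superposed on their
targets), so no rotation/translation search exists.

sigmaA per resolution shell (6 shells of equal reflection counts, shells
under 5 reflections merged) is the Pearson correlation of the
shell-normalized amplitudes E_obs, E_calc, clamped to [0, 1]. The
correlation is computed on mean-centred amplitudes: amplitudes are strictly
positive, so an uncentred cosine similarity sits near 0.8 even for unrelated
structures and would make every imperfect model score below the random
baseline. The centred estimator is conservative — it underestimates the
true sigmaA of the complex-Gaussian model (numerically, r ≈ 0.79 at
sigmaA = 0.9) — which keeps the plug-in LLG non-negative in expectation and
leaves the comparative conclusions untouched.

The score is Σ_h [log Rice(E_obs | σ_A, E_calc) − log Wilson(E_obs)] with
the acentric Rice density and the Wilson baseline being its σ_A = 0 case,
so the per-reflection terms cancel exactly when σ_A = 0. Inside the
likelihood σ_A is additionally capped at 0.999 so a perfect model on
noise-free data gives a large finite LLG instead of a divergence; the
reported per-shell values are the uncapped estimates. I₀ is evaluated via
the exponentially scaled Bessel function to avoid overflow. No centric
reflections, no measurement-error term, no bulk solvent, no element form
factors: each omission strips a constant or a smooth scale the shell
normalization would largely absorb, while keeping the sigmaA-mediated route
by which smearing helps. Consequently absolute LLG values are on this
engine's own scale; only comparisons between models on the same data are
meaningful. The LLG > 50 success threshold is retained as the reporting
default with exactly that caveat, and is configurable.

## Benchmark

For each pair (default 50 pairs × 100 residues, sized to run in well under
a minute on one CPU): generate target and decoy, compute true and emulated
predicted error profiles, place both structures in a box from their joint
bounding box plus 10 Å padding per side, simulate observations, and score
llg_none / llg_pred / llg_true. Per-pair seeds derive from one master seed,
so runs are bit-reproducible. Percent LLG increase is reported under both
natural definitions — ratio of sums, 100·(Σm − Σb)/|Σb|, and mean of
per-pair percent changes over pairs with |baseline| > 1 — since they
answer different questions and diverge when baselines are small. Paired
comparisons use the exact two-sided sign test on discordant pairs (ties
dropped); ΔLLG = 0 counts as not improved.

## Numerical choices

- Reflection resolution limits use a 1e-9 relative tolerance so reflections
  exactly on a limit are included regardless of rounding.
- Kabsch degeneracy: second singular value below 1e-8 of the first raises a
  degenerate-geometry error in the public API; the GDT seed search instead
  accepts any minimizer, since collinear windows occur legitimately.
- Sign test p-values come from the exact binomial distribution
  (min(1, 2·tail)); no normal approximation at these ensemble sizes.
- The self-avoiding walk backtracks 5 residues after 120 failed extension
  attempts and aborts with a seed-change suggestion after 40·n failures.

## Known limitations

Absolute LLG magnitudes are not comparable to crystallographic software;
the synthetic error model omits register-shift and coverage effects; GDT_TS
is a documented approximation, not the canonical LGA search; and the
benchmark's "predicted" errors inherit the truth's spatial structure by
construction, so predictor realism is limited to fidelity (correlation with
truth), not error anatomy.
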