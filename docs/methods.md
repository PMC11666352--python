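# Methods

`taqdesign` implements one turn of a low-N, multi-objective enzyme-design
loop for Taq DNA polymerase variants: measured multiparametric properties of
a small mutant panel train per-property regression models on sequence
embeddings; the models screen a constrained combinatorial mutation space;
explicit thresholds select candidates. The package also includes the
sequencing-based fidelity estimator used to measure one of those properties,
and synthetic-data generators that reproduce the statistical structure the
loop relies on, so the whole pipeline is testable without external services.

## Variant representation and the constrained scan

A variant is an ordered, duplicate-free set of point substitutions on a
reference sequence, named in the conventional dash-joined form
(`E507Q-D578S-I614M`); `WT` denotes the empty variant. Positions use native
numbering throughout: constructs that omit N-terminal residues record a
`numbering_offset` and never shift coordinates. The packaged reference is
the 832-residue full-length Taq polymerase (UniProt P19821).

The in-silico scan enumerates all `19 L` single substitutions across the
reference plus all doubles and triples restricted to a set of combinatorial
sites (the campaign used 21 sites), capped at a trust radius of three
simultaneous substitutions — models trained on tens of points cannot be
trusted far from the wild type. The closed-form size is
`19 L + C(s,2)·19² + C(s,3)·19³`; for L = 832 and s = 21 this is 9,214,088
variants. Enumeration is streaming, deterministic (positions
lexicographically, then residues alphabetically), and resumable via an
integer cursor, so a screen can be checkpointed.

## Embeddings

Sequences are mapped to fixed-length vectors by mean-pooling per-residue
features over residue positions only (no boundary tokens). The backend is
pluggable. The default `mock` backend assigns each (residue identity,
position bucket, flanking 3-mer) context a deterministic pseudo-random
feature vector derived from a seed via a cryptographic hash; pooled vectors
are therefore mutation-sensitive and position-aware, a single substitution
perturbs at most three rows of the feature matrix, and nothing is
downloaded. The `external-plm` slot accepts any callable producing an
(L, dim) matrix, so a transformer protein language model can be dropped in
without touching downstream code; its absence is an error only when it is
actually requested. Defaults: dim 64, bucket size 16. Nothing downstream
assumes a particular dimension.

## Targets and censoring

Measured tables carry censoring explicitly: `N/A` cells are below the
detection limit and carry no value; `>40`-style cells carry only the printed
bound. Censored cells are excluded from regression fit sets by default (an
impute-at-bound reading is possible by using the stored bound directly); the
detection/bound semantics also drive the table-derived counts (a
below-detection ΔCq can never count as "better" for a lower-is-better
property, while an above-bound value is compared at its bound).

Each property has a schema: transform (`log` for strictly positive,
right-skewed quantities — fidelity, K_d, rate ratios, catalytic constants,
LNA delays; identity for ΔCq differences and PCR efficiency), direction of
merit, and training role. Short-template RT activities (90/116 nt), the
relative rate constant, fidelity, PCR efficiency, the dT/dU rate, both
catalytic constants, and the two blocking scores train models; long-template
RT activities, K_d, and the LNA-3 delay are monitored only. Targets are
z-scaled after the transform; the fitted `TransformParams` invert the
mapping exactly, so predictive densities are reported on measurement scales.

Hot-start blocking levels are encoded as an ordinal loss score —
Strong → 0.0, Weak → 0.5, Absent → 1.0 — and regressed like any other
target; the selection rule "probability of no blocking ≤ 0.1" is evaluated
on the predicted score (mean mode) or as a posterior probability (chance
mode). The underlying probabilistic construction is a design choice of this
package; the score is monotone in the severity of blocking loss, which is
all the selection rule needs.

## Regression

**Ridge** (first round): penalized least squares on the intercept-augmented
embedding matrix with the intercept unpenalized. The penalty α is chosen on
a grid by leave-one-out cross-validation scored as MAPE on the original
measurement scale (MAPE on z-scored targets divides by near-zero values;
denominators are floored at 1e-6). LOO residuals use the exact
linear-smoother identity `e_i / (1 − h_ii)`, so the whole grid costs one
factorization per α rather than n refits; the identity is exact for any
fixed penalty matrix and is tested against explicit refits.

**Exact GP** (later rounds): zero-mean GP on centered targets with either a
Matérn kernel (ν ∈ {1.5, 2.5}; closed half-integer forms) or a
spectral-delta kernel, `k(x,x′) = (1/Q) Σ_q cos(2π ω_qᵀ(x−x′))` with
`k(x,x) = 1` — a valid stationary covariance because its spectral measure is
a symmetric mixture of point masses. The posterior is computed by Cholesky
factorization of `K + σ_n² I`, with jitter escalated 1e-8 → 1e-4 in decade
steps before failing. Hyperparameters (log lengthscale, log signal variance,
log noise for Matérn; the Q×d frequency matrix and log noise for
spectral-delta, frequencies initialized from seeded Gaussian draws scaled by
the median pairwise distance, Q default 16) maximize the log marginal
likelihood by bounded L-BFGS-B from a seeded start; fits are deterministic
given the seed, and the recorded objective trace is monotone. Defaults:
Matérn ν 2.5 for every property, noise variance initialized at 1e-2, 50
optimizer iterations. Each property is fitted independently.

Predictions are Gaussian on the modeling scale; original-scale summaries
invert the z-scaling and, for log targets, use the lognormal identities
(mean `exp(μ + σ²/2)`, median `exp(μ)`, quantiles `exp(μ ± z σ)`). Reported
predictive standard deviations include the observation noise.

## Model selection protocol

Because the design setting only ever provides small training sets (18 points
in round one, 33 in round two), models are compared by repeated random
subsampling: draw a small training set, fit, and score the held-out
remainder with Spearman rank correlation (ranking mutants matters more than
absolute accuracy) and Top-k hit rates for k ∈ {4, 8, 16, 24} — the fraction
of the k best-predicted variants whose *true* value beats the wild type,
which models the situation where only the top predictions get wet-lab
budget. Hit rates are reported as fractions (multiply by k for counts).
Prediction ties break by variant name so results are reproducible;
constant-input correlations are reported as NaN, never fabricated. Deep
mutational scanning tables (CSV with `mutant`/`score`, colon- or dash-joined
tokens) can be benchmarked through the same protocol.

## Screening and selection

The default candidate filter transcribes the campaign's criteria: catalytic
constants (dT and dU mixes) ≥ 20, PCR efficiency ≥ 1.85, dT/dU rate ≤ 1.5,
error rate ≤ 1/3,000 expressed as fidelity ≥ 3,000 nt/error, relative rate
constant ≥ 0.2 of the wild type, and blocking-loss scores ≤ 0.1. Thresholds
are closed (equality passes, matching "at least"/"not more than"). The
catalytic-constant threshold of 20 is applied to the property as tabulated
in s⁻¹; the source's "20 nM" unit is treated as a typo. Each rule runs in
mean mode (original-scale predictive mean vs threshold) or chance mode
(posterior probability of satisfying the constraint ≥ p_level, computed on
the modeling scale where the posterior is Gaussian); for symmetric
posteriors chance mode at p_level 0.5 coincides with mean mode.

Passing candidates are ranked on a chosen objective by predictive mean with
an optional uncertainty penalty λ·σ (λ = 0 by default; the campaign states
no ranking rule, so this is an explicit design choice of the package), with
a deterministic name tie-break. A design round (`run_design_round` or the
`round` CLI subcommand) chains load → embed → fit → enumerate → predict →
select → rank and writes a prediction TSV, a candidate report TSV, a FASTA
of selected variants, and a manifest with seeds and content digests; fixed
`%.6g` formatting makes reruns byte-identical.

## Fidelity estimation

Per-position base counts from amplicon sequencing give the pool substitution
frequency `f = N_alt / N_alt+ref`, summed over all positions outside primer
intervals (0-based half-open; overlaps mask their union). The per-nucleotide
per-cycle error rate is `p = E·f/n` with PCR efficiency E ∈ (1, 2] and n
amplification cycles; fidelity is reported as 1/p nt per error (infinite at
f = 0). Base calls are pre-filtered by quality — calls with Q ≥ 30 are
retained by default (the threshold is exposed; the conventional reading of a
Q filter). Indels are ignored: only substitutions count. The 12 directed
substitution types form the error spectrum with transition/transversion
totals. Replicates average f and p arithmetically and pool spectra before
renormalizing; replicates measured under different (E, n) are rejected.
Input is a plain per-position count TSV (or BED intervals for primers);
alignment-file parsing is deliberately out of scope so the module stays
dependency-light, and the reader contract is simple enough for an alignment
front-end to target.

## Synthetic data: what it emulates and what it does not

The landscape generator promotes the campaign's own mechanistic reading —
tighter substrate binding drives correlated shifts across properties — to a
generative model. A latent factor `b(v)` is additive over per-substitution
effects (a per-site base effect plus a per-residue deviation) with sparse
pairwise epistasis; every property is `intercept + loading·b` on its
transform scale plus Gaussian noise, back-transformed to its natural scale.
Loadings are sign-constrained to the observed trade-off pattern: RT ΔCq
co-varies positively with K_d, fidelity, dT/dU rate, and LNA delay, and
negatively with catalytic constants. Intercepts anchor at the wild type's
measured values (b = 0 is WT), so simulated ranges match the real panel
(ΔCq ≈ −2…18, K_d ≈ 0.5…200 nM) and the WT passes the continuous selection
thresholds, as it does in the real data. Long-template ΔCq censors to
below-detection beyond a limit, LNA delays censor to an upper bound, and
blocking levels come from a b-dependent ordinal model. An optional second
latent factor decouples fidelity to emulate exception mutants. Defaults: a
random 120-residue reference, 8 combinatorial sites with 6 alternative
residues each, variants of order 1–3 (30/40/30%), effect sd 0.55 per site.

What passing tests on this generator shows: the pipeline can recover an
additive-with-mild-epistasis landscape from 33 noisy, partially censored
measurements and enrich threshold-satisfying variants. What it does not
show: performance under real biophysics — strong higher-order epistasis,
property-specific nonlinearities, systematic assay errors, or embeddings
whose geometry diverges from the additive structure of the mock backend.

The sequencing simulator inverts the estimator's model: alt calls are
binomial with success probability `f = p·n/E` per position, split across the
three non-reference bases by transition/transversion weights (2:1 by
default), with primer positions emitted flagged. Defaults mirror the real
assay's scale: a 99-bp amplicon with two 20-bp primers, 30 cycles, E = 2,
coverage 1e5, true p = 3e-5.

`recovery_experiment` runs the loop end to end per seed: generate a
landscape (200 variants + WT), train a GP for the primary RT activity on a
33-point sample (the scale of the campaign's second-round dataset), score
held-out Spearman against the noise-free truth, and screen the held-out
variants with the default criteria, reporting the enrichment of
truly-passing variants among the selected set relative to random picking. A
shuffled-label control checks that the evaluation cannot manufacture signal.

## Numerical choices and degenerate inputs

- Cholesky jitter escalation 0 → 1e-8 … 1e-4, then a hard failure.
- L-BFGS-B bounds keep log-hyperparameters in numerically safe ranges; a
  non-finite marginal likelihood is treated as a large penalty, and the
  initial hyperparameters are kept if optimization does not improve on them.
- With `optimize=False` the requested noise (including exactly zero) is used
  verbatim, giving exact interpolation on well-conditioned toys.
- MAPE denominators floored at 1e-6; zero-variance or all-censored target
  columns are skipped by the round orchestrator (and are hard errors in the
  low-level preprocessing, where silently dropping them would be surprising).
- Ties: Top-k and candidate ranking break ties by name; Spearman uses
  average ranks.
- Problem sizes in the shipped tests and the acceptance script are desk
  scale by design — landscapes of 120–200 variants, GP training sets of 33,
  scans limited to a few hundred enumerated variants, 20-seed replications —
  chosen so a full verification run completes in minutes on one core while
  still exercising every code path at the campaign's actual training-set
  sizes.

## Known limitations

- The mock embedding backend shares no weights with any real protein
  language model; absolute performance numbers on synthetic landscapes do
  not transfer to real assay data.
- Ridge predictive output carries no uncertainty (σ = 0), so chance-mode
  selection degenerates to mean mode for ridge models.
- Censored measurements are excluded rather than modeled (no Tobit-style
  likelihood); heavily censored properties are therefore monitor-only by
  default.
- The GP is exact and dense: fitting is O(n³) and screening cost is linear
  in scan size with small constants, which is ample for tens of training
  points and millions of predictions, but no sparse approximations are
  provided.
- Blocking is modeled as an ordinal score under a Gaussian likelihood; a
  proper ordinal-regression treatment is out of scope.
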