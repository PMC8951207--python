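# Methods

`plinet` reimplements, as a tested library, a resting-state EEG
functional-network analysis with a metabolomics arm: phase-lag-index (PLI)
connectivity on the 20 canonical 10–20 electrodes, proportional-sparsity
binary graphs with four global graph metrics, band-wise group statistics
with FDR control and a permutation network-difference test, PLS-DA/VIP
metabolite screening, and rank correlation of metabolites and symptom
scores against network topology.  Because no public dataset accompanies the
original study design, every stage is validated against a synthetic-cohort
generator with analytic ground truth.  This note records the models, the
numerical choices, and what the synthetic validation does and does not
establish.

## Preprocessing

A continuous recording (channels × samples, µV) passes through, in order:
zero-phase FIR band-pass 0.5–45 Hz with a 50 Hz notch, a zero-phase FIR
narrowband filter for the analysis band, segmentation into non-overlapping
2 s epochs (trailing remainder dropped), average-reference re-referencing,
polyphase anti-aliased downsampling to 512 Hz, rejection of any epoch whose
absolute amplitude exceeds 80 µV on any channel, and a Hjorth
nearest-neighbour surface Laplacian (each channel minus the mean of its
montage neighbours).  Every `EpochSet` carries a provenance trail of these
steps, and the pipeline logs per-band subject attrition explicitly, so a
reduced analyzed-n is always visible in the outputs.

Filter design: linear-phase Hamming-window FIR, transition width 25 % of
the lower band edge floored at 0.4 Hz (the floor keeps kernels shorter than
short recordings; stop-band attenuation of the design is ≈ 53 dB).  Kernels
are applied by FFT convolution with reflection padding and exact
group-delay compensation (odd tap counts), so the phase of the filtered
signal — the quantity PLI depends on — is untouched.

Band edges are never unambiguous in clinical practice; the package uses the
standard seven-band split delta 0.5–4, theta 4–8, alpha-1 8–10, alpha-2
10–13, beta-1 13–20, beta-2 20–30, gamma 30–45 Hz, configurable in
`RunConfig`.  Artifact handling is amplitude rejection only: ICA-based
component removal is a visual, operator-dependent step with no reproducible
algorithmic specification, so it is deliberately out of scope.

## Phase lag index

Per epoch, the instantaneous phase of each channel is the angle of its
analytic (Hilbert) signal; 10 % of samples at each epoch edge are discarded
to suppress Hilbert end transients.  For channels *j, k*:

    PLI_jk = | ⟨ sign( sin( φ_j(t) − φ_k(t) ) ) ⟩_t |

with `sign(0)` contributing exactly 0.  The PLI measures the asymmetry of
the phase-difference distribution, so coupling at exactly zero (or π) lag —
the signature of volume conduction — is invisible to it.  Per-epoch PLI
values are averaged across retained epochs (1:1 phase locking only; the
general n:m case is out of scope).  Averaging per-epoch absolute means,
rather than concatenating epochs, matches common practice but has a
consequence worth stating: the estimator has a positive noise floor of
roughly `sqrt(2/(π·B·T))` for band-width *B* and epoch length *T* (≈ 0.15–0.2
for the beta bands at 2 s) that does **not** shrink with more epochs — only
its variance does.  All thresholding behaviour downstream lives on top of
this floor.

## Binary networks and graph metrics

Each subject × band PLI matrix is binarized by **proportional**
thresholding: at sparsity *S* the strongest `round(S·N(N−1)/2)` edges (N =
20, so `round(S·190)`, round-half-up) become edges, over the grid
S = 0.05, 0.06, …, 0.40 (36 levels).  Proportional thresholding was chosen
over an absolute cutoff because indexing networks by S requires fixed edge
counts; an absolute-threshold mode (`binarize_by_threshold`) is also
provided.  Ties at the cutoff break by lexicographic node-pair order, so
binarization is deterministic.

On each binary graph four global metrics are computed with hand-rolled
numpy routines (BFS hop counts): characteristic path length L_p (mean
shortest-path length over connected ordered pairs; graphs with unreachable
pairs are flagged *fragmented* and averaged over connected pairs only),
clustering coefficient C_c (mean of 2t_i/(k_i(k_i−1)), zero below degree
2), global efficiency E_global (mean of 1/d with 1/∞ = 0), and local
efficiency E_local (mean over nodes of the global efficiency of each
node's neighbour subgraph, zero below degree 2).  The test suite checks all
four against networkx on hundreds of random graphs to 1e−12, and the
acceptance script cross-checks against an independent in-script
Floyd–Warshall oracle.

A caveat that matters for interpretation: because L_p averages over
connected pairs only, a *more* fragmented graph can show a *shorter* L_p
(paths are measured inside small clumps).  The fragmentation flag is
carried through `TopologyCurve` precisely so users can condition on it.

## Group statistics

Per band × metric × sparsity, groups are compared with a pooled-variance
two-sided t test (df = n₁+n₂−2).  Benjamini–Hochberg adjustment is applied
within each band × metric family (the 36 sparsity levels) — the narrowest
defensible family; `fdr_family="all"` pools everything instead.  Effect
sizes use the equal-n conversion d = 2|t|/√df, which reproduces the five
reported effect sizes of the source analysis exactly at two decimals; the
signed pooled-SD d from raw samples is available as `cohens_d_pooled` (the
two differ by a factor √(1−1/n) at equal n).  `average_significant`
re-averages each subject's metric over the FDR-significant sparsity set and
re-tests, returning `None` when the set is empty.  A rank-sum utility
(exact null up to n = 25) covers demographics.

The network-difference test is a reimplementation of the network-based
statistic: pooled t statistics on all 190 edges, thresholding at a primary
t (default 2.0, |t| for the two-sided tail), connected components of the
suprathreshold graph scored by edge count, and a max-component-size
permutation null with the add-one estimator
p = (1 + #{null ≥ observed})/(1 + n_perm).  Deterministic under its seed.

## Metabolite screening

Intensities are log₁₀-transformed, centred, and unit-variance scaled by
default (the original multivariate software's defaults are undisclosed;
`scale="pareto"`/`"none"` are available).  The discriminant model is PLS-DA
fit by NIPALS with X-deflation on a centred ±1 class dummy; with a single
response the weight direction is closed-form (w = X'y/‖X'y‖), making the
fit deterministic.  An orthogonal-signal-correction prefilter (removing the
dominant class-orthogonal component) is available behind
`orthogonal_correction=True` as the transparent stand-in for an
OPLS-style predictive/orthogonal split.  Variable importance in projection:

    VIP_j = sqrt( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a )

with SSY_a the class variance explained by component a; mean(VIP²) = 1 by
construction.  The screen selects features with VIP > 1 **and** raw
t-test p < 0.05 (t tests on log intensities), reporting BH-adjusted
p-values alongside; fold changes are ratios of raw group means with the
case group in the numerator.

## Correlation with topology

Spearman correlations (average ranks for ties) are evaluated per selected
feature × band × metric at every sparsity level, recording the sparsity of
maximum |ρ| per slice.  P-values use the t approximation, or exact
enumeration of all pairings for n ≤ 8 (raising `exact_limit` towards 10 is
supported but costs seconds; full enumeration of 10! pairings is why the
default stops at 8).  Because the scan spans 36 correlated thresholds, a
max-|ρ| permutation family-wise p is available (`scan_max_statistic_p` and
the `n_perm` option of the scan).  Score–metabolite correlations use the
same Spearman machinery.  Pathway-level correlation is interpreted as the
correlation of the first principal-component score of the pathway's member
features (log-z-scored), flagged as an interpretation rather than a
published formula.

## Synthetic cohorts: what is planted and how

The generator favours analytic ground truth over physiological realism.

**Coupled pairs.**  Each coupled channel pair shares a sinusoidal carrier;
the receiving channel's phase is offset by `lag·σ(t)` where σ is a ±1
sequence.  σ is held in 16-sample blocks (≈ 31 ms at 512 Hz) with an
*exact* count `round(q·n_blocks)` of negative blocks placed uniformly at
random, so the ground-truth PLI of an active pair is exactly |1−2q|.
Per-sample independent flips would be spectrally broadband: the Hilbert
phase cannot follow them and the estimate biases toward 1 (measured ≈ 0.65
instead of 0.5 at q = 0.25).  Block-held flips with exact counts keep the
estimator within ≈ 0.02 of |1−2q| on 60 s pairs.

**Carrier frequencies.**  Constant-lag coupling is transitive — if i locks
to j and j to k, then i locks to k — so an arbitrary planted graph cannot
be realized on one shared carrier.  Each simultaneously active pair gets
its own carrier on a `1/epoch` grid (0.5 Hz for 2 s epochs), which makes
cross-pair phase drift integrate to zero within every epoch.  Pairs may be
duty-cycled (active on alternating epochs) and pairs that are never active
together may share a carrier, extending the structure budget beyond the
band's slot count.

**Spatially structured background.**  All channels carry independent
band-limited noise; each channel additionally receives *directed* delayed
leakage (≈ 6 ms) from its 1-hop (gain 1.0) and, more weakly, 2-hop
(gain 0.7) montage neighbours.  Directionality matters: bidirectional
mixing produces a symmetric phase-difference distribution and leaves no
PLI trace at all.  The result is a background PLI "lattice" that decays
with scalp distance, emulating the residual spatially correlated coupling
of real recordings — and it is what makes proportional thresholding
meaningful, because a subject without planted long-range structure fills
the edge budget with *local* edges rather than uniformly random ones.

**Group contrast.**  The standard contrast cohort plants a connected cycle
of ten long-range "chord" pairs in the beta-2 band.  The case group carries
the chord oscillators at full amplitude; the control group has none, so its
channels stay noise-dominated and its thresholded graphs are elongated,
locally clustered lattices.  The case group's chords both act as long-range
shortcuts and dilute its local background (its analytic phase is
carrier-dominated), driving higher E_global, lower L_p, and lower C_c — a
topology shift toward randomness.  Realizing "stronger coupling" as chord
*amplitude* rather than consistency is deliberate: with proportional
thresholding a uniform consistency change alone barely alters which edges
survive, and carrier power is what simultaneously controls chord PLI and
local-background dilution.  The chords form a cycle, not a matching,
because a disjoint matching makes the sparsest graphs of a strongly
coupled subject maximally fragmented and flips the E_global contrast below
S ≈ 0.11.  Subject-level heterogeneity is a log-normal amplitude scale on
the chord pairs; the subject trait *u* (mean chord amplitude scale) is the
planted "coupling strength".

**Linked cohort and the correlation peak.**  For correlation-scan
validation, all subjects share a mid-strength chord template with a wide
log-normal amplitude spread, and one metabolite is tied to *u* through a
Gaussian copula with ρ_pearson = 2·sin(π·ρ_spearman/6), hitting a target
Spearman of 0.7.  The ground-truth profile of Spearman(u, E_global(S)) was
measured once with a 120-subject Monte-Carlo run: its deepest feature is at
S = 0.07–0.09 with *negative* sign (ρ ≈ −0.45), because at the sparsest
thresholds a strongly coupled subject's graphs are dominated by the chord
cycle and lose the scattered local edges that connect the remaining nodes.
These constants are frozen as `LINKED_EGLOBAL_ARGMAX_S = 0.08` and
`LINKED_EGLOBAL_PEAK_SIGN = -1` and are what the scan-recovery test checks
against.

**Metabolites and scores.**  Intensities are log-normal (log-sd 0.5, means
spread over e⁶–e¹⁰), strictly positive; affected features shift by a
natural-log fold change of 1.0 in the case group (five planted features by
default).  Depression-like scores are a group offset (≈ 20 vs ≈ 6, echoing
a screening-scale split) plus a monotone component in *u* and noise.
Everything is byte-reproducible from a single integer seed via spawned
`SeedSequence` streams.

## Problem sizes used in validation

Test and acceptance runs use: 60 s recordings at 512 Hz (≈ 30 epochs);
contrast cohorts of 31 + 32 subjects — the analyzed-cohort scale of the
source study (df = 61) — over 20 seeds; null calibration on 200 label
permutations of a 28-subject exchangeable chord-free pool (generating
hundreds of independent EEG cohorts for the null would add nothing
statistically: under exchangeability, label permutation draws from exactly
the null distribution); metabolite screens at 20 + 20 subjects with 50
features; correlation scans on 20 cohorts of 40 subjects.  The
permutation tests use 100–500 permutations with the add-one p estimator.

## What passing tests do and do not show

The synthetic validation establishes that each stage recovers *its own*
planted ground truth at realistic SNR: the PLI estimator inverts the
sign-flip model, the graph metrics are exact, the statistical chain has
calibrated type-I error and detects a planted topology contrast at
study-scale n, the screen recovers planted fold changes, and the scan
localizes a planted association.  It does not establish anything about
real EEG: the generator has no 1/f spectrum, no volume-conduction forward
model, no non-stationarity beyond epoch-level duty cycling, no ocular or
muscle artifacts (amplitude rejection is exercised only by construction),
and metabolite covariance is diagonal apart from the planted effects.
Conclusions about real cohorts require the real data.

## Known limitations

- L_p on fragmented graphs averages connected pairs only; comparisons at
  sparsities where groups differ in fragmentation rate need the flag.
- The per-epoch |mean| PLI estimator's noise floor bounds how weak a
  planted edge can be and still rank above chance.
- PLS-DA with two components is not OPLS-DA; the OSC prefilter approximates
  the orthogonal split but the decomposition is not identical.
- The exact Spearman p stops at n ≤ 8 by default (enumeration cost).
- EDF reading requires the optional `mne` dependency; the native format is
  delimited text with a YAML sidecar.
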