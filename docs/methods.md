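# Methods

## Seizure propagation model

A seizure is modeled as a discrete-time SIR epidemic on a weighted,
undirected brain network of N atlas ROIs. S, I and R stand for pre-ictal,
ictal and post-ictal tissue. Two engines implement the dynamics:

**Synchronous reference chain** (`simulate_sir`). At every step each ictal
node attempts to recruit each pre-ictal neighbour `j` independently with
probability `w_ij`; after all attempts, every node that was ictal at the
start of the step recovers with probability `γ`. Newly recruited nodes
cannot recover in their recruitment step, so a unit-weight link transmits
with certainty — this makes small-network behaviour exactly enumerable and
is the semantics used by all resection and δIR analyses and by the
exhaustive-enumeration tests. Once no pre-ictal node is reachable from the
ictal set, the absorbing state is determined (every ictal node recovers
with probability one) and the engine finishes in closed form. A hard cap
of 10·N steps guards against `γ → 0`; `on_cap="truncate"` instead maps
residual ictal nodes to recovered, which leaves infection ratios and
activation steps untouched and is used by the fitting sweep where
`γ = 0.01` recovery tails outlive the cap without affecting the pattern.

**Event-driven sampler** (`simulate_sir_async`). Competing clocks: each
ictal→pre-ictal link carries transmission propensity `w_ij`, each ictal
node recovery propensity `γ`; events fire one at a time with probability
proportional to propensity. Exactly one node changes state per event, so
the sampler natively produces the one-ROI-at-a-time activation order that
iEEG seizure patterns record, and recovery competes with transmission at
the level of single events. The two engines agree qualitatively but not
exactly; the event-driven one is the default for pattern fitting because
with synchronous updates every ictal node gets one full attempt round
before recovery can act, which at functional-connectivity weight scales
(retained weights 0.65–1.0) makes patterns almost independent of `γ` and
the recovery probability unidentifiable. The inner loop is compiled with
numba when available (pure-numpy fallback, identical algorithm).

Randomness is organised in substreams: realization `r` uses
`default_rng(rng_seed + r)`, so ensembles are reproducible and parallel
execution would match serial results. Paired (common-random-number)
estimation reuses the same substream on the intact and resected network.

## Networks

Connectivity matrices are symmetric with weights in [0, 1] (amplitude-
envelope-correlation convention: 0.5 = no coupling). Proportional
thresholding keeps the `round(ρ·N(N−1)/2)` strongest links at their
original weights; ties at the cutoff break by (weight desc, row asc,
col asc), which makes link sets nested across densities. Density sweeps
default to 12 log-spaced points in [0.01, 0.35].

Surrogate connectomes follow the exponential distance rule,
`w_ij ∝ exp(−α·d_ij)` (default `α = 1` per spatial unit), on a two-cluster
"hemispheres" geometry: N/2 ROIs per cluster, cluster centres 1.5 units
apart, isotropic unit Gaussian spread — close enough that the strongest
links are short-range yet the hemispheres stay bridged, as in real
connectomes. Raw weights are rescaled affinely into [0.5, 1.0] to inhabit
the same range as the rescaled functional networks; at the operating
density this leaves the weakest retained weight near 0.70, matching the
clinically reported value (~0.71).

Network distances use `1/w_ij` edge lengths by default (strong couplings
are short); hop counts are available because the published convention is
not stated. The default operating density for a synthetic patient of size
N preserves the *mean degree* of the clinical operating point (ρ = 0.03 on
246 ROIs, i.e. degree ≈ 7.35) rather than the raw density: at small N a
literal ρ = 0.03 yields fewer links than nodes and a fragmented network in
a different spreading regime.

## Seed-probability maps

The presurgical work-up is encoded per database region (34-region
ontology, 17 per hemisphere) and modality as binary abnormality flags.
Aggregation is the relevance-weighted mean
`A_i = n⁻¹ Σ_m D_m ω_m a_{i,m}` with `ω` = 1 (EEG), 2 (MRI, MEG, PET,
SPECT), 4 (iEEG) and `n = Σ_m D_m ω_m`; `A` is invariant to rescaling all
`ω_m`. A total projection maps each atlas ROI to one database region, and
`SP_i = A_{proj(i)}^R` with `R = 3` sharpens the map so that co-occurring
abnormalities dominate. Seed realizations are Bernoulli by default — each
ROI joins the seed independently with probability `SP_i`, redrawn while
empty (cap 1000) — so seed extent tracks map focality; fixed-size sampling
(k draws ∝ SP) is available for sensitivity analyses.

## Virtual resections and optimization

A resection zeroes all links of the resected node set; the node count is
unchanged, so infection-ratio denominators stay comparable, resected seed
nodes still count as ictal at t = 0 (they transmit nothing), and resected
non-seed nodes can never be recruited.

δIR is estimated as a ratio of paired means,
`δIR = (⟨IR₀⟩ − ⟨IR_R⟩)/⟨IR₀⟩` over (default 300) shared seed
realizations. The per-realization ratio is not used: in the bistable
regime a die-out realization has `IR₀ ≈ IR_R ≈` seed fraction and a
per-realization ratio of ~0, which would bias any resection's score
toward zero regardless of its effect; the ratio of means reduces to the
documented limits (0 for the empty resection exactly, `1 − seed
fraction/⟨IR₀⟩` for complete isolation).

The annealer searches, for each size S, the node set minimizing the mean
seed efficiency over a fixed panel of (default 20) pre-sampled seed
realizations. The *reported* seed efficiency follows the published
convention — seed and complement restricted to the giant component, 0 if
the seed leaves it — but the *search objective* drops the giant-component
restriction and simply counts `1/d_ij` with infinite distances
contributing zero and fixed denominators. The restricted quantity is
identically zero as soon as every panel seed is severed from the giant
component, leaving the optimizer without a gradient while the seed's
residual local component still seizes; it is also non-monotone under
resection growth (remote nodes dropping out of the component shrink the
averaging set). The unrestricted objective is monotone, has the same
minimizer whenever the seed stays in the giant component, and keeps
rewarding resections that shrink the seed's local neighbourhood.

Schedule: swap one resected with one non-resected node; initial
temperature calibrated to ≈80% acceptance of worsening moves; geometric
cooling (0.95) with 60 proposals per temperature; stop below 10⁻³·T₀, on
a zero-acceptance temperature, or at exact zero energy; 10 restarts with
the best-evaluated state returned. One restart per size warm-starts from
the previous size's best set plus one node, which guarantees the best
energy is non-increasing in size. `find_optimal_resection` locates
`S(R_op)` by bisection over sizes (assuming the empirically solid
monotonicity of δIR in size) for cohort-scale studies where a full sweep
per patient is unnecessary.

When no size reaches the δIR target the patient is censored: `S(R_op)` is
reported at the largest size swept and the overlap is taken against the
largest optimized resection.

## Pattern fitting

An iEEG pattern is the activation order of electrode-sampled ROIs plus
the sampled-but-silent set. A model pattern aggregates an ensemble:
participation (fraction of realizations recruiting the ROI) and mean
activation step. The fit is `C = max(0, C_w) · P_overlap`; `C_w` is the
participation-weighted Pearson correlation of rank orders over ROIs
active in both patterns (average ranks for ties; fewer than 3 joint ROIs
gives C = 0 with a degeneracy flag; anti-correlation is floored to 0), and
`P_overlap = ½(|A_m∩A_i|/|A_i| + |I_m∩I_i|/|I_i|)` the balanced agreement
of active and inactive sets over sampled ROIs (an empty reference set
contributes 1 iff the model set is empty too).

Which model ROIs count as "active" is a strategy switch: a fixed
participation threshold (default 0.05), or the self-calibrating
`"expected_extent"` strategy — the top-k sampled ROIs by participation
with `k = round(Σ participation)`, the model's own expected active-set
size. The fixed thresholds compare an *ensemble* set against a *single
recorded seizure* and are systematically biased (a 0.5 threshold yields
the ensemble core, which is larger than a typical single draw, so
inflating `γ` always looks better); the expected-extent strategy is the
default choice for single-seizure comparisons in the recovery
experiments.

`parameter_sweep` evaluates C on 12×12 log grids (ρ ∈ [0.01, 0.35],
γ ∈ [0.01, 1.00]), averaging per patient and repetition; the group
operating point is the argmax of the cohort-mean surface.

## Synthetic cohorts

The generator emulates the statistical structure the framework assumes,
not any real patient:

* EDR network on the two-cluster geometry, thresholded at the generating
  density (default: operating mean degree, see above); default generating
  `γ = 0.3`, inside the bistable regime where seizures either die locally
  or spread macroscopically.
* A focal EZ: the `ez_size` (default 6) nearest ROIs around a random
  centre.
* Work-up noise: each available modality detects an EZ region with
  sensitivity 0.7 (miss rate 0.3) and reports one spurious region with
  probability `0.4/ω_m` — the poorly localizing modalities err most. EEG,
  MRI and MEG are always acquired; PET, SPECT and iEEG each with
  probability 0.5. These rates sit in the range of reported modality
  sensitivities in presurgical evaluation and keep abnormality tables as
  sparse as clinical ones.
* Outcome mechanisms: seizure-free (SF) patients' resection areas cover
  the EZ plus up to two adjacent ROIs. Non-seizure-free (NSF) patients
  (default "mismatch" mode) carry a second, remote EZ cluster of equal
  size that the plan misses entirely, and the plan also misses half the
  primary cluster, landing partly on adjacent tissue — so the NSF group
  differs both intrinsically (larger, more diffuse EZ, hence larger
  optimal resections) and through plan/EZ mismatch. An "offset" mode
  keeps EZ sizes equal and only offsets the plan, for sensitivity
  analyses. Default cohort composition mirrors a realistic surgical
  series: 34 patients, 8 NSF.
* Recorded seizures: one event-driven realization from the true EZ at the
  generating operating point, observed through an electrode sample of
  `coverage·N` ROIs drawn with weights decaying with distance from the
  seed-map maximum (implantations target the clinical hypothesis). Of
  five valid candidate seizures the one of median extent is kept — the
  analogue of selecting a *characteristic* seizure rather than an extreme
  one.

What passing tests on these cohorts does **not** show: real MEG networks
are not EDR surrogates (they contain long-range functional coupling and
measurement noise), real abnormality tables encode correlated clinical
judgment rather than independent Bernoulli flags, and real NSF outcomes
have causes beyond EZ extent and plan mismatch. The synthetic results
validate the machinery and its internal consistency, not clinical
performance.

## Study-scale choices in the test suite

The end-to-end checks run at reduced problem sizes chosen to keep the
full suite near ten minutes on one CPU while preserving each effect
being tested: the optimal-resection contract at N = 60 with the full
protocol (sizes 1–20, 10 restarts, 300 paired realizations); operating-
point recovery on cohorts of 7 patients at N = 36, electrode coverage
0.8, truth at grid point (ρ = 0.133, γ = 0.658) — a generating point is
only a meaningful recovery target where single-seizure patterns constrain
both parameters, i.e. the network is connected but sparse (otherwise
component boundaries, not `γ`, cap seizure extent) and recovery is fast
enough to curb spread; and group-contrast replication over 50 cohorts of
34 patients at N = 30 with bisection search, one light annealing restart
and 40 paired realizations per estimate.

## Statistics layer

ROC curves and AUC come from scikit-learn's threshold sweep; the Youden
point maximizes TPR − FPR with ties resolved toward lower FPR, and the
reported threshold is placed midway between adjacent observed scores so
unseen cases in a separating gap classify correctly. Score orientations
are fixed a priori (larger `S(R_op)`, smaller `Ov`, smaller `δIR(RA)` →
NSF) to avoid data-dependent direction choices. The exact two-sided
rank-sum test enumerates the null distribution of the rank sum by a
counting recursion over doubled midranks (exact under ties) up to pooled
n = 40, then falls back to the tie-corrected normal approximation with a
warning; the two-sided p is twice the smaller tail, capped at 1.
Leave-one-out prediction refits the ROC threshold on each training fold
(the held-out label is never touched); the combined call is NSF iff at
least two of the three per-biomarker calls are NSF. The boosting
predictor runs a leave-one-out outer loop; per fold the majority class is
undersampled to the minority size, an AdaBoost ensemble of depth-1 stumps
(learners = balanced-training size − 1, learning rate 1.0) is fitted on
the three biomarkers, and everything is averaged over 10 undersampling
repetitions; feature importances are normalized mean stump usage.

## Known limitations

* The event-driven and synchronous engines are not distributionally
  identical; quantitative results state which engine they use.
* `Ov` uses `|∩|/min(|·|,|·|)` by default (Jaccard optional); with the
  min convention a small plan inside a large optimized resection scores 1.
* The annealer is stochastic; the exhaustive-oracle test bounds its
  optimality gap only at N ≤ 12.
* Exact rank-sum enumeration is limited to pooled n ≤ 40 by design.
* The giant-component tie-break (smallest contained index) matters only
  for pathological equal-size splits.
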