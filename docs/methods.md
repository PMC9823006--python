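# Methods

## The analysis problem

A two-dimensional ^1H–^15N HSQC spectrum shows one cross peak per backbone
amide. When a ligand binds in fast exchange on the NMR timescale, each
affected peak is the population-weighted average of its free and bound
positions, so it drifts continuously as ligand is titrated in. From a series
of per-point peak lists, `cspmap` answers three questions: *which* residues
respond (the binding surface), *how strongly* the ligand binds (K_D), and
*where* the responsive residues sit on the structure.

## Combined shift metric

All distances in the shift plane use the combined amide change

    dd = sqrt(dd_H^2 + (alpha * dd_N)^2)        [ppm]

with alpha = 0.154, the conventional weight that makes ^15N differences
commensurate with ^1H differences (ratio of average BMRB shift variances).
The same metric drives assignment transfer, peak tracking, overlap
detection, the significance statistic, and the fitted amplitude, so a single
`alpha` parameter controls all of them.

## Peak tracking

Correspondence across titration points is established by
mutual-nearest-neighbor matching in the scaled metric, chained point to
point (each spectrum matched against the previous one). Chaining exploits
the fast-exchange property that per-step motion is a fraction of the total
trajectory; matching against the apo spectrum directly would fail for any
residue whose total shift exceeds the inter-peak spacing. Conflicts fall
back to a greedy distance-ordered pass; candidate pairs tied within 1e-9 ppm
are rejected outright rather than resolved arbitrarily (a track is easier to
recover than a silent misassignment). Defaults: `max_step = 0.05` ppm
(largest credible per-step motion on a well-designed titration),
`overlap_tol = 0.01` ppm (peaks closer than this are not independently
quantifiable). A global optimal-assignment solver is deliberately not the
default; the greedy mutual-NN scheme is transparent and its failure mode
(a lost track) is visible in the output.

## Significance classification

The per-residue statistic is the endpoint combined CSP (apo vs final
point). Its distribution over all assigned, tracked residues gives mean and
sample SD sigma; no outlier trimming is applied. The default rule classifies
a residue as significant at k-sigma when dd > k * sigma (`ksigma`); the
alternative reading dd > mean + k * sigma (`mean_plus_ksigma`) is selectable
and both thresholds are always recorded in the table metadata. The default
follows the plain reading of the significance convention for this analysis
("larger than two standard deviations of the average shift"); with a
zero-width distribution (sigma = 0) nothing is classified significant under
either rule. Classification is scale-equivariant by construction — only
ratios to sigma matter.

## Binding model and K_D fit

At 0.4 mM protein and micromolar K_D the bound ligand is a large fraction of
total ligand, so the hyperbolic (excess-ligand) isotherm is wrong. The bound
fraction solves the mass balance exactly:

    f([L]_t) = [(K_D + L_t + P_t) - sqrt((K_D + L_t + P_t)^2 - 4 L_t P_t)] / (2 P_t)

and each reporter residue is fitted as dd_obs = dd_max * f with two free
parameters (K_D, dd_max). Numerical choices:

- K_D is parameterized as log K_D (positivity by construction), reported in
  uM at the interface; concentrations are mM internally everywhere.
- Multi-start: 5 initial K_D values log-spaced over [smallest nonzero L,
  10 * largest L]; amplitude initialized at 1.2x the endpoint CSP; best
  objective wins, ties toward the smaller K_D. Trust-region least squares,
  objective tolerance 1e-10.
- A fit is discarded (not pooled) when the optimizer fails or the track has
  fewer than 5 matched points or no signal.

Reporters are the residues that are significant (>= 1 sigma), fully tracked,
and not overlapped. Pooling default is `per_residue_average`: independent
fits, pooled K_D = mean +- SD over reporters, matching the convention of
reporting "mean +- SD over individual residues (n = ...)". The alternative
`shared_kd` mode (one K_D, per-residue amplitudes, leave-one-residue-out
jackknife SD) is retained because "global fitting" also admits that reading;
on well-behaved data the two agree within combined uncertainties. Whether
the published +-SD is across residues or from a fit covariance is not
derivable from the text; across-residues is implemented as primary.

The normalized binding curve averages dd_obs/dd_max across reporters at each
titration point with its SD — the quantity conventionally plotted against
ligand concentration.

### Identifiability

K_D is well determined only when the titration brackets the bend of the
isotherm. Two regimes degrade it: (i) K_D << P_t — binding is essentially
stoichiometric and the curve shape is insensitive to K_D (recovery scatter
grows toward the tight end); (ii) K_D beyond the largest ligand
concentration — the curve never bends and recovery scatter blows up (a >30x
jump in relative SD between K_D = 0.6 mM and K_D = 10 mM under the default
design). Both regimes are asserted in the test suite.

## Synthetic titrations

The generator emulates the study conditions: 160 assignable backbone amides
over a 2–192 residue span (8 prolines and two contiguous unassigned
clusters are excluded), protein fixed at 0.4 mM, 12 titration points, and a
named scenario table (generating K_D, final molar ratio, planted binder
count): `fc14-like` (0.0171 mM, 1:12, 20 binders), `lpc14-like` (0.0189 mM,
1:7, 13), `mutant-like` (0.129 mM, 1:24, 10); every parameter is overridable
to emulate the remaining reported titrations. Binders draw
dd_max ~ Uniform(0.05, 0.30) ppm; non-binders |Normal(0, 0.005)| ppm.

Design choices worth knowing:

- **Ligand schedule.** Per-point concentrations are not published for these
  experiments, so the generator uses an equal-bound-fraction schedule:
  target fractions evenly spaced to the endpoint fraction, inverted
  analytically via L_t = f P_t + K_D f/(1-f). This mirrors actual practice
  (small aliquots while peaks move fast, larger near saturation) and keeps
  per-step peak motion at ~1/11 of the total trajectory, well inside the
  tracker's step limit.
- **Noise** is Gaussian with SD 0.003 ppm applied in the scaled metric
  (so ^1H and ^15N errors are commensurate). No noise figure is published;
  this value reproduces CSP distribution means of the observed 0.02–0.03 ppm
  order.
- **Trajectories are linear** in the scaled plane with a fixed per-residue
  direction — the strict two-state fast-exchange signature the analysis
  relies on.
- **Separation guarantee.** Free positions are rejection-sampled so every
  pair of assignable trajectories keeps >= 0.10 ppm scaled separation at
  every titration point; this makes zero-noise tracking exactly correct and
  well-defined. Crowding is supplied instead by decoys: non-titrating peaks
  (20 by default) dropped uniformly into the congested 8.0–8.5 ppm ^1H
  region with no separation guarantee.
- **Dropout** (per-point Bernoulli peak loss, default 0) exists to emulate
  exchange broadening but is off by default since the fits use persistent
  peaks.

What the generator does *not* emulate: lineshapes and intermediate
exchange, intensity changes, temperature/pH drift between points,
systematic referencing offsets, and peak-picker artifacts. Passing
recovery tests therefore certify the analysis chain under the stated
statistical model, not robustness to every pathology of real spectra.

## Structure mapping

Coordinates are read via gemmi (PDB/mmCIF); alternate locations resolve to
the highest-occupancy atom. Per-residue CSPs are painted into the
temperature-factor field of every atom of the residue, scaled x100 and
capped at 999.99 so 0.01-ppm-order values survive the two-decimal column;
unmatched or unassigned residues get 0 and a sidecar report line.
Superposition is least-squares (Kabsch) on the C-alpha atoms of the
residue-number intersection of each chain pair — sufficient since copies in
an asymmetric unit share one sequence. Both the all-pairs mean rmsd and a
reference-chain mean are available, since published multi-copy rmsd values
rarely state which convention they use. Spatial clustering of the
significant set is scored by its mean pairwise C-alpha distance against a
permutation null of equal-size random subsets of the assigned residues,
p = (1 + #{null <= observed}) / (n_perm + 1).

## Problem sizes used in the checked examples

Recovery studies run 100 independent seeds per scenario with the full
pipeline (simulate, transfer, track, classify, select, fit) at the scenario
defaults above; the bias grid uses 60 seeds per K_D. These sizes put the
Monte-Carlo standard error of a pooled K_D mean well below the 15% recovery
band while keeping a full study in minutes on one core.

## Known limitations

- Tracking has no global optimum guarantee; pathological crossings can in
  principle swap two tracks (observed rate < 0.2% of binder tracks at
  default noise).
- The sigma-threshold classification is descriptive, not a hypothesis test;
  no multiple-testing control is intended or provided.
- Errors from peak-position uncertainty are not propagated into per-residue
  K_D confidence intervals; the pooled SD across residues is the only
  uncertainty reported.
- One binding site, one K_D: no cooperative, two-site, or exchange-regime
  (k_ex) modelling.
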