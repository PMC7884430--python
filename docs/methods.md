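# Methods

## The problem

Hydrogen–deuterium exchange mass spectrometry (HDX-MS) reports isotope
uptake for proteolytic peptides, not residues.  Each peptide's relative
fractional uptake (RFU) at labelling time *t* mixes the exchange of all of
its backbone amides, so the per-residue quantities of interest — the
observed exchange rate `k_obs` and the protection factor
`PF = k_ch / k_obs` (reported throughout as `lnP = ln k_ch − ln k_obs`) —
are only indirectly constrained.  hdxsolver deconvolves peptide-level RFU
tables into residue-level lnP and, because the inversion is frequently
underdetermined, scores its own trustworthiness post hoc from the
consistency of replicate solutions.

## Forward model

A residue exchanging with first-order rate `k_obs` (min⁻¹) carries
deuterium fraction `1 − exp(−k_obs·t)`.  A peptide's model RFU is the
arithmetic mean of those uptakes over its *exchange-competent* residues:
prolines (no amide proton) and the peptide's first residue (fast
back-exchange of the nascent amine) are excluded.  One N-terminal residue
is excluded by default; the count is configurable (`n_term_exclusion`)
since some processing conventions exclude two.  Uptake exponentials are
evaluated with `expm1` so strongly protected residues (RFU ≈ 0) remain
well resolved.  Time is minutes everywhere.

## Intrinsic rates

`k_ch` per residue is computed from sequence, pD and temperature as the sum
of acid-, base- and water-catalysed terms with log-additive near-neighbour
side-chain corrections, using the standard poly-DL-alanine reference rates
for exchange into D₂O (log₁₀ k at 293 K: acid 1.62, base 10.18, water
−1.5; activation energies 14/17/19 kcal·mol⁻¹; pK(D₂O) 15.05) and the
published left/right correction-factor tables (Bai et al. 1993, with the
2018 Englander-lab updates).  Titratable side chains (Asp, Glu, His) and
the chain termini are log-interpolated between their protonated and
deprotonated factors at the working pD.  pD is used as given — no
pH-meter correction is applied.  The first chain residue and prolines carry
no rate.  The constant set lives in `hdxsolver/_rate_tables.py`; the
poly-alanine arithmetic is verified by independent hand computation in the
test suite.

## Map structure: redundancy, occupancy, subsections

Redundancy counts peptides covering a residue.  A peptide's *density* sums,
over its competent residues, the number of peptides in which that residue
is competent (a peptide does not count toward its own N-terminal residue's
tally — this convention is what makes the occupancy of an isolated peptide
exactly 1); *occupancy* is density divided by the number of competent
residues.  Peptides with occupancy < 2.5 are filtered before fitting.  The
filter is single-pass by default (all occupancies evaluated against the
original map); an iterative mode re-evaluates to a fixed point.  Subsections
are connected components of the span-overlap graph and are fitted
independently; bridging peptides (articulation points of that graph) are
reported because deleting one splits a subsection in two.

## Optimisation engine

Each subsection is fitted by minimising the mean squared error between
model and experimental RFU over all peptide/timepoint pairs, with one
`k_obs` variable per competent residue bounded to `[1e-18, k_ch]` min⁻¹
(the loose lower bound admits extreme protection at the cost of weak
constraint — see data collapse below).  The SQP core is SLSQP with an
analytic gradient, run on variables scaled to the unit box
(`u = k_obs/k_ch`) so the quasi-Newton model is well conditioned across
rate decades; a log-rate parameterisation is available behind a flag.

This misfit surface is riddled with *compensation minima*: residues that
share most of their peptides can settle with exchanged or mutually
compensating rates, and no gradient step escapes.  The engine therefore
manages the optimisation as a loop — SLSQP cycle, exact bounded 1-D refit
of each rate in turn, then greedy proposals that swap the rates of residue
pairs up to `swap_width` (default 3) apart — repeated until a full cycle
improves the MSE by less than the precision goal (10⁻⁶) or the cumulative
SQP iteration budget (1000) is spent.  The polish stages are toggleable
(`polish=False` reduces to a single SLSQP call).  An optional equality
constraint `h(x) = MSE = 0` can be added for experimentation; it is off by
default because it is infeasible for noisy data and redundant otherwise.

Each replicate starts from an independent initial guess with `k_obs` drawn
per residue from an exponential distribution (scale 1.0 min⁻¹, clipped
strictly inside the bounds); replicate *i* uses seed `base_seed + i`, so
ensembles are bit-reproducible.  Defaults: 50 replicates for production,
10 for evaluation runs.  Non-converged replicates are kept and flagged —
the validation matrix naturally downweights pathological runs.  Replicate
lnP vectors are aggregated by the per-residue median (mean and dominant
2-means-cluster centroid are available; the median is the most robust and
best preserves the separation between accuracy classes).

## Auto-validation

With ground truth unavailable, fit quality is read from replicate
agreement.  For *m* replicates the validation matrix holds all pairwise
Pearson correlations `R_ij = C_ij/√(C_ii·C_jj)` between replicate lnP
vectors; the **R̂-matrix** score is the arithmetic mean of all *m²* entries
(the unit diagonal included by default; an off-diagonal mode exists because
diagonal inclusion inflates small-*m* scores).  Replicates with zero lnP
variance have undefined correlations; those entries are recorded missing
and excluded from the mean with a warning.  Scores are binned high
(> 0.7), fair (0.5–0.7, both boundaries inclusive) or low (< 0.5);
production runs are not recommended for subsections that evaluate below
0.5 (they are reported with an advisory, never silently dropped).

Per-residue diagnostics use leave-one-out:
`ΔR̂(r) = R̂(all) − R̂(all except r)`.  Omitting an accurately fitted
residue lowers replicate agreement (ΔR̂ > 0); omitting an outlier raises
it (ΔR̂ < 0).  Each omission is recomputed with the same Pearson kernel,
and equality with from-scratch brute force is asserted to 1e-12 in the
tests.  Per-residue histograms of replicate lnP (bin width 1, integer
edges) are the primary visual guide; residues with an interquartile range
≥ 20 lnP (inclusive) are flagged as possible *data collapse* — fits
drifting to the weak lower bound, typically when the longest timepoint
leaves uptake far from saturation.

In simulation studies the **R̂-reference** (mean correlation of each
replicate with the true profile) is also computed, along with per-residue
RMSE and median error, the ROC AUC of RMSE as a classifier of sign(ΔR̂),
and the enrichment of accurate (|error| < 1) and outlier (|error| > 2)
residues in the positive and negative ΔR̂ pools.

## Reference-data simulator

The simulator regenerates the kind of benchmark library the validation
method is developed and tested on, with every residue's truth known:

* **lnP profiles** — `smooth-random` draws a moving-average-smoothed random
  field rescaled to a range (default 0–14 lnP, window 7), giving the
  spatial autocorrelation real protection profiles have; `two-term`
  evaluates the standard structural expression
  `lnP = β_c·N_c + β_h·N_h` (defaults β_c = 0.35, β_h = 2.0) from
  user-supplied contact and H-bond counts.  Control variants invert or
  permute a profile.
* **Peptide maps** — random covering walks plus random top-up peptides,
  with realised mean redundancy within 20% of target; a `dense` layout
  places a peptide at every start position, maximising terminus diversity.
* **RFU projection** — the forward model at the standard 7 timepoints
  (0.25, 1, 5, 20, 60, 240, 480 min), noise-free by default (optional
  truncated Gaussian RFU noise); sequence-derived k_ch at pD 7.0 / 293 K
  (4% proline admixture) or a uniform k_ch to isolate optimiser behaviour.
* **Library** — a grid of regimes from well constrained (short peptides,
  redundancy ~6) to poorly constrained (15–25-residue peptides, redundancy
  ~1.5–3, high lnP); every generated map passes the occupancy-2.5 filter
  and subsection splitting before emission, and regimes gutted by the
  filter are retried with fresh spawned seeds, which is precisely how the
  weakly constrained members arise.

What the simulator does **not** emulate: back-/forward-exchange artefacts
(inputs are assumed corrected upstream), EX1/EXX kinetics, ion-envelope
shapes, or instrument noise models beyond additive Gaussian RFU noise.
Passing tests therefore demonstrate the estimator's behaviour under ideal
exchange kinetics, not robustness to raw experimental pathology.

## Identifiability, and what "best case" means

Residues covered by *exactly* the same peptide set are mathematically
interchangeable: only the multiset of their rates is determined, however
good the optimiser.  Random tilings leave such runs; dense maps almost
eliminate them.  The best-case benchmark (`benchmark.well_constrained_run`)
therefore uses a ~60-residue dense map (realised redundancy ~7, noise-free,
50 replicates), where the median model recovers essentially every residue
within ±1 lnP and R² vs truth exceeds 0.99.  Random-tiling maps of similar
redundancy plateau around 85% / R² ≈ 0.85 for reasons of map structure,
not optimisation.

## Benchmark scale and numerical choices

The library study (`benchmark.run_reference_study`) uses 12 subsections
spanning the regime grid, fitted with 50 replicates each (≈ 2 minutes on
one CPU); per-subsection optimiser seeds are derived from the study seed
and kept below 2³¹.  Coordinate refits use bounded scalar minimisation in
log-rate with `xatol = 1e-3`; initial guesses are clipped to
`[10·lower_bound, k_ch·(1−1e-9)]` so no replicate starts pinned to a
bound; fitted rates are clipped into the box before lnP is formed.
Correlation matrices are symmetrised exactly and clipped to [−1, 1] to
absorb last-bit floating-point asymmetry.

Observed at this scale (seeds 1–3): the R̂-matrix vs R̂-reference
relationship is tight (R² ≈ 0.90–0.97) and the libraries span all three
accuracy bins; RMSE classifies the sign of ΔR̂ with AUC ≈ 0.68–0.73;
accurate residues are enriched in the positive-ΔR̂ pool (≈ 20–30% excess)
and outliers are ≈ 1.7–2× more likely in the negative pool.  The
enrichment magnitudes depend strongly on the library's joint error/ΔR̂
composition and are the least transferable of these statistics.

## Known limitations

* Absolute k_ch values away from pD ≈ 7 depend on the transcribed
  side-chain constants; diff against the published tables before relying
  on them quantitatively.
* The occupancy filter plus subsection splitting can leave residues
  uncovered; they are dropped from the fit with a logged warning.
* ΔR̂ is a relative, not calibrated, signal: its sign ranks residues
  within a subsection but thresholds do not transfer across datasets.
* The engine fits EX2-like per-residue first-order uptake only.
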