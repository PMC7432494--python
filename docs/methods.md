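# Methods

## Observable model

Each backbone amide of a Ub unit exchanges between an open and a closed
environment fast on the chemical-shift timescale (exchange rates well above
the frequency separation of the two pure-state peaks, which is of order
100 Hz for the diagnostic hydrophobic-patch residues). The observed peak
therefore sits at the population-weighted average position

x = x_open + t (x_closed − x_open),  t = f_closed.

Monomeric Ub supplies x_open and cyclic Lys48-linked diUb supplies
x_closed. The cyclic trimer is *not* a valid closed reference — its
hydrophobic surfaces are partially exposed, which shows up as a peak off
the open↔closed line; the collinearity diagnostic below encodes exactly
that disqualification test.

## Dividing ratio by orthogonal projection

Distances are measured in composite-shift coordinates (δH, α·δN) with
α = 0.14 by default, the common weighting that compensates the larger ppm
dispersion of ¹⁵N. The dividing ratio t is the orthogonal-projection
parameter of the observed point onto the line through the two references;
the orthogonal residual (perpendicular deviation, in composite ppm) and its
ratio to the reference separation are reported per peak.

Choices that matter:

* **α (alpha_N), default 0.14.** For exactly collinear triples the ratio is
  invariant to α (and to any anisotropic rescaling/translation of the
  plane — tested as a property); α only shapes how position noise and the
  deviation metric are weighted between the two axes. Configurable.
* **Whether to project in 2D or read one axis.** Published analyses of this
  kind rarely state it; orthogonal projection in the composite plane is
  this package's definition. It uses both axes, reduces to the single-axis
  answer when the displacement is axis-parallel, and comes with a natural
  off-line diagnostic.
* **min_separation, default 0.02 composite ppm.** Reference pairs closer
  than this are flagged `uninformative`: dividing a near-zero segment
  amplifies noise without bound.
* **rel_deviation threshold, default 0.10.** A peak whose perpendicular
  deviation exceeds 10% of the reference separation is flagged `off_line`
  and excluded from aggregation. This makes the qualitative "significant
  deviation from the straight line" criterion a testable cutoff.
* **Out-of-range ratios.** Raw t is always reported (diagnostics must not
  lie); clamping to [0, 1] happens only when per-unit fractions are
  aggregated, and t outside [−0.05, 1.05] is flagged `out_of_range`.
* **Aggregation policy.** Default `single_probe` uses Val70, the canonical
  hydrophobic-patch reporter, so a unit's open fraction is that one
  residue's f_open. `weighted_mean` averages f_open over all usable
  residues weighted by separation² (longer reference segments divide more
  precisely), with a weighted standard error.

## State space and inversion

A chain conformer is modelled as a *matching* on the unit-contact graph:
each unit shields its patch in at most one pairwise contact, and the empty
matching is the all-open state. For three units with all contacts allowed
this gives exactly four states (A all-open; B = Ub2–Ub3; C = Ub1–Ub2;
D = Ub1–Ub3 end-to-end, middle unit open); matchings of the complete graph
on n units count 2, 4, 10, 26 for n = 2…5. Non-adjacent contacts are
allowed by default because the end-to-end state is part of the three-unit
model; an adjacency-only contact graph is a configuration option.

The unit-openness incidence matrix M links populations to measured open
fractions, M P = f with Σ P = 1. For n = 3 the augmented system is square
and nonsingular and is solved exactly (P_A = (Σf − 1)/2). Negative exact
solutions are returned as-is with `feasible=False` — clipping would hide
model misfit (e.g. f = (0,0,0) is unreachable because no matching closes
all three units simultaneously). For longer chains the system is
underdetermined; `nnls` mode minimises ‖M P − f‖ over the simplex (SLSQP
with the normalisation as a hard equality, tolerance 1e-14), and
`feasibility_bounds` reports each state's [min, max] population over the
polytope {P ≥ 0, Σ P = 1, M P = f} by linear programming (HiGHS). The
generalisation beyond three units is an extension of the published
three-unit model and is labelled as such in the pipeline summary.

Populations are reported both at full precision and rounded to integer
percent, the convention used when quoting such equilibria.

Uncertainty, when requested, comes from a parametric bootstrap: unit
fractions are resampled from independent Gaussians (the simplest defensible
model when only per-unit standard errors are available), re-solved, and
2.5/97.5 percentiles reported. Deterministic given the seed. For the
three-unit chain the delta method gives sd(P_A) = σ√3/2 for a common
per-fraction σ, which the bootstrap reproduces (the 95% half-width is 1.96
times that sd).

## Synthetic data generator

The generator emulates exactly the statistical structure the analysis
assumes: per-unit open fractions are forward-mapped from ground-truth state
populations, each probe residue's peak is placed at the weighted-average
position on its reference segment, and independent Gaussian position noise
is added per axis (defaults σ_H = 0.003 ppm, σ_N = 0.02 ppm, typical
peak-position precision in a well-resolved HSQC). Reference lists are
noise-free. One seed governs everything via spawned per-unit substreams, so
generated files are byte-reproducible.

The reference geometry (open positions in the amide region, closed
positions displaced by 0.1–0.5 ppm ¹H / 0.5–2.0 ppm ¹⁵N in
residue-dependent directions) is a **synthetic fixture**, not measured
shifts. Exchange broadening is modelled only optionally, as an intensity
attenuation ∝ f_open(1 − f_open) — lineshapes, relaxation and
slow/intermediate exchange are out of scope.

What passing tests therefore show: the projection, aggregation and
inversion are mutually consistent and numerically exact on data that obey
the fast-exchange two-site model, and robust at realistic position noise.
What they do not show: behaviour under reference miscalibration, peak
overlap, assignment errors, or exchange regimes where the single-peak
weighted-average picture itself breaks down — on real spectra the
collinearity report is the first place such violations surface.

## Numerical and testing notes

* Exact-collinear constructions recover t to 1e-12; the closed-form
  projection is verified against a brute-force grid-search oracle
  (t ∈ [−0.5, 1.5], step 1e-6) to 1e-5.
* Noise-free end-to-end identity (simulate → project → solve) holds to
  1e-10 over 1000 random simplex population vectors.
* Noisy-recovery checks use 200 replicates per noise level at the default
  σ and two tenfold reductions; mean absolute population error at the
  default noise is well below 0.05 and decreases monotonically with σ.
* Peak lists round-trip through both file dialects at 4-decimal ppm
  precision; analysis pipelines that need exact identity should stay in
  memory (file precision bounds t errors by ~1e-4/separation).
* Exit codes of the CLI: 0 success, 2 validation error, 3 infeasible
  solution (outputs are still written in the infeasible case).
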