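# Methods

## The model

`axisbreak` simulates the breaking of radial symmetry in the early chick
blastodisc: the transition from ubiquitous, uniform *Bmp4* and *Vg1*
expression to one BMP4-high (future anterior) and one Vg1-high (future
posterior) domain in the marginal zone, the annular ring of cells whose
posterior sector later initiates the primitive streak.

The marginal zone is modelled as a closed 1-D ring of `n_cells` identical
cells.  Each cell carries four dimensionless state variables: the
extracellular ligands BMP4 (`B`) and Vg1 (`V`) and two intracellular
factors, `F_B` (candidate: Gata2) and `F_V` (candidate: Pitx2).  Cells
communicate only by short-range paracrine signalling: the signal a cell
perceives is the *mean* ligand level over the window of cells within graph
distance `coupling_radius` (`r`) of it — a window mean rather than a sum so
that uniform states are fixed points independent of `r`.  On sealed
fragments the window truncates at the cut and averages the available cells
only.

Per cell, with `S_B`, `S_V` the perceived ligands and Hill terms
`act(x; K) = x^n / (K^n + x^n)`, `inh(x; K) = 1 - act(x; K)`:

    dF_B/dt = alpha_B * act(S_B; K_BB) * inh(S_V; K_VB)              - delta_F * F_B
    dF_V/dt = alpha_V * inh(S_B; K_hi)
              * [ act(S_V; K_VV) + c_BV * act(S_B; K_lo) ]           - delta_F * F_V
    dB/dt   = beta_B * F_B - delta_B * B   (+ graft sources)
    dV/dt   = beta_V * F_V - delta_V * V   (+ graft sources)

The interactions encode: BMP4 induces its own factor F_B; Vg1 represses
F_B; Vg1 renews itself through F_V; and BMP4 acts on F_V as a *band-pass*
(biphasic dose response): perceived BMP4 inside the `(K_lo, K_hi)` band
induces F_V, above `K_hi` it shuts F_V production down.  The band-pass is
the model's realization of the central experimental paradox — the same
ligand suppresses Vg1 when grafted into the Vg1 domain (where it drives
`S_B` above `K_hi`) and induces Vg1 near a graft in the BMP4 domain (whose
flanks fall inside the band).

Units: the model is fully dimensionless.  Time is measured in intracellular
factor lifetimes (`delta_F = 1` defines the clock); concentrations are on
the scale of the Hill constants.  No mapping to hours or protein
concentrations is attempted.

## How symmetry breaks

Simulations start from the "both-on" uniform fixed point — the launch
state representing ubiquitous expression before stage X — perturbed by
independent per-cell lognormal noise of relative amplitude `sigma_init`
(default 0.02).  No positional bias is imposed; the final orientation of
the axis is set by the noise realization, and the dynamics are exactly
equivariant under rotations and reflections of the ring.

Because every interaction flows through the perceived (window-averaged)
signals, the linearization around any uniform state block-diagonalises
over discrete wavenumbers `k`: each mode sees the single-cell Jacobian
with its signal-mediated entries multiplied by the window transfer factor
`g(k)` (the DFT of the normalized window kernel).  `axisbreak.stability`
computes this spectrum in closed form.  The committed default parameters
were *calibrated* (see below) so that at the launch state:

* the leading eigenvector at `k = 1` is real and antiphase in (B, V) —
  BMP4 up where Vg1 down — so the growing mode is a segregation mode;
* `k = 1` has the largest growth rate, with `k = 2` also unstable but
  clearly slower, and all shorter wavelengths decaying;
* the uniform (`k = 0`) mode grows much more slowly than `k = 1`, so the
  race from equal-amplitude noise is won by the bipolar mode rather than
  by a whole-ring collapse into a single phase.

The growing `k = 1` mode saturates nonlinearly into one BMP4-high and one
antipodal Vg1-high domain.  The `k = 2` instability is not a defect: a
sealed quarter-ring fragment cannot host the `k = 1` wavelength, and its
lowest internal mode corresponds to ring wavenumber ~2.  Keeping that mode
unstable is exactly what lets every fragment of a cut embryo regenerate
its own Vg1 pole (twinning) while the intact ring still selects a single
axis.

## Perturbations

* **Bead / pellet** — a constant-rate ligand source over a footprint of
  `2*radius + 1` cells (a reservoir releasing ligand; a concentration
  clamp was rejected because it breaks smoothness of the flow).  The
  default strength is chosen so the steady perceived BMP4 at the bead
  center is about `2 * K_hi` — a saturating bead whose center shuts the
  Vg1 branch down while its flanks sweep through the inductive band.
* **Knockdown** — multiplies the production term of `F_B` or `F_V` by
  `1 - efficiency` in the covered cells (antisense/morpholino semantics;
  modelled as production scaling, not accelerated decay).
* **Fragmentation** — seals the ring into arcs at inter-cell boundaries;
  cell contents are untouched at the instant of cutting.

All perturbations act over half-open windows `[t_on, t_off)` and are
sampled once per integration step (zero-order hold).  Experiments that
manipulate a formed pattern (bead grafts, knockdowns) first run the
unperturbed dynamics, place the manipulation relative to the *realized*
axis (posterior := the Vg1-domain centroid, anterior := its antipode), and
score fold-changes against the same seed's **pre-manipulation** expression
map — paired, never absolute.  The pre-graft state was chosen as the
reference (rather than an unperturbed continuation run) because the
unperturbed pattern's position wanders slowly (see Limitations): a
continuation control can move its Vg1 pole onto the readout zone by drift
alone, corrupting the pairing, whereas the pre-graft map is exactly the
geometry against which the graft was placed — the same convention used
when a grafted embryo is scored against its own pre-graft in-situ
geometry.  Readout statistics follow the staining they mimic: *inductions*
(Vg1 or F_B upregulation near a graft) are read as the peak over the
readout zone (footprint radius + twice the paracrine range) — a localized
bright patch; *suppressions* are read as zone means.  Induction calls
require a 2x fold-change, suppressions 0.5x (Vg1 under a posterior bead:
0.2x of the pre-bead footprint mean); all thresholds are configurable
protocol fields.

## Numerics

Fixed-step classical Runge–Kutta (RK4).  Adaptive stepping was rejected so
that trajectories are bit-reproducible across runs and platforms; the
window mean is accumulated in a symmetric pairwise order so the scheme is
bitwise equivariant under ring rotation and reflection.  Negative
excursions (possible only at the last ulp) are clamped to zero, with a
warning if the clamped magnitude ever exceeds 1e-9.  Optional intrinsic
noise (`sigma_dyn > 0`) is applied after each step as multiplicative
lognormal factors `exp(sigma_dyn * sqrt(dt) * z)`, preserving
non-negativity without reflection schemes.  Integration stops early when
`max |rhs| < 1e-6` (with currently active sources) and no scheduled event
is pending; a `t_end` cap prevents non-terminating runs.  The library
default step is `dt = 0.01` for high-accuracy work; the experiment battery
uses `dt = 0.1`, which RK4 resolves to well below the pattern
scales probed (halving `dt` moves a short trajectory by < 1e-6 per field).

Uniform fixed points are found by multi-start root search (a 14x14
log-spaced grid over ligand levels with consistently initialized factor
levels, plus coarse 4-D corners), deduplicated at relative tolerance 1e-6
and verified to residual < 1e-10.

## Calibration

The biological literature fixes this network's interaction structure but
not its constants, so the committed defaults are a calibrated set: the
parameter space was searched (linear-spectrum screening of designed
both-on fixed points, then simulated-annealing refinement against
simulated outcomes) for a regime satisfying, simultaneously, the
wavenumber-selection conditions above, macroscopic saturated amplitude,
the anterior-bead induction, and regeneration of a Vg1 domain in each of
four quarter-ring fragments.  The certified regime combines a sharp Hill
cooperativity (`n = 6`), a paracrine range of 10 cells on the 100-cell
ring, fast BMP4 ligand turnover against slow Vg1 turnover
(`delta_B ~ 4.35` vs `delta_V ~ 0.42` factor-lifetimes), Vg1 thresholds
well below the BMP4 ones (`K_VV ~ 0.21`, `K_VB ~ 0.26` vs
`K_BB ~ 0.49`), and the inductive band at `(K_lo, K_hi) ~ (1.01, 6.23)` —
above the patterned BMP4 level, reachable only near a graft.  The exact
values are the `ModelParameters` defaults.  At these defaults the full
battery passes: symmetry breaking is strictly bipolar in 19/20 seeds and
every perturbation experiment passes in 20/20 seeds.
`axisbreak.battery.calibrate` re-scores any candidate set against the
battery (seed ensembles, 80% pass criterion with the unperturbed
experiment as a mandatory gate) so the certification is reproducible.

Battery protocols integrate the unperturbed phase to `t = 1200`
factor-lifetimes with `dt = 0.1`: multipolar transients (the faster
two-wave mode) coarsen into the single bipolar pattern by `t ~ 1000`, and
RK4 at this step is far below the accuracy the readouts probe.  The
library-level `integrate` keeps the conservative `dt = 0.01` default for
high-accuracy work.

The experiment battery encodes ensemble statistics over 20 seeds with an
80% pass criterion: the wet-lab penetrance the model mirrors is itself
partial (roughly half to nine-tenths of embryos respond in the grafting
experiments), so demanding every seed to pass would be a stricter standard
than the biology meets.

## What the synthetic fixtures do and do not show

`axisbreak.fixtures` generates idealized circular expression profiles
(uniform, von-Mises bumps, k-modal, step blocks) with known ground truth.
They exist so the pattern metrics — domain calling, polarity index, B–V
correlation, streak prediction — are tested independently of the
simulator: a metrics bug cannot hide behind a dynamics bug.  They emulate
only the *geometry* of expression patterns (smooth circular bumps with
controlled separation and noise), not the dynamics, growth, cell movement,
or measurement noise of real in-situ data; passing fixture tests says the
readouts are computed correctly, not that the model describes embryos.

## Pattern metrics

Domains are called by relative thresholding: cells above
`min + 0.5 * (max - min)` form candidate arcs; arcs separated by at most 2
sub-threshold cells merge; arcs narrower than 3 cells are dropped; profiles
with relative range under 5% (or maximum under 1e-6) are flat and yield no
domains.  These defaults make smooth, saturated bipolar fields yield
exactly one domain per ligand.  Predicted streaks are the Vg1 domains
whose peak exceeds an *absolute* threshold — half the Vg1 level of the
V-on uniform attractor — so streak calls are anchored to the model's own
expression scale rather than to each run's maximum.  The polarity index is
the magnitude of the first circular harmonic of the profile treated as a
mass distribution; centroids are circular means weighted by
above-threshold mass.  Classification: no domains = uniform; one B and one
V domain with centroid separation > 2*pi/3 = bipolar; two or more called
domains of a species = multipolar.

## Known limitations

* The ring is 1-D; the disc geometry of the blastodisc, the area
  pellucida/opaca, cell division, and cell movement are all outside scope.
* The model is deterministic ODE per cell with noisy initial conditions by
  default; molecule-count stochasticity is approximated at best by the
  optional multiplicative noise.
* The band-pass BMP4→F_V response is one realization of the paradoxical
  anterior induction; other network realizations could produce the same
  qualitative behaviour and are not excluded by this package's tests.
* The calibrated defaults are one certified point in a large parameter
  space, selected for the qualitative behaviours above; no claim is made
  that they are biologically unique, and quantitative levels are not
  fitted to any measurement.
* The saturated pattern is not a machine-precision steady state: domain
  amplitude breathes slowly and over hundreds of factor-lifetimes the
  Vg1 pole can swap between antipodal positions (a slow standing-wave
  oscillation; the pattern stays bipolar and antiphase throughout, but
  the convergence criterion rarely triggers on the unperturbed ring).
  This is why perturbation fold-changes are referenced to the pre-graft
  state, and it should be read as a model property the present
  calibration does not eliminate — a real embryo's axis, once chosen,
  does not wander.
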