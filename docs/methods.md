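# Methods

## Model

Each cell is a diffuse-interface indicator field φ_i on a shared uniform
periodic grid, evolved by overdamped force balance
τ ∂φ_i/∂t = γΔφ_i + F_i.  The force terms (surface tension through the
double well W(φ) = φ²(φ−1)², eggshell and cell–cell repulsion, pairwise
adhesion, volume constriction, optional noise) are assembled exclusively in
the *transport-contracted* form listed in the README.  The textbook force
expressions contain ∇φ/|∇φ|² factors; contracting them with the ·∇φ of the
transport equation cancels those factors algebraically, and the package
only ever evaluates the contracted result — so nothing is divided by |∇φ|
and the off-interface region (where |∇φ| → 0) needs no regularization.
A unit-test verifies the contracted and literal forms agree on the
interface region to 1e-8.

Assumptions worth keeping in mind:

* **Overdamped mechanics.** Inertia is absent; τ sets the single mobility
  scale.  No intracellular fluid dynamics or biochemistry.
* **Periodic domain.** The Fourier-spectral discretization makes the box
  periodic in all axes.  Scenario builders must keep cells at least two
  interface widths off the box faces; the eggshell (embryo runs) or a
  padded packing region (aggregate runs) guarantees this.  `tanh_ball`
  warns when a seeded cell violates the margin.
* **Division is instantaneous.** A tanh-smoothed plane splits the parent
  field; the sigmoid pair is an exact partition of unity, so the split
  conserves field mass to rounding regardless of the smoothing width ε.
  Division axes and volume ratios are inputs, not predictions.

## Numerical schemes

Three steppers share one right-hand side: explicit Euler, a first-order
stabilized semi-implicit scheme, and a second-order (BDF2-type) stabilized
scheme; the linear γΔφ term is solved per Fourier mode.  Properties used
by the tests: with F = 0 the k = 0 mode is conserved exactly and all other
modes are damped; the first-order update matches its closed-form mode
amplification to 1e-12; the second-order scheme shows observed order 2
(Richardson) on a linear per-mode problem and on a nonlinear single-cell
relaxation.

The stabilization term (coefficient S) trades accuracy for stability.  In
the first-order scheme it acts like an extra viscosity — the effective
time scale stretches by roughly (τ + S·δt)/τ, which is the "overdamping"
inflation of in-silico durations the scalability test measures.  In the
second-order scheme the term enters as a second difference (O(δt²)), so
in-silico durations stay nearly δt-independent and the relative step cost
of a fixed physical transient follows 0.3·δt⁻¹ (fit with R² ≥ 0.95 in the
acceptance suite).  `optimize_stabilization` scans an increasing S grid
(conventional step 0.1) and returns the smallest value whose trial run is
finite and passes a user accuracy predicate.

First derivatives zero the Nyquist mode of even-length axes: its sine
component is unrepresentable and keeping it breaks the mirror equivariance
of the gradient (this showed up as a 1e-4 symmetry violation before the
fix; afterwards mirror-symmetric states stay symmetric to rounding).
No dealiasing is applied by default; the nonlinearities are cubic and the
fields band-limited in practice.

Instability is flagged when any field goes non-finite or exceeds |φ| > 10.
*Cell disappearance* is declared when a field's global maximum drops below
0.5; `evolve` aborts with a structured error carrying the last good
snapshot (scans that want to observe the collapse pass
`raise_on_disappearance=False` or catch the error).

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| γ | surface tension | 0.3 | drives sphericity |
| c | double-well coefficient | 1 (2 in relative mode) | interface width √(2/c) µm |
| g_e, g | eggshell / cell–cell repulsion | 1.0 | |
| M | absolute volume constriction | 1.5e-3 | see calibration below |
| M′ | relative volume constriction | 8.0 | |
| τ | ambient viscosity | 1.0 | |
| S | stabilization | 12.0 | embryo-run value at δt = 2 |
| δt | time step | 2.0 | 1.25 for aggregate runs, 1.5 for late-stage embryo runs |
| κ | noise strength | √5/10 in aggregate scenarios, else 0 | |
| δl | grid spacing | 0.5 µm | 120×60×80 nodes for the embryo box, 128³ for aggregates |

The physical constants are the package's own baseline, chosen by a
sharp-interface analysis and then calibrated once so the free-cell
disappearance threshold falls between R = 4 and R = 5 µm under absolute
volume constriction: a sphere collapses when its target volume falls below
(16π/3)·(γ/(2πM))^{3/4} (balance of curvature shrinkage against the
volume restoring force); diffuse-interface effects shift the measured
threshold upward, and γ = 0.3 with M = 1.5e-3 places it at ≈ 4.5 µm on the
default grid.  The same baseline keeps the relative-mode (M′ = 8, c = 2)
4-µm cell within ~2 % of its 268 µm³ target.  These defaults are
reconstructions: they reproduce the qualitative regime structure, not any
particular organism's measured constants.

Noise semantics: ξ_i is a per-cell, spatially uniform standard-normal
3-vector redrawn each step, entering as −κξ_i·∇φ_i inside the τ-divided
force sum.  No √δt rescaling is applied by default, so the effective
diffusivity depends on δt; `noise_sqrt_dt_scaling=True` opts into the
δt-independent convention.  The noise stream is a deterministic child of
the run seed, separate from the packing stream, so toggling noise does not
change packed initial conditions.

A reporting utility converts in-silico time to in vivo seconds at
0.0036 s per 0.1 in-silico units.

## Division scheduling

v̄ is the RMS velocity of all cell mass centers, sampled every
`check_every` steps (default 10) over the elapsed interval.  Stage
triggers: steady state v̄ < 1e-4 (1- to 4-cell stages), first quasi-steady
state — the first strict local minimum of v̄(t) after centered
moving-average smoothing, default window 51 samples — for the 6/7-cell
stages, fixed duration 15,000 for the 8-cell stage, and equilibrium-or-cap
(v̄ < 1e-4 or 10,000 time units) afterwards.  The smoothing window exists
because the literal derivative conditions dv̄/dt = 0, d²v̄/dt² > 0 are
meaningless on noisy discrete samples; it is configurable.

The bundled lineage fixture encodes the founder structure AB (6
synchronous generations → 64 cells), MS (4 → 16), E (3 → 8), C (3 → 8),
D (2 → 4), P4 (1 → 2) plus the five early P-lineage/EMS divisions: 24
groups, 101 events, 102 terminal cells.  Its division axes cycle the
coordinate directions by generation and its ratios are 0.5 except for
documented asymmetric early divisions — stand-ins, not measurements, so
topology-sensitive conclusions from the fixture are qualitative only.

## Aggregate scenarios

Initial positions come from the random packing relaxation
(r̄_i ← r̄_i + F_boundary + ΣF_ij with k1 = 0.05, k2 = 0.1) iterated until
every pairwise distance ≥ 2R and every wall clearance ≥ R.  Both residuals
decay geometrically *toward* their targets, so an exact inequality never
terminates; clearances are accepted within 1e-6 µm (a picometer — far
below any physical scale).  At the full scale (125 cells, R = 5 µm,
L = 64 µm) the mean iteration count over seeds is ~250-270.  Packing runs
in an inner cube two interface widths off the box faces; the offset keeps
cell surfaces clear of the periodic boundary and changes nothing else
(the update rule is translation invariant).

Contact is defined by the overlap integral ∫φ_iφ_j dr > θ_c with
θ_c = 1 µm³ by default (exposed everywhere).  Cells packed at contact
distance retain a diffuse-tail overlap of up to ~1-2 % of a cell volume at
interface width 0.5 µm — the "disjoint" initial condition is disjoint at
the θ_c scale, not to machine precision.  The scenario presets encode the
adhesion programs: separation σ_11 = σ_22 = 0.9, σ_12 = 0.5; layered
σ_11 = 0.9, σ_12 = 0.5, σ_22 = 0.3; dissociation a uniform residual 0.3
(dropping to 0 via `dissociate`).  The contact-dependent differentiation
rule relabels every type-1 cell touching a type-2 cell at the trigger time;
the new type keeps the old mechanics.  Ablation removes cells below the
domain mid-plane and then any cell disconnected from the largest contact
component.

## What the synthetic scenarios do and do not show

The generator produces idealized conditions: spherical initial cells of
one radius, binary adhesion programs, spatially uniform noise, pseudo-
synchronous division groups, stand-in division axes.  Real embryos and
engineered aggregates have size dispersion, graded adhesion, measured
axes, and signaling dynamics none of which are modelled.  Passing tests
demonstrate that the numerics (schemes, division, scheduling, packing,
contact metrics) implement the stated model faithfully and that the
model's qualitative regimes (disappearance threshold, sorting, core-shell
ordering, self-repair topology) appear under the stated programs — not
that any particular biological measurement is reproduced.

## Problem sizes in the test suite

The test and acceptance suites run desk-scale versions of the study
conditions, chosen as the smallest systems that still exhibit each
behaviour: single-cell disappearance scans on a 48³ grid (24-µm box);
scheme-scalability and adhesion checks with two 4-µm cells on 48×32×32;
sorting with 16 cells and layering with 14 cells of R = 2.5 µm on a 40³
grid over 3 seeds, evolved for 500 and 1500 in-silico time units
respectively (durations picked from pilot runs as the point where the
ordering signal is established across seeds); the packing statistic alone
runs at full scale (125 cells), since it involves no fields.  Full-scale
field simulations (102-cell embryo, 125-cell aggregates for 50,000 time
units) use the same code paths unchanged and are hours-long runs.

## Known limitations

* Periodic boundaries only; no adaptive or non-uniform meshes.
* No energy bookkeeping — the model is posed at the force level, so there
  is no discrete energy decay guarantee to monitor.
* The quasi-steady detector depends on its smoothing window; very short
  stages can escape detection and fall through to the cap.
* Asymmetric σ is accepted by the data model (directed attraction), but
  all bundled scenarios use symmetric programs.
* `contact_map` is O(N²) in bounding-box overlaps; fine for ~10² cells,
  not for thousands.
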