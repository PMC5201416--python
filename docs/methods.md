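# Methods

`il2field` models how the *mode* of IL-2 secretion — binary (all-or-none) per
cell versus graded per cell — shapes antigen-dose-dependent activation of T
helper (Th) and regulatory T (Treg) cells in a secondary lymphoid organ, and
provides the statistical machinery to analyze the single-cell cytometry that
motivates the model.  This note records the model, the calibration, every
deliberate numerical and design choice, and what the synthetic data do and do
not establish.

## 1. The statistical stage: binary vs graded calls

Flow-cytometry fluorescence is modeled throughout on the log10 scale.  For a
condition (population × antigen dose × time × marker):

1. **Hartigan's dip test** on the log-transformed values decides whether the
   distribution departs from unimodality.  The dip statistic is the sup-norm
   distance between the empirical CDF and the nearest unimodal CDF.  Our
   implementation uses the classical modal-interval iteration on the ECDF's
   greatest convex minorant / least concave majorant envelopes; it is verified
   in the test suite against an independent oracle that computes the dip
   directly from its definition (LP feasibility of a unimodal function inside
   the tube `[F−d, F+d]`, bisected over `d`).  P-values come from a bootstrap
   under the uniform null of equal sample size — the classical calibration;
   the null table depends on `n` only and is cached.
2. **Gaussian-mixture deconvolution.**  Only when the dip rejects (p < 0.05)
   is a two-component mixture fitted (EM; best of 20 restarts, tolerance
   1e-8, variance floor 1e-4 in squared log10 units to prevent singular
   collapse).  The *percent positive* is then 100× the weight of the
   higher-mean component, and the component means are the mode expression
   values.  Model selection by information criteria is deliberately not used:
   the two-component model is entered only on dip rejection.
3. **Graded conditions** have no mixture split, so percent-positive is gated:
   the gate is the 99th percentile of the matching unimmunized (dose-0)
   condition, mirroring how cytometry gates are set from negative controls.
   This gate has a built-in 1% false-positive rate by construction.

Quartile conditioning splits a condition's events into four equal-count
quartiles of a conditioning marker (c-Fos, NFATc2) and reports the
IL-2-positive fraction per quartile, positivity being posterior membership of
the mixture's upper component.

The CFSE summary uses cohort correction: observed generation-`i` counts are
divided by `2^i` to count precursors, and the precursor frequency of dividing
cells is `100 · Σ_{i≥1} m_i / Σ_{i≥0} m_i`.  It is exactly invariant to
rescaling all counts.

## 2. The synthetic-cytometry generator (the stated world)

No public dataset exists for this system, so the generator *is* the data
source, built to encode the qualitative and quantitative structure reported
for the murine adoptive-transfer experiments.  All fluorescence is
log10-normal per component.

* **IL-2 (secretion assay), transgenic Th:** two components with
  dose-independent locations (log10 0.8 and 2.2, spreads 0.25/0.30).  The
  antigen dose moves *only* the upper-component weight:
  `w⁺ = p_max · φ̂(A) · T_pos(t)` with `p_max = 0.75` — at the maximal dose
  (2 mg) and 14 h, 75% of Th cells secrete IL-2.  Treg and endogenous
  populations do not produce.
* **CD25:** one component whose location shifts with dose (graded).  The
  transgenic-Th shift is *derived*, not hand-set: the anchored 95% CD25⁺ at
  (2 mg, 14 h) against the dose-0 99th-percentile gate fixes the shift via
  `shift · T_rec(14) = (z_0.99 + z_0.95) · sd`.  Treg baseline (log10 2.2)
  exceeds Th baseline (1.5) — constitutive CD25 — and shifts moderately
  (0.5 log10).  Endogenous cells never upregulate.
* **p-STAT5:** two components; maximal upper weights 0.11 (Th_tg), 0.50
  (Treg_tg and Treg_endo), 0.01 (Th_endo, "almost none"), scaled by
  `φ̂(A)` so STAT5 signaling tracks the producer fraction across doses.
* **CD69:** three states (negative / intermediate bystander / high).
  Transgenic cells populate the high state with dose; endogenous cells show
  only the intermediate bystander state and only after immunization.
* **c-Fos / NFATc2:** log-normal with an event-wise location shift coupled to
  the cell's IL-2-positivity indicator (+0.5 log10 for c-Fos, 0 for NFATc2),
  so the probability of IL-2 production correlates with c-Fos but not NFATc2.
* **CFSE:** each of `n` precursors divides with probability `f` (defaults:
  background 0.10; at the 500 µg dose 0.94 for Th, 0.65 for Treg); a
  divider's generation is drawn from a supplied distribution and contributes
  `2^i` observed cells.

**Time factors.**  The *measured positive fraction* uses a trapezoidal window
(ramp 0–6 h, plateau 6–18 h, gone by 24 h): a capture assay scores a cell
positive while expression is ongoing, so the 14 h measurement sits on the
plateau.  This deliberately differs from the model's instantaneous
secretion-rate factor `T_sec` (§3): using the triangular rate profile for
measured positivity would contradict the anchored 75% at 14 h
(T_sec(14) = 0.44).  CD25 locations follow the receptor factor `T_rec`.

**Dose → stimulus.**  `A = dose / 2000 µg`, linear, since doses enter the
model only through normalized stimulus.  Dose dependences are "rescaled Hill"
curves `w(A) = A^h (1+A50^h)/(A^h+A50^h)`, chosen over the textbook Hill form
so the ceiling is attained exactly at `A = 1` (the invariant φ(1) = p_max
cannot hold otherwise).  Default `A50 = 0.0625` (125 µg) and `h = 1`
interpolate the reported dose series; intermediate-dose weights are
interpolation, not published values.

**What a green test establishes.**  Round-trip tests (generator → analysis)
establish that the statistical stage is correct and calibrated, *given*
log-normal mixtures with independent events.  Real cytometry has spillover,
autofluorescence, debris/doublets, per-mouse effects and non-Gaussian tails —
none of which are emulated, so green tests here do not validate the pipeline
against instrument artifacts.

## 3. The spatial reaction-diffusion model

A population of T cells (discs of radius 5 µm) is placed uniformly at random
without overlap on a circular domain (default radius 200 µm; 10% Treg).  The
IL-2 concentration `u(x, t)` (pM) obeys

    ∂u/∂t = D Δu − d_UR · IL2R_bg · u/(u + k),

with absorbing (Dirichlet, u = 0) outer boundary; the sink is homogeneous
background consumption by unspecific CD25⁺ cells.  Producer cells inject flux
`IL2_max · f(A,t) / c_cell` on their boundary; consumer cells remove
`IL2R_max · g(A,t)/c_cell · u/(u+k)`, with `c_cell = 2πr` and half-saturation
`k = (k_deg + k_off)/k_on`.  Time factors: `T_sec` triangular (0→9→18 h)
inside `f`; `T_rec` triangular (0→18→30 h) inside `g`; simulations run 48 h,
covering both pulses.

**Scenarios (equal total secretion).**
* *binary*: `round(φ(A)·n_Th)` randomly chosen Th secrete at the full rate;
* *graded*: `round(p_max·n_Th)` Th secrete at `φ(A)/p_max` of the full rate.

Each cell boundary carries one condition: **producers secrete and do not
consume**.  This matches the boundary-condition structure of the original
formulation and the experimental observation that IL-2 producers do not
phosphorylate STAT5 (paracrine, not autocrine, signaling); letting producers
consume would trivially activate every producer through its own near field.
Activated fractions are reported over *all* cells of a population (producers,
which accumulate nothing, count in the denominator) because the experimental
p-STAT5 fractions are measured over whole populations.

**Activation.**  Per consumer the absorbed IL-2 is time-integrated
("internalized complex", molecules); a cell is activated when the integral
exceeds a threshold θ.  θ is the *only* fitted parameter of the simulation
stage: a log-scale search (coarse scan over 121 points in [1e-2, 1e8], then
golden-section refinement — the objective is piecewise constant, so a pure
golden section can strand on a plateau) minimizes the summed squared error
between model activated fractions and observed p-STAT5⁺ fractions, jointly
over both populations and all stimuli.

### Parameter regime (all defaults are package choices, not published values)

The published parameter table for the original model is not available, so
defaults were chosen once, on mechanistic grounds, and are fully
configurable:

| parameter | default | rationale |
|---|---|---|
| D | 3.6e4 µm²/h (10 µm²/s) | cytokine-scale diffusivity |
| k_on, k_off, k_deg | 0.004 pM⁻¹h⁻¹, 0.1 h⁻¹, 3.9 h⁻¹ | give k = 1000 pM, see below |
| IL2_max | 3.6e4 molecules/h (10/s) | T-cell cytokine secretion scale |
| IL2R_max | Th 7.5e3, Treg 1.0e4 molecules/h | see below |
| γ_Th(A) | 0.05 → 1 (A50 0.0625) | CD25 on Th requires antigen |
| γ_Treg(A) | 0.80 → 1 | near-constitutive Treg CD25 |
| d_UR·IL2R_bg | 1.6e5 pM/h | screening length ≈ 15 µm, see below |
| slab thickness | 10 µm | volumetric reading of the 2D field |
| cells / domain | 500 / 200 µm (scaled-down runs: 200) | splenic T-zone densities |

Three regime constraints drove these numbers:

1. **Reaction-limited uptake.**  If per-cell demand `IL2R_max/k` approaches
   the diffusive supply coefficient (~2πD·h_slab/ln-factor), cells act as
   perfect absorbers and capacity (hence the Th/Treg CD25 difference) cancels
   out of the uptake.  `k = 1000 pM` with capacities ≤1e4/h keeps demand at
   a few percent of supply, so uptake is proportional to `IL2R·γ·u/k` as the
   Michaelis–Menten term intends.  (k here is an *effective* half-saturation
   of consumption including transport steps, intermediate between the
   high-affinity trimeric and dimeric receptor K_d.)
2. **Paracrine range below producer spacing.**  The background degradation
   sets the screening length `L = sqrt(D·k/(d_UR·IL2R_bg))` ≈ 15 µm, a few
   cell diameters: IL-2 acts locally, so in the binary scenario the cells
   *near* producers activate first and the activated fraction tracks the
   producer number — the mechanism behind the wide linear response range.
   A long screening length makes the field spatially uniform and the two
   scenarios indistinguishable.  (This choice overrides an earlier working
   note to size the background for a fixed ~30% share of secreted IL-2;
   the share is an outcome, not a constraint.)
3. **Overlapping Th/Treg uptake distributions at full stimulus.**  The
   observed ~11% p-STAT5⁺ Th vs ~50% Treg at the maximal dose requires a
   single θ to sit at the Th 89th and Treg 50th uptake percentiles, i.e. the
   Treg:Th capacity ratio at A=1 (default 1.33) must be comparable to the
   positional spread between those percentiles.  At low stimulus the γ
   floors (0.80 vs 0.05) make the ratio ~20, so Treg cells activate at much
   lower antigen amounts than Th — Treg-first activation is preserved.

### Numerics

Finite differences on a square lattice (spacing Δx, default 4 µm) masked to
the disc; nodes outside the disc are Dirichlet-0.  Cells are rasterized
discs; each cell's boundary line flux is distributed uniformly over its
covered nodes (≥1 node guaranteed for Δx ≤ r_cell; Δx > r_cell is rejected so
a cell spans ≥2 nodes across).

Time stepping is backward Euler with the sinks *inside* the linear system:

    (I − dt·(D·L − diag(s))) u_{n+1} = u_n + dt·src,

where `s` is the Michaelis–Menten sink linearized about a lagged reference
field (`s = a/(k + u_ref)`), re-linearized whenever the field moves 10%
toward saturation.  Splitting the sink from diffusion is *not* an option
here: with a stiff background sink the reaction substep equilibrates within
each step and the effective screening length degenerates to the diffusion
length per step `sqrt(D·dt)` — activated fractions then depend strongly on
dt.  The coupled scheme is verified dt-converged (identical fractions at
dt = 0.1/0.05/0.025).  Grid refinement: halving Δx from 4 to 2 µm moves
activated Th fractions by <1 percentage point at the calibrated threshold,
but Treg fractions by ~3-4 points — per-cell uptake integrals carry a few
percent discretization error (5 µm cells rasterized on a 4 µm lattice,
near-producer K0 profiles marginally resolved at L ≈ 15 µm) and the Treg
uptake distribution is dense near the operating threshold, so small uptake
shifts translate into visible fraction shifts.  An anti-aliased
rasterization halves this but perturbs the calibration landscape; it was
not adopted (see the ledgered analysis).  Treg headline fractions therefore
carry a ±3-4 point discretization uncertainty on the Δx = 4 µm grid.  The
receptor time factor inside `s` is quantized
in steps of 0.05 so the sparse LU factorization is computed once per level
and cached (~20 factorizations per 48 h run, reused on the rising and
falling flanks).

The system matrix is an M-matrix, so `u ≥ 0` holds without clipping.
Removal bookkeeping uses exactly the matrix coefficients, making the global
mass balance (secretion = uptake + background + rim outflux + residual)
exact to machine precision; the test suite asserts ≤0.5% but observes
~1e-15.  A no-sink steady solve is checked against the closed-form 2D
Poisson disc solution `u(r) = Q/(2πD)·ln(R/r)` to ≤5% beyond two cell radii.

Randomness: one master seed; tissue placement and producer selection use
deterministic child seeds per (stimulus, replicate), redrawn for every
replicate.

## 4. Pipeline and calibration flow

`run_full_pipeline` chains: generate events → per-condition summaries → fit
φ(A) from IL-2 percent-positive (floor fixed at 0) and the γ shape from
normalized CD25 mode shifts (population floors from the defaults; only
A50/h are data-driven, since a fluorescence shift fixes the shape but not
the absolute receptor capacity) → run both scenario sweeps → calibrate θ on
the p-STAT5 summaries → report Hill steepness, half-points and 10–90%
linear-range widths per population and scenario.  Outputs are plain
CSV/JSON with SHA-256 digests in a run manifest; a fixed master seed
reproduces every output byte.

## 5. Known limitations

* The activation-curve residuals at intermediate stimuli are visibly larger
  than at the anchors: with 200 cells the Treg curve rises later and steeper
  than the measured p-STAT5 fractions (which rise from ~6% of maximal dose).
  The calibration trades this against matching both endpoint fractions.
* 2D domain with a slab-thickness conversion, no cell motility, no Treg
  clustering around producers, no STAT5 kinetics, no receptor dynamics
  beyond the single CD25-scaled capacity, no apoptosis.
* Stochastic resolution: scaled-down runs carry 20 Treg cells per tissue, so
  per-replicate Treg fractions are quantized at 5%; headline numbers average
  5 replicates and remain seed-sensitive at the ±3–4 percentage-point level,
  with a comparable grid-discretization uncertainty (see §3 Numerics).
* The dip implementation models the unimodal class as continuous: an atom
  *at the mode* (allowed in the classical definition) is not represented, so
  for samples dominated by a single atom the statistic is an upper bound on
  the classical dip and the test errs toward rejecting unimodality.  The
  package applies the test to continuous log-fluorescence only, and the
  bootstrap null (continuous uniforms) is unaffected.
* Generator events are i.i.d. within conditions; no per-animal random
  effects, so between-mouse variance is not represented.
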