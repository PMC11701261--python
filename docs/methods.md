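# Methods

This note records the model as implemented, the parameter choices that
matter, the numerical decisions taken where the design was genuinely open,
and what the synthetic-fixture tests do and do not demonstrate.

## Polymer model and force field

Chromatin is a Kremer–Grest-style bead-spring chain at 1 kbp/bead; the bead
diameter σ is the length unit, k_BT the energy unit, τ = σ√(m/k_BT) the
time unit, with m = 1 and friction γ = 2 (so the Brownian time is 2 τ — the
system is overdamped on the timescales of interest, while retaining enough
inertia for an efficient timestep).

Energy terms (all separations minimum-image under periodic boundaries):

| term | form | parameters |
|---|---|---|
| excluded volume | WCA: 4[(σ/r)¹² − (σ/r)⁶ + ¼], r < 2^{1/6}σ | between any two beads |
| connectivity | FENE: −(K_f R₀²/2) ln[1 − (r/R₀)²] | K_f = 30 k_BT/σ², R₀ = 1.6 σ |
| stiffness | Kratky–Porod: (l_p/σ)(1 − cos θ) | l_p = 4 σ |
| protein–chromatin | truncated-shifted LJ, depth normalized to −ε | r_c = 1.8 σ, ε per affinity table |
| extruder bond | WCA + k_extr (r − r₀)² | k_extr = 40, r₀ = 1.5 σ |
| crumple bond | k_h (r − r₀)² on (i, i+2) | k_h = 200, r₀ = 1.1 σ |

Decisions the formulas leave open, and what this package does:

- **Truncated-shifted LJ below the minimum.** The single-formula shifted LJ
  is used verbatim for d < 2^{1/6}σ (no splice to WCA); the normalization N
  is found per cutoff by bounded 1-D minimization and cached (N(1.8 σ) ≈
  1.1289). For ε = 0 (non-binding protein states) the interaction falls
  back to plain WCA — the steric-only branch.
- **Multi-mark beads.** A bead may carry several marks; a binding protein
  sees the *maximum* ε among the marks it recognizes (one pairwise
  potential needs one depth, and max preserves strong-site semantics: an
  ATAC + H3K27ac bead binds active proteins at 7 k_BT, not 10).
- **Weak chromatin self-attraction.** 0.4 k_BT between bead pairs where
  *neither* carries H3K27ac, same functional form and cutoff as the
  protein wells.
- **Bonded exclusions.** Nonbonded WCA acts between all pairs except
  directly bonded neighbors, whose WCA core lives inside the FENE bond
  (identical physics, convenient for phantom-chain runs where nonbonded
  interactions are switched off entirely).
- **FENE overstretch** aborts the run with step and bond in the message;
  silent clamping would hide timestep errors.

## Dynamics

The Langevin equations (delta-correlated Gaussian noise, variance
2 γ k_BT) are integrated with the Langevin-middle / BAOAB splitting at
dt = 0.01 τ: half kick, half drift, exact Ornstein–Uhlenbeck velocity
refresh, half drift, half kick. At γ = 0 this is exactly velocity-Verlet,
which is the NVE validation mode (measured dimer energy drift ~10⁻⁶
relative over 10⁴ steps); with the thermostat on the velocity marginal is
exact, so equipartition holds without finite-dt temperature bias. Noise is
pre-generated in blocks by a seeded numpy generator and passed into the
numba kernel — one integer seed makes entire runs bit-reproducible.

Nonbonded forces run over a Verlet pair list (cutoff 1.8 σ + 0.4 σ skin,
O(N²) rebuild when any bead has moved half a skin). The systems this
package targets are a few thousand beads, where the quadratic rebuild is
negligible; the contract is correctness (no missed pair inside the
cutoff), not the search structure.

## Staged protocol

Full-scale stage durations (all scalable by one desk-scale factor):

1. stack-of-rosettes initial conformation; 600 τ under a soft push-off
   U = A(1 + cos(πr/r_cut)) ramped A: 0 → 500 k_BT, harmonic backbone
   (k = 100, r₀ = 1.1 σ) — then FENE + WCA replace them;
2. slow z-compression to the target cube over 10⁴ τ (50 affine slabs);
3. 5×10³ τ with fixed (harmonic-wall) boundaries;
4. 2.5×10⁴ τ periodic — the first 10% re-ramps the soft push-off, because
   opposite wall faces become adjacent at the switch and any face-straddling
   overlap would otherwise explode;
5. 2×10⁴ τ of CTCF-free loop extrusion at 7.5 extruders/Mbp (erases the
   rosette memory);
6. crumple springs added genome-wide, stiffness ramped quadratically to
   k_h over 10⁴ τ (simultaneous full-stiffness switch-on dumps ~10² k_BT
   per bond and breaks FENE bonds at this timestep);
7. proteins inserted (10% of bead count; active:polycomb:HP1 = ¼:⅛:⅝,
   floor per species, remainder to HP1) and equilibrated sterically for
   10³ τ.

Production (3×10⁵ τ) starts from a relaxed state: acetylated crumple
springs are removed (a bond (i, i+2) is dropped if any of the three beads
is acetylated), CTCF boundaries are drawn for the run (activation
probability = peak score / best qualifying score on the fragment; multiple
peaks on one bead enumerate joint outcomes), a fresh extruder set loads at
10/Mbp, chromatin–chromatin attraction switches on at 10⁴ τ and
protein–chromatin attraction at 5×10⁴ τ, and conformations are sampled
every 2×10³ τ over the final 10⁵ τ. The two-tier scheme (N relaxed states
× M production seeds) is `run_protocol`. Extrusion events and protein
state switching interleave with MD every `event_interval` = 100 steps
(Δt = 1 τ per sweep; rates, not cadence, are the physical contract, and
kinetics-only studies may use larger sweeps up to v·Δt = 1 kbp).

The rosette itself is a lobed helix ρ(θ) = R₀ + ΔR cos(mθ), z = cθ
(R₀ = 2.4 σ, ΔR = 1.0 σ, m = 3, c = 0.25 σ/rad), arclength-resampled to
1.1 σ per bead; the parameters are validated purely by the geometric
postconditions (consecutive chords in [0.9, 1.3] σ, center of mass on the
box axis) since the conformation's memory is erased at stage 5.

The simulation-to-real-time mapping is reported in trajectory metadata
(τ_B = 2 τ; τ_B ≈ 8 ms at σ ≈ 25 nm) but never asserted: the two published
anchors (step count vs wall-clock statements) disagree by a factor ~2, so
both are carried as metadata only.

## Extrusion logic

Extruders load at (i, i+3) (a crumple spring may already join i and i+2),
anchors never share beads, and each end steps outward independently with
probability v_extr·Δt per sweep. Blocking is evaluated against the *next*
bead: an end halts one bead short of an active CTCF boundary of opposing
orientation — a forward (+ strand) motif blocks leftward-travelling ends,
a backward motif rightward ones, bidirectional both, which is what makes
captured loops convergent. CTCF and chain-end arrests persist until
unbinding; collision arrests re-test every sweep because the obstacle may
move. Unbinding (rate k_off) instantly reseeds the extruder elsewhere, so
the bound count is constant. Since both ends translocate, the
collision-free steady-state loop is 2λ = 320 kbp (time-average over the
stationary exponential age distribution); the validation suite asserts
this two-sided value.

## Analysis stack

- **Contact maps.** Reads are sampled by picking a structure and a random
  bead pair and accepting with exp(−r/r_t); self-pairs are excluded,
  counts accumulate symmetrically at 1 kbp and are block-summed to coarser
  bins (totals conserved exactly). ICE balancing divides by bias vectors
  until the non-masked row-sum coefficient of variation is below
  tolerance; zero-marginal bins are masked. Comparisons: Pearson of upper
  triangles (optional near-diagonal exclusion band, default none) and the
  directionality score D(i) = (left − right) aggregated contacts within
  20–500 kbp, with edge-truncated windows flagged and excluded from
  D-profile correlations.
- **FISH.** Probe positions are centers of mass of the overlapped beads on
  unwrapped coordinates (a probe straddling the periodic box would
  otherwise produce a spurious center). The physical bead size is fitted
  by a 0.5 nm grid search of the two-sample KS statistic over 10–50 nm
  plus bounded local refinement; the planted-σ recovery test works at the
  5% level.
- **Topoi.** Contact = center-to-center minimum-image distance strictly
  below 3.5 σ; partner (≥10%) and influential (≥50%) thresholds are
  inclusive. The topos extent spans promoter ∪ partners; a partner-less
  gene degenerates to its own 1 kbp bead. Interaction networks are partner
  subsets per structure (the empty subset counts); diversity
  H = S/(q+1) with S the Shannon entropy of network frequencies, so
  H = 0 for a single network and the q = 0 case is well-defined.

## Persistence length of the discrete chain

The bending parameter l_p = 4 σ enters as the per-angle stiffness κ = 4.
For a discrete chain with independent angle Boltzmann weights
exp(κ cos θ) sin θ, the exact per-bond tangent correlation is the Langevin
function coth κ − 1/κ = 0.7507, so the fitted exponential decay length is
−1/ln(0.7507) = 3.49 bonds ≈ κ − ½, *not* κ. The measured value on
simulated phantom chains is 3.4–3.5 σ accordingly; quoting the effective
persistence length of the discretized model rather than the continuum
parameter is the honest reading of the measurement, and the validation
suite documents the offset explicitly. The fit uses variance-weighted
least squares on ln⟨cos θ(s)⟩, s = 1…10 (delta-method weights ∝ ⟨cos θ⟩²),
because the slowly-converging long-s tail otherwise dominates the
log-space fit; the weighted estimator tracks the closed form.

## Synthetic fixtures: scope and limits

The fixture generator emulates the *shape* of real input stacks — ENCODE
narrowPeak/BED dialects, CTCF–RAD21 co-peaks with oriented motif hits,
promoter intervals — for a 150 kbp locus with one gene, strong flanking
enhancers at −8/+10 kbp (typical enhancer–promoter distances), a weak
distal ATAC site, a convergent CTCF pair and flanking repressed domains.
Desk-scale runs (factor 0.01) keep the full protocol structure at 1/100 of
every duration.

What passing tests show: the force field matches its closed forms, the
integrator is symplectic/thermostatted correctly, extrusion kinetics
reproduce their rate constants, bridging produces protein enrichment at
binding blocks, crumpled regions are more compact than acetylated ones,
and the pipeline end-to-end calls planted proximal enhancers as partners
reproducibly across seeds.

What they do not show: desk-scale ensembles are small (≈50 frames/run) and
time-correlated, so per-seed contact frequencies are noisy; the synthetic
locus has none of the peak-width, score and spacing heterogeneity of real
epigenomes; and genome-scale statistics (topos size distributions,
map-vs-experiment correlations) require full-scale multi-Mbp campaigns on
real tracks, which this package supports but its test suite does not run.

## Known limitations

No electrostatics, hydrodynamics, or supercoiling; no explicit cohesin
chemistry (loading bias, bypass); chromosome fragments are simulated in
isolation, so trans and very-long-range cis contacts are absent; the
protein species are generic single-bead bridges.
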