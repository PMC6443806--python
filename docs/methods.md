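# Methods

This package analyses the pH-dependent domain-swapping equilibrium of the
forkhead domain of human FoxP1 (wild type and its H59A mutant) and the
coupled folding problem. It covers five analysis stages: dissociation
kinetics, equilibrium denaturation, proton linkage, coarse-grained folding
simulation, and hydrogen-bond occupancy. All stages operate on data that the
package can generate synthetically, so every estimator is validated by
parameter recovery against a generator whose truth is known.

Physical constants: R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹; the default temperature
is 310 K (the experiments are performed at 37 °C); the Eyring prefactor
k_BT/h is evaluated at the given temperature (6.46×10¹² s⁻¹ at 310 K).

## Dissociation kinetics

The dimer D and monomer M interconvert by 2M ⇌ D with
d[D]/dt = k_on[M]² − k_off[D]. The observable is the dimer fraction in
monomer units, f_D = 2[D]/P_t, matching chromatographic area fractions.
Following standard practice for these experiments, a trace is fitted to a
single exponential f_D(t) = f_eq + A·e^(−k_obs·t) and the decay constant is
reported as k_off. This is deliberate: the true small-perturbation
relaxation constant of the reversible bimolecular system is
k_relax = k_off + 4·k_on·[M]_eq, and the package exposes this linearization
(`relaxation_rate`) as an oracle to quantify the estimator's bias. For the
pH 6.0-like condition (k_off = 0.033 min⁻¹, K_d = 3.7 μM, P_t = 5 μM) the
single-exponential estimate of the full-amplitude decay sits between k_off
and k_relax, about 20% below k_relax; the test suite asserts exactly this
measured property rather than a smaller nominal figure.

Derived quantities: K_d = 2·P_t·(1−f_eq)²/f_eq (from K_d = [M]²/[D]);
ΔG_d = −RT·ln K_d with a 1 M standard state; k_on = k_off/K_d; Eyring
barriers ΔG‡ = −RT·ln(k·h/k_BT) with rates converted to s⁻¹ and bimolecular
rates made pseudo-first-order by the standard-state concentration
C° = 1 M. With C° = 1 M, ΔG_d = ΔG‡_off − ΔG‡_on holds by construction, and
barrier *differences* are exactly independent of C° and of the time unit.

Fit initialization: f_eq from the final point, amplitude from the first,
k_obs from a log-linear regression over the first half of the trace; up to
five perturbed restarts. Recovery statistics use synthetic traces at the
pH 6.0-like condition on a 2-minute grid to 90 minutes — dense enough to
resolve the ~0.11 min⁻¹ relaxation — with Gaussian noise of 0.02 on the
fraction (truncated to [0, 1], as area ratios are).

## Equilibrium denaturation

Linear extrapolation is used throughout: ΔG(den) = ΔG − m·[den], with the
denaturant grid spanning the experimental 0–6 M range. Three schemes:

* two-state I ⇌ U: f_U = K/(1+K);
* three-state monomer N ⇌ I ⇌ U: populations 1 : K₁ : K₁K₂, normalized;
* three-state dimer N₂ ⇌ 2I ⇌ 2U: K₁ = [I]²/[N₂] carries molar units, so
  the mass balance 2[I]²/K₁ + (1+K₂)[I] = P_t couples the first transition
  to total protein concentration. The positive root is evaluated in the
  numerically stable quotient form, and equals brute-force root finding to
  better than 1e-8 (tested on 1000 random parameter draws). The
  concentration dependence is what shifts the first-transition midpoint
  when the protein is diluted; only the *direction* of that shift is
  asserted, because the midpoint value depends on the convention used to
  define a dimeric midpoint (here: the denaturant at which the monomer-unit
  fractions of N₂ and I cross, found by bracketed root finding).

The signal is Σ_s f_s(a_s + b_s·den) with a linear baseline per species,
including the intermediate (initialized midway between the native and
unfolded baselines). Fits are unit-weighted least squares (replicate sigmas
are used when provided); uncertainties come from the Jacobian covariance
scaled by the residual variance. Initialization takes midpoints from the
extrema of the derivative of a smoothed signal and m from the transition
width. A single noisy curve constrains the dimeric first transition only
weakly — ΔG₁ and m₁ trade against the baselines — so individual estimates
can wander while remaining within their (correspondingly large) reported
uncertainties; the acceptance property is therefore calibration (true ΔG
within 2σ in ≥90% of runs), not point accuracy.

## Proton linkage (Wyman–Tanford)

The pH dependence of a free-energy difference between states A and B is

ΔΔG(pH) = s·(−RT Σ_i ln{[(1+10^(pKaᵢ^A−pH))(1+10^(pKaᵢ^B−pH_ref))] /
                        [(1+10^(pKaᵢ^B−pH))(1+10^(pKaᵢ^A−pH_ref))]})

with pH_ref = 5.0 by default. The explicit sign s is carried because, with
the natural state assignment for the unfolding data (A = intermediate,
B = unfolded), the bare expression yields the opposite sign to the observed
stabilization at basic pH; the fit chooses s by best residual, and results
are canonicalized to s = −1 (exactly equivalent under the A↔B
antisymmetry), which makes "state A" the first-listed state of each pair.
Evaluation uses log1p-style identities and is verified against an
independent binding-polynomial oracle to 1e-12.

Reference free energy: ΔΔG(pH_ref) = 0 forces ΔG(pH_ref) = ΔG_ref. The
measured point at pH_ref is, however, as noisy as any other, so pinning
ΔG_ref to it propagates that one measurement's error into every pKa. The
default is therefore "auto": ΔG_ref is fitted as a free offset whenever at
least three points remain beyond the free pKa values, and pinned otherwise
(e.g. for a three-point series with two free pKa values). Fits are bounded
to pKa ∈ [2, 12], multi-started from a 3×3 grid, and bootstrap resampling
of residuals (200 draws, seeded) provides uncertainties for the short
series typical of these experiments.

The sequential protocol mirrors the two-protein experimental design: stage
1 fits the single titratable residue of the mutant series (H54, the only
histidine left in H59A); stage 2 fixes that residue and fits the second
residue (H59) on the wild-type series, keeping the stage-1 sign. Barrier
series are built from rate ratios, ΔΔG‡ = −RT·ln(k/k_ref), which makes them
independent of standard state and time unit.

## Coarse-grained folding model

Each residue is a bead at its Cα position. Native contacts are residue
pairs with sequence separation ≥ 4 whose heavy atoms approach within 6 Å in
the native structure; σ_ij is the native Cα–Cα distance. The potential is

* harmonic bonds (k_b = 200 ε Å⁻²) and angles (k_θ = 40 ε rad⁻²) at native
  geometry, plus cosine dihedrals
  k_φ[(1−cos Δφ) + ½(1−cos 3Δφ)] with k_φ = 1 ε — the conventional Cα
  backbone terms, config-exposed since only "harmonic restraints" is
  prescribed by the underlying model class;
* native 12-10 contacts ε_C[5(σ/r)¹² − 6(σ/r)¹⁰] (minimum −ε_C at r = σ);
* non-native excluded volume ε_NC(σ_NC/r)¹² with σ_NC = 4 Å, ε_NC = ε_C;
* Debye–Hückel electrostatics k_elec·B(λ_D)·q_iq_j·e^(−r/λ_D)/(ε_r·r) over
  all charged pairs with separation ≥ 4, *added to* (never replacing) the
  contact terms. Charges: Asp/Glu −1, Lys/Arg +1, and the titratable
  histidine +1 when protonated. Parameters: ε_r = 80, B = 1,
  k_elec = 332 kcal Å mol⁻¹ e⁻², mapped to reduced units via
  ε_C ≡ 1 kcal/mol. The Debye length is 13.6 Å, the value for 0.05 M
  monovalent salt (λ_D[nm] = 0.304/√I ≈ 1.36 nm; an inverse length of
  0.735 nm⁻¹ states the same screening).

Dynamics: BAOAB Langevin splitting in reduced units (k_B = 1, m = 1),
default friction 1.0, dt = 0.0005; with friction 0 the integrator is
velocity Verlet and conserves energy to < 1e-4 ε over 10⁵ steps. Analytic
forces match central differences to 1e-6 relative (including the dihedral
gradients, validated term by term). Runs are bitwise deterministic per
seed. Q is the fraction of native contacts with r ≤ 1.2 σ_ij.

WHAM: multi-temperature runs are combined on (E, Q) histograms. Because
the inter-temperature bias depends only on E, the density of states
factorizes over energy bins; self-consistent iteration stops when every
per-run shift changes by < 1e-6. For a single run the profile reduces
exactly to −ln(histogram). The first 20% of each run is discarded as
equilibration.

T_F is defined by equal folded/unfolded populations. For strongly two-state
systems the divide is the barrier top of F(Q); the packaged toy systems are
only weakly cooperative (their F(Q) is shallow), so the folded/unfolded
divide can instead be fixed at a Q value (`q_split`), which measures the
same stability midpoint far more robustly — this is what the protonation
comparison uses. The comparison runs the same topology with the histidine
neutral and protonated, same seeds, five temperatures spanning the
transition, and compares seed-averaged T_F.

The toy system for charge effects is an 18-residue ideal β-hairpin whose
histidine faces a Lys/Arg patch directly across the strand pair (all
native-contact partners, ~5–6 Å), with an Asp/Glu pair at the turn.
Protonation adds ≈ +1.3 ε of screened repulsion inside the folded state
(and much less in the unfolded ensemble), so the fold is destabilized —
the same physics as a protonated histidine packed against positive charge
in a real protein. What passing this test shows is that the model's
electrostatics shift the folding equilibrium in the physically expected
direction; it does not reproduce protein-scale cooperativity, barrier
heights, or the magnitude of the shift in the real system, which would
require the full-size native topology and orders of magnitude more
sampling. Scaled-down defaults (5 temperatures, 10⁵–10⁶ steps, toy
structures) keep simulations desk-sized; full-size runs are configuration
presets, not code changes.

Transition-state contact analysis selects frames with Q within ±0.025 of
the barrier top (or any stated ensemble: native side, unfolded side) and
reports per-contact formation probabilities P(i,j); two charge states are
compared by |ΔP| > 0.10, matching the published thresholding. The window
width for the transition-state ensemble is config-exposed because the
published count of affected contacts depends on it.

## Hydrogen bonds

A donor (N/O with an attached hydrogen, association by < 1.2 Å proximity
since multi-model PDB files carry no bond records) and an acceptor (N/O)
are hydrogen bonded when d(D,A) ≤ 3.0 Å and the angle between the D→H and
D→A vectors is ≤ 20° — the convention of the common trajectory-analysis
tools for this criterion. The alternative convention (deviation of the
D–H···A angle from linearity) is selectable; the two disagree for
geometries near the cutoffs. Occupancy is the fraction of qualifying
frames. The synthetic trajectory generator places a donor–H–acceptor triad
at 2.9 Å/5° in exactly round(occupancy·n_frames) frames and at 4.5 Å
otherwise, so occupancy recovery is exact by construction. Reproducing the
~20% occupancy reported for the H59–N55 interaction from real explicit-
solvent MD is outside desk scope; the analysis here is the measuring
instrument, validated on constructed data.

## Synthetic-data generators

All generators are seed-deterministic (NumPy Generator seeded per call).
The kinetic generator integrates the exact rate equation (LSODA,
rtol 1e-9) or evaluates the idealized exponential; noise is additive
Gaussian on the fraction, truncated to [0, 1]. The unfolding generator
shares the population code with the fitter (the fitter is validated
against independent oracles, not against itself). The pH-series generator
evaluates the linkage model directly. Toy structures are ideal-geometry
helices (2.3 Å radius, 1.5 Å rise, 100°/residue) and two-strand hairpins
(4.8 Å strand separation, 0.6 Å pleat so no bond angle sits at the
degenerate straight-chain geometry) with interpolated backbone N/C/O
atoms — enough
to exercise the all-atom contact definition, not a model of real geometry.
What the generators do not emulate: instrument drift, chromatographic peak
shapes, correlated noise, aggregation, and real unfolded-state ensembles;
recovery tests therefore validate the estimators under their stated
assumptions, not robustness to systematic error.

## Numerical choices

* Quadratic roots are evaluated in cancellation-free quotient forms.
* The linkage expression uses logaddexp; fits are bounded and
  multi-started; sign degeneracy is resolved by canonicalization.
* WHAM iterates in log space (logsumexp throughout); zero-count bins are
  flagged, never interpolated.
* Zero-friction dynamics use the velocity-Verlet limit of BAOAB rather
  than a separate integrator, so the thermostatted and microcanonical
  paths share one code path.
* Overlapping beads (r < 0.01 Å) and diverging energies (|E| > 10⁶ ε)
  raise explicit errors with the offending step.
* Ties in barrier location are broken toward higher Q.

## Known limitations

* The single-exponential k_off is a biased estimator of the true
  relaxation constant (quantified above); this mirrors the published
  analysis rather than improving on it.
* The dimeric first transition of a single unfolding curve is weakly
  identified; meaningful constraints need multiple protein concentrations.
* The printed midpoints of the dimeric transition (1.3 M/0.6 M at
  15 μM/3 μM) are not reproducible from the printed ΔG₁, m₁ under any
  standard midpoint convention; only the direction of the shift is
  asserted.
* The toy folding systems are weakly cooperative; transition-state
  analyses on them exercise the machinery, not protein physics.
* pKa uncertainties from 3–5-point series are bootstrap estimates and
  should be read as orders of magnitude.
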