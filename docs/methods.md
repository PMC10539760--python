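# Methods

This note records the models implemented in `ligandconf`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter for reproducing results.

Units throughout: energies in kcal/mol, temperatures in K, rates in 1/s,
frequencies in Hz, angles in degrees on the half-open interval [−180, 180).
The gas constant is fixed at R = 1.9872×10⁻³ kcal/(mol·K) and the Eyring
attempt frequency at k_B·T/h = 2.0837×10¹⁰·T 1/s (≈ 6.251×10¹² /s at
300 K).

## Two-site exchange lineshape

The absorption lineshape of a spin exchanging between sites A and B is
computed from the steady-state transverse McConnell equations. For each
frequency ν the complex 2×2 system

    [R₂A + i·2π(ν − νA) + k_AB,        −k_BA      ] [mA]   [pA]
    [       −k_AB,         R₂B + i·2π(ν − νB) + k_BA] [mB] = [pB]

is inverted in closed form and the signal is Re(mA + mB). Rate convention:
`ExchangeSystem.k_ex = k_AB + k_BA` with detailed balance
`pA·k_AB = pB·k_BA`, so `k_AB = k_ex·pB`. This is unambiguous for unequal
populations and reduces to the familiar equal-population formulas.

For equal populations and negligible R₂ the lineshape reduces to
S(x) ∝ 2cδ²/((δ²−x²)² + 4c²x²) with c = k_ex/2 and δ = πΔν (rad/s), whose
two maxima merge when c = δ/√2. The classical coalescence rate
`coalescence_rate(Δν) = πΔν/√2` is therefore expressed in the
*unidirectional* rate k_AB = k_BA = k_ex/2 — the same first-order rate
constant EXSY measures — and the simulated maxima transition occurs at
k_ex = 2k_c. The regime classifier uses the same convention (slow below
k_c/10, fast above 10·k_c).

Linewidths are measured as full width at half maximum with linear
interpolation between grid points; for a pure Lorentzian FWHM = R₂/π.
Absorption mode only; no phase errors, no scalar-coupling multiplets, no
temperature-dependent shift drift.

## EXSY kinetics and barriers

For a 1:1 rotamer pair the selective-EXSY transferred fraction follows
f(τ) = ½(1 − e^(−2kτ)), where k is the unidirectional rotation rate (the
magnetization-difference decay rate is k_AB + k_BA = 2k). An optional
multiplicative e^(−τ/T1) damping models longitudinal relaxation; the
default is the undamped model (`model_tag="no-t1"`), the simplest form
consistent with first-order kinetics, and the tag records the choice. An
unequal-population generalization f(τ) = p_B(1 − e^(−k_ex·τ)) is provided
but non-default. Fits use Levenberg–Marquardt least squares (lmfit) with
k ≥ 0; all-zero curves return k = 0 with a no-exchange flag rather than an
error.

The Arrhenius fit regresses ln k on 1/(R·T) so the slope is −Ea directly
and the intercept is ln A. Temperature spans below 20 K raise a
`NarrowTemperatureSpanWarning`: a 10 K VT window is standard practice for
keeping a single dynamic process dominant, but it conditions Ea poorly
against rate noise. The "barrier" reported from VT-EXSY is the Arrhenius
Ea; the Eyring free energy ΔG‡ = RT·ln(k_B·T/(h·k)) (transmission
coefficient 1) is exposed separately and the two are never conflated.
Useful anchors, both computed by the package: t½ = 0.5 s at 300 K ↔
ΔG‡ ≈ 17.4 kcal/mol (slow exchange); t½ = 1 ns ↔ ≈ 5.4 kcal/mol (fast
exchange).

## Replica-exchange torsional sampler

With no explicit solvent, replica exchange with solute tempering
degenerates to parallel tempering on the torsional potential, and that is
what is implemented: one torsion angle per walker, Metropolis updates with
uniform proposals of half-width `step_deg`, and neighbor configuration
swaps accepted with min(1, exp[(1/RT_i − 1/RT_j)(E_i − E_j)]). This
preserves the phenomenology solute-tempering MD is used for — barrier
crossing via hot replicas — at desk scale.

Defaults and rationale:

- **Ladder**: geometric spacing T_i = T_min·(T_max/T_min)^(i/(m−1)), which
  keeps neighbor energy-distribution overlap roughly constant; endpoints
  are user inputs (typical ladders: 300–1263 K with 12 replicas,
  300–3302 K with 20).
- **Proposal width 60°**: a quarter turn, of the order of the spacing
  between wells 120° apart, so well-to-well moves are proposed directly;
  low within-well acceptance at 300 K is irrelevant compared to the gain
  in crossing rate.
- **Exchange attempts every sweep**, alternating even/odd ladder edges:
  frequent swaps maximize walker diffusion through the ladder, the known
  best practice for parallel tempering.
- **Seeding**: one `numpy` Generator seeded by the master seed drives
  proposals, acceptances and swaps; identical config + seed gives a
  byte-identical trajectory.

Reports: histograms over [−180, 180) at the base temperature (optionally
evenly subsampled to a fixed frame count, e.g. the routine 1002-frame
report); free-energy profiles ΔG(bin) = −RT·ln(count/max count) with empty
bins masked as NaN, never ±∞; radial (spiral) series mapping sweep index to
radius and angle to azimuth with start/end flagged; and stationary-point
analysis by dense periodic grid scan (0.05° resolution) with bounded Brent
refinement. For a double well with unequal saddles the headline barrier is
the *lowest* escape barrier out of the global-minimum well ("the lower of
the two barriers" convention).

Ergodicity diagnostics assign each base-temperature sample to a well basin
bounded by the saddle angles (ties toward the lower-index minimum), count
inter-well transitions, and flag a run ergodic only if every well with
> 5 % Boltzmann population was visited and at least 10 transitions
occurred. A single 300 K replica in the calibrated 20 kcal/mol double well
is the canonical non-ergodic case: it reproduces the
starting-condition-dependent single-well histograms that motivate checking
simulations against the NMR 1:1 integrals.

## Torsion potential presets

Potentials are cosine series V(φ) = Σ (Vn/2)(1 + cos(n·φ − γ)). Three
presets cover the rigid/flexible spectrum:

| preset | shape | headline barrier |
|---|---|---|
| `hindered_biaryl` | symmetric double well near ±90°, unequal saddles (2-fold + 0.25×1-fold) | 20 kcal/mol |
| `desmethyl` | same shape, low-barrier | 5.5 kcal/mol |
| `flexible_threefold` | pure 3-fold, three equal wells | 3 kcal/mol |

Amplitudes are calibrated by linear scaling so the min-to-lowest-saddle
difference equals the nominal barrier exactly (energy is linear in the
overall amplitude, so one grid scan suffices). The des-methyl barrier is
nominally "below 6 kcal/mol"; 5.5 was fixed once as the representative
value. These analytic profiles substitute for fragment-based force-field
torsion scans; they reproduce barrier heights and well topology, not the
fine shape of real profiles.

## Conformer ensembles, clustering, averaging

Clustering is complete-linkage agglomerative (scipy) under either the
periodic RMS torsion distance (wrapped per angle to [−180, 180]) or
superposed Cartesian RMSD (Kabsch via proper rotations;
`allow_mirror` also tries the inverted copy). The linkage choice is
deterministic and conservative: a cluster's diameter never exceeds the
cut threshold. One representative per cluster is the member minimizing the
summed distance to its cluster mates (nearest-to-centroid), ties broken by
conformer id. With `discard_mirrors`, a conformer whose mirror image
(sign-flipped torsions / inverted coordinates) falls within the threshold
of an already-kept conformer is dropped before clustering — racemic
duplicates from achiral sampling carry no extra information. The RMSD is
computed over all supplied atoms; substructure alignment metadata
(a SMARTS string for the rigid core) is carried but not interpreted, since
coordinates are expected pre-aligned.

Boltzmann populations are softmax(−E/RT), invariant to energy offsets.
Ensemble averages are linear for shifts and couplings and
⟨r⁻⁶⟩^(−1/6) for NOE distances (NOE intensity ∝ r⁻⁶); an r⁻³ option covers
the fast-internal-motion limit. r⁻⁶ is the default.

## Population fitting

The fitter minimizes Σ λ_kind·w_obs·(calc(w) − exp)² over the probability
simplex. The shift/coupling part is convex in w; r⁻⁶ distance averaging is
not, so the solver multi-starts SLSQP from every simplex vertex plus the
barycenter, takes the best SSD, and resolves ties (within 10⁻⁹) to the
lexicographically smallest weight vector — fully deterministic.
Conformers fitted below the pruning threshold (default 1 %, the NAMFIS
tradition) are removed and the fit re-run once. Default kind weights are
1 per ppm², 0.1 per Hz², 1 per Å² — the Hz-scale couplings are
down-weighted so one coupling does not dominate several shifts; all are
tunable per call, since observable weighting in this kind of fit is
implementation-defined. Per-observable `include` flags allow the selective
use of couplings and NOEs.

## Shift-list parsing and rotamer populations

The parser accepts exactly the printed ACD-style dialect
(`δ (mult, J = …, nH[, tag])`, en-dash ranges, `br` prefixes, `isomer1` /
`isomer2` / `isomer1+isomer2` tags). Integrals are exact `Fraction`s so
half-proton rotamer arithmetic is exact; unknown multiplicity tokens are
kept verbatim with a warning; malformed groups raise naming the offending
span; and a group-accounting check guarantees no parenthesized group is
ever silently dropped.

Rotamer populations are reported two ways. The *raw* estimate sums all
singly-tagged integrals per isomer — simple, but sensitive to tag
misprints, which do occur in printed lists (the packaged dimethyl-compound
list contains two methyl singlets both tagged `isomer2` where a
1.5H/1.5H isomer1/isomer2 pair is chemically expected, plus further
inconsistencies; the raw sums come out 8.5H : 10.5H). The *primary*
estimate instead mirrors how a spectroscopist reads a rotamer ratio:
integrate resolved counterpart pairs — the same proton site split into two
signals by the two rotamers. Pairs are recognized greedily in printed
order as two singly-tagged entries with opposite tags, identical base
multiplicity (ignoring `br`), the same number of J values agreeing within
2 Hz, and chemical shifts within 0.5 ppm (typical rotamer splittings are
hundredths of ppm; 0.5 ppm is a generous upper bound). Entries with no
counterpart are excluded and flagged — never silently re-tagged. On the
packaged list the seven clean pairs (NH, benzylic CH, CH₂F, and four
others) give exactly 1:1, matching the spectrum's doubled peaks, while the
imbalance of the unpairable entries is reported as a warning.

## Synthetic data: what it does and does not emulate

Generators are pure functions of configuration + seed and embed their
ground truth in a provenance block. They emulate: first-order two-site
EXSY build-up at 300/305/310 K with the standard eight mixing times
(0.1–2 s) and Arrhenius-consistent rates; VT lineshape stacks crossing
coalescence; the three torsion-potential regimes; and conformer ensembles
whose predicted observables depend trigonometrically on the torsion
(Karplus-like), making distinct conformers spectroscopically
distinguishable and population fits identifiable.

Noise is additive Gaussian on normalized intensities (or on observed
observables), the simplest model consistent with integral noise; real
integral errors also contain baseline and phase components that are not
modeled. No real spectra, no molecular mechanics, no explicit solvent, no
3D structure generation. Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated noise model, not robustness
to every artifact of experimental spectra.

## Problem sizes and tolerances used in the checks

The packaged checks run at desk scale: replica-exchange runs of 1–2×10⁵
sweeps (single replica, 12 replicas to 3300 K, or 8 replicas to 1200 K),
72-bin histograms, 200 noise replicates per EXSY rate, 500 replicates for
the Arrhenius noise study, and 8001-point frequency grids. At these sizes
the Monte-Carlo checks hold with margin (ladder well occupancies within
±0.03 of 50 % across seeds against a ±0.05 band; free-energy profiles
within ≈0.12 kcal/mol against a 0.2 kcal/mol band). Numerical tolerances
on closed-form quantities are at machine precision or the printed
precision of the quantity.

## Known limitations

- Two sites only; no multi-site exchange networks and no full
  Bloch–McConnell longitudinal treatment with per-site T1.
- One torsion per sampler run; coupled multi-torsion potentials are out of
  scope (independent sums only).
- The parser targets one printed dialect; other vendors' formats are not
  recognized.
- The counterpart-pairing rule can mispair accidentally degenerate signals
  in pathological lists; all pairings are returned for inspection.
- Population-fit identifiability depends on the observable design; with
  fewer independent observables than conformers the simplex optimum is a
  face, and the deterministic tie rule picks one point of it.
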