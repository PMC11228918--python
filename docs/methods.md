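# Methods

`prenuc` analyses prenucleation clustering of a small-molecule solute
(the packaged constants describe salicylamide in methanol, acetonitrile
and ethyl acetate) along four connected threads: sizing clusters from
photon-correlation decays, quantifying cluster occupancy and growth
kinetics, comparing cluster sizes with classical-nucleation-theory
(CNT) critical nuclei, and re-implementing the standard
molecular-trajectory analyses (distance-cutoff clustering, radial
distribution functions, hydrogen-bond lifetimes, ring-stacking
landscapes, pair energies) as standalone operators on plain-text
trajectories. Every stage can be exercised end to end on synthetic data
with embedded ground truth.

## DLS sizing (`prenuc.dls`)

The measurement model is the second-order cumulant expansion of the
normalized intensity autocorrelation:

    ln(g2(τ) − 1) = ln β − 2Γτ + µ₂τ² ,

fitted by weighted least squares with χ² weights (g2−1)², which
counteracts the noise amplification of the log transform in the decay
tail. The default fit window keeps lags where g2−1 ≥ 0.1·max(g2−1),
standard practice for excluding the noise-dominated tail. The Z-average
decay rate Γ converts to a translational diffusivity D_t = Γ/q²
(q = 4πn sin(θ/2)/λ) and then to the solvodynamic diameter through
Stokes–Einstein, D_h = k_B·T/(3πη·D_t). The polydispersity index is
µ₂/Γ², clamped at zero when tail noise drives the fitted µ₂ slightly
negative.

Defaults emulate a backscatter instrument: λ = 633 nm, θ = 173°,
T = 298.15 K, η = 1 mPa·s, solvent refractive index supplied per
configuration. All are overridable. Only single-angle cumulant sizing
is provided — no regularized inverse-Laplace distributions, no
multi-angle analysis.

Note the inversion direction: at fixed measured Γ, a larger solvent
viscosity implies a *smaller* inferred diameter (η sits in the
denominator through D_t), and the fit recovers (β, Γ, µ₂) to machine
precision on noise-free single-exponential input.

## Cluster occupancy and growth kinetics (`prenuc.growth`)

A cluster of solvodynamic diameter D is modeled as a solute-dense
sphere, so its occupancy is

    N(D) = (π/6)·D³/ϑ ,     ϑ = 0.169 nm³/molecule.

At the measured micrometer scale this yields ~10⁸ molecules for a
400-nm cluster. Literature discussions of similar systems sometimes
quote 10³–10⁴ molecules for such clusters; that is inconsistent with a
solute-dense sphere at this diameter, and the package deliberately
implements the formula as defined rather than guessing a corrective
packing fraction. Reported occupancies should be read as *upper bounds*
under the solute-dense assumption.

Growth rates are simple forward differences of N between consecutive
measurements, reported at interval midpoints, with the midpoint radius
taken as the linear interpolation of D/2. The mechanism diagnostic
compares two candidate ratios:

* diffusion-limited attachment: dN/dt ∝ r, so (dN/dt)/r is flat in time;
* interface-transfer-limited attachment: dN/dt ∝ r², so (dN/dt)/r² is flat.

Each ratio gets a dimensionless trend = slope × time-span / mean level.
The slope and mean are estimated by **generalized least squares** rather
than ordinary least squares: under a constant relative size error
(which is how sizing noise behaves), the absolute noise of ΔN/Δt grows
with N while the increments shrink, and adjacent differences share an
endpoint and are therefore negatively correlated. The GLS covariance is
tridiagonal and known up to a scale factor that cancels, so no noise
magnitude has to be supplied. With plain OLS the trend statistic is
dominated by differencing noise at a 3-h sampling interval;
GLS restores full power (200/200 correct classifications per mechanism
at 2% size noise in the test suite).

Classification: the mechanism with the smaller |trend| wins, provided
that trend is flat in absolute terms (|trend| < 0.25) and the two
|trends| differ by at least 0.1; otherwise `indeterminate`. Both
thresholds are explicit and configurable (`RegimeThresholds`), because
"looks flat" is inherently a judgment call that must be auditable.

Saturation handling: S = x/x* labels conditions under-, exactly-, or
supersaturated; cluster sizes at a target S (default 1.05) are obtained
by piecewise-linear interpolation of measured (S, D_s) points, with
extrapolation allowed but flagged. Interpolation is linear in S, not
ln S. Note that two-point linear interpolation of the packaged measured
sizes does **not** reproduce some historical interpolated values quoted
alongside this data set (e.g. 2259.8 nm here vs 2046 nm quoted for
ethyl acetate at S = 1.05); the exact point set behind those quoted
values is not recoverable, so the package reports its own rule's result
and labels it `computed`.

Units are fixed: D in nm, t in h, N dimensionless, rates in molecules/h.

## CNT quantities (`prenuc.cnt`)

Driving force ΔG = RT ln S (J/mol, R = 8.314) and Gibbs–Thomson
critical diameter

    D_c = 4·γ·ϑ_m / (RT·ln S) ,

with γ in mJ/m² and ϑ_m = 1.01853×10⁻⁴ m³/mol. The quantity printed as
a "molecular volume" in the source tables carries molar-volume units
and is treated as a molar volume; that convention reproduces every
reference D_c cell to the printed 0.01 nm. The packaged study
temperature is 25 °C (298.15 K): with T = 298 K exactly, several
reference cells land 0.01 nm high, so the tabulated values were
evidently computed at 298.15 K even where "298 K" is printed. No
activity-coefficient correction is applied, matching the reference
values. Unit conversions (mJ/m² → J/m², m → nm) are centralized in
`prenuc.constants` and covered by exactness tests, since Eq-level unit
mixing is the main silent-bug risk here.

Cross-solvent relations (cluster size vs driving force, vs γ, vs D_c;
γ vs solvation free energy and vs carbonyl IR peak) are reported as
descriptive OLS lines with Pearson r and **no p-values**: with three
solvents, inference would be theater.

## Trajectory operators (`prenuc.md`)

Trajectories are extended XYZ (comment line `box Lx Ly Lz time t_ps`,
nm/ps units), topologies are flat per-atom CSVs with masses, charges,
Lennard-Jones parameters, molecule assignments, donor/acceptor roles
and ordered 6-atom ring lists. Boxes are orthorhombic only; triclinic
input is rejected rather than mishandled. All distances use the
minimum-image convention (verified against 27-image enumeration).

* **Clustering** — single-linkage components of solute molecules;
  molecules are connected when the minimum heavy-atom pair distance is
  ≤ 0.35 nm (inclusive). The linkage atom set is configurable
  (heavy/any/COM) because "distance between molecules" is convention-
  dependent; heavy-atom minimum is the default. Contacts come from a
  periodic k-d tree; components from a sparse connected-components
  pass. Labels are deterministic (smallest member id). A per-frame
  count series gets a second-order polynomial fit when ≥3 frames exist.
* **RDF** — center-of-mass g(r) with mass-weighted, PBC-unwrapped COMs,
  bin width 0.02 nm by default, r_max = 3 nm, reference density
  N_b/⟨V⟩ (N_b−1 for identical groups). r_max beyond half the smallest
  box edge is an error, not a truncation.
* **H-bonds** — donor–acceptor distance ≤ 0.35 nm AND the angle at the
  donor between donor→H and donor→acceptor ≤ 30°, both inclusive so the
  criterion is reproducible bit-for-bit. Lifetime curves come in
  continuous-survival (default) and intermittent-autocorrelation
  flavors; both start at 1 and the continuous curve is a lower bound on
  the intermittent one. Which definition a given published P(t) used is
  often unstated, so both are provided and labeled.
* **Stacking landscape** — for every solute pair, ring-centroid
  minimum-image distance vs inter-ring-plane angle, histogrammed on a
  5° × 0.01 nm grid (distances capped at 1.5 nm) and Boltzmann-inverted:
  F = −k_B T ln(P/P_max), zero at the modal bin, +∞ (masked) in empty
  bins — −ln 0 must never silently clip. Ring normals are **circulation
  (Newell) normals** of the ordered ring-atom list: deterministic,
  rotation-equivariant, and genuinely oriented, so parallel stacks with
  opposite circulation appear at 180° rather than folding onto 0°. A
  least-squares plane normal has an arbitrary sign, which makes
  landscapes irreproducible bin-for-bin; that is why it is not used.
* **Pair energies** — plain-cutoff Coulomb (f = 138.935458
  kJ·nm/(mol·e²)) plus 12-6 Lennard-Jones with Lorentz–Berthelot
  combination, summed over inter-group atom pairs and normalized per
  group-a molecule. No Ewald/PME, no bonded terms: this is a
  configuration-comparison diagnostic, not a force-field evaluation.

## Synthetic data (`prenuc.synth`)

Generators define the study conditions and embed their ground truth in
their return values; recovery tests read truth only from there.

* **Growth series** — integrates dN/dt = a·r (diffusion) or b·r²
  (interface transfer) with solve_ivp at rtol 1e-8; both laws have
  closed forms (r² linear in t, resp. r linear in t) used as
  independent oracles on the integrator. Defaults: initial diameter
  400 nm, sampling every 3 h over 72 h (the cadence of the emulated
  sizing experiments), multiplicative Gaussian size noise σ = 2%
  (instrument repeatability), and rate constants a = 10⁶
  molecules/(h·nm), b = 1.2×10³ molecules/(h·nm²) chosen so the series
  grow from 400 nm to ≈2700–2800 nm over 72 h, the range spanned by the
  measured data.
* **Correlograms** — truncated second-cumulant decays for a known
  diameter with additive Gaussian noise; lags log-spaced over ~2.5
  decay times, inside the range where the quadratic term still decays.
* **Planted configurations** — a rigid 12-atom planar solute template
  (benzene ring, carbonyl acceptor, amide N–H donor, hydroxyl O–H
  donor/acceptor) chained so consecutive heavy-atom gaps are 0.30 nm
  (< cutoff) within clusters, with clusters placed ≥ cutoff + 0.30 nm
  apart: the single-linkage partition at 0.35 nm *is* the plan, by
  construction. Solvent molecules are single-site dummies (clustering
  and RDF tests need no solvent chemistry; H-bond tests use solute
  topologies). Optional scripted merges fuse one cluster onto another
  at a given frame, dropping the count by exactly one. Packing
  infeasibility raises an error rather than silently overlapping.
* **Telegraph bonds** — independent two-state Markov chains sampled on
  the frame grid, all starting present; with zero reforming rate the
  continuous survival is exactly exp(−kt) at the sampled times.

What the synthetic data does *not* emulate: real solvent structure,
force-field energetics, nucleation events, plateau physics of measured
growth curves, or the actual trajectory observables of the emulated
simulations. Passing recovery tests therefore demonstrates the
correctness of the estimators and operators, not the reproduction of
any laboratory measurement. Measured quantities (cluster sizes,
solvation free energies, IR peaks) are consumed as provenance-labeled
inputs and never recomputed.

## Numerical choices and degenerate inputs

* Cumulant fits require ≥10 window points, a positive decay head, and a
  well-conditioned design matrix; violations raise typed errors.
* Regime diagnostics need ≥4 points; constant series give all-zero rate
  ratios and classify `indeterminate`; NaNs are rejected.
* Interpolation rejects duplicate S values; extrapolation is flagged,
  not forbidden.
* Cluster detection treats the contact cutoff inclusively; coordinates
  landing exactly on the upper box face are wrapped to 0 before the
  periodic tree is built.
* Degenerate (collinear) rings are skipped per pair with a count kept
  on the landscape result.
* Lifetime curves on non-uniform frame grids use actual mean lag times
  per frame offset.
* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bitwise-identical outputs.

## Problem sizes in the shipped checks

The packaged verification suite runs at desk scale, chosen as the
smallest sizes at which each statistical band has comfortable power:
200 growth series per mechanism, 100 correlograms, 50 random frames of
≤20 molecules for the clustering oracle, 600 uniform molecules × 50
frames for RDF flatness (0.1-nm bins put the ±5% band beyond 4σ of
counting noise), 2000 telegraph bonds, a 70/30 planted stacking mixture
of 100 pairs, and 50-atom frames for energy brute-force comparisons.

## Known limitations

* The solute-dense-sphere occupancy overestimates molecule counts if
  real prenucleation clusters are solvent-rich.
* Single-angle cumulant sizing reports a Z-average; strongly bimodal
  populations yield an intermediate Γ (tested) and a large PDI, not two
  sizes.
* The regime diagnostic assumes one mechanism over the full window; a
  crossover series will tend to `indeterminate`.
* Plain-cutoff electrostatics are not quantitative for charged systems.
* The 12-atom template makes no force-field fidelity claims; energies
  on synthetic configurations are for operator verification only.
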