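# Methods

`ivdflow` models the fluid-driven (poroelastic) viscoelasticity of the
human lumbar intervertebral disc at population scale.  This note documents
the model, its assumptions, the numerical choices, and the boundaries of
what the package's tests demonstrate.

## The scientific question

Disc viscoelasticity under slow loading is dominated by interstitial fluid
flow driven by coupled osmotic and mechanical pressure gradients.
Degeneration attacks both drivers at once: glycosaminoglycan loss lowers
the fixed charge density (FCD) and hence the Donnan osmotic pressure, and
cartilage-endplate (CEP) calcification lowers the permeability of the main
fluid route.  The pipeline asks how these changes — and the magnitude of
the applied compressive load — reshape swelling, creep, and
stress-relaxation behavior across a realistic population of disc
geometries.

## Population model

Five geometric features are independent Gaussians (means/SDs from
published lumbar morphometry): disc height 10.21 ± 1.8 mm,
anterior–posterior length 37.5 ± 6.21 mm, lateral width 55.5 ± 6.3 mm,
nucleus pulposus (NP) volume ratio 39.3 ± 5.5 %, wedge angle 7.82 ± 6.07°.
A Latin hypercube draws one sample per equal-probability stratum per
marginal, **at the stratum median**, with independent random permutations
pairing strata across parameters.  Median placement makes the single-
stratum case collapse to the distribution median and gives essentially
exact first moments at n = 50 (sample SD of the disc-height column is
1.795 mm against the nominal 1.8).  Draws outside physical bounds
(non-positive lengths or angles; NP ratio outside 5–95 %) are replaced by
rejection sampling from the full Gaussian; with the tabulated wedge-angle
SD roughly 10 % of its draws need this, so strict stratification holds for
the other four marginals.

Each parameter set is reduced for the one-dimensional solver: the
mid-plane is an ellipse (area π·APL·width/4), the NP takes
`np_volume_ratio` of it (area ratio equals volume ratio to first order
under linear height fields), the annulus fibrosus (AF) the rest; twenty
mid-point lamella stations carry the AF's linear inner→outer property
gradients; the wedge angle is carried as metadata only, since a uniform
column cannot express wedging.  CEP thickness (0.6 mm) and bony-endplate
(BEP) thickness (1.0 mm) are literature-typical defaults, configurable;
the CEPs are counted inside the disc height, the BEPs outside.

## Constitutive model

Soft tissues (NP, AF, CEP) are biphasic swelling mixtures:

* **Solid matrix** — Holmes–Mow hyperelasticity.  Under the column's
  laterally confined kinematics (F = diag(λz, 1, 1), J = λz) the axial
  Cauchy stress reduces to
  σ = HA·(λz²−1)/(2λz) · λz^(−2βm) · exp(βm(λz²−1)),
  with HA = E(1−ν)/((1+ν)(1−2ν)); zero at λz = 1, slope HA at small
  strain.  BEPs are compressible neo-Hookean with constant permeability.
* **Permeability** — Holmes–Mow,
  k(J) = k0·((J−φ0s)/(1−φ0s))^βm · exp(M(J²−1)/2); the tabulated
  footnote assigns the same βm to solid and permeability laws and is
  followed literally.
* **Osmotic pressure** — ideal Donnan,
  Δπ = ΦRT(√(cF²+4c0²) − 2c0), with deformation-dependent FCD
  cF(J) = cf0·φ0w/(J−1+φ0w), bath concentration c0 = 150 mmol/L and
  T = 298.15 K (room-temperature in vitro convention; configurable).
* **Fibers** — a stretch-only toe-linear law (power-law toe with exponent
  βf up to the critical stretch square I0, then linear with modulus Ef,
  stress- and tangent-continuous at the junction).  Oblique AF collagen
  lies near the transverse plane, so axial confined kinematics barely
  engage it; the law is implemented and unit-tested but enters the column
  only through the CEP's simplified axial modulus Efa = Efap/10 = 0.701
  MPa (I0 = 1 degenerates the toe away, leaving the linear branch).

Degeneration (severe grade) = reduced NP/AF fixed charge density plus
reduced CEP permeability and the CEP's stiffer, altered transport card —
taken cell-for-cell from the published tissue table shipped as package
data (`ivdflow/data/materials.yaml`).

Units: the solver works in the self-consistent mm/N/s/MPa system the
tables are printed in (permeability column scaled by its tabulated 1e−4
factor); `ivdflow.units` provides exact SI round-trips.  This replaces an
earlier plan to convert everything to strict SI internally — the native
table system avoids any conversion in the hot path and round-trips the
published values bit-exactly.

## The reduced-order column

The 3D disc becomes two laterally confined axial columns in parallel — an
NP path and an AF path (AF transport/charge properties averaged over the
twenty lamella cards), each a BEP–CEP–core–CEP–BEP stack over its own
area — kinematically coupled through rigid endplates: bottom fixed, top
plate shared.  Total axial stress σ_solid + σ_fiber − Δπ − p is uniform
along each path; fluid continuity ∂J/∂t = ∂/∂Z(k ∂p/∂Z) holds per layer
with flux continuity at interfaces; p = 0 on the outer faces (immersion in
saline).  Here p is the seepage pressure relative to local osmotic
equilibrium, so drained equilibrium is p ≡ 0 with σ_solid − Δπ balancing
the load.  Node counts per layer are BEP 2, CEP 3, core 10.

Two closures deserve emphasis because they are *not* consequences of the
3D model but necessities of the 1D reduction:

1. **Swelling restraint.**  A confined column converts all osmotic volume
   gain into axial stretch; unrestrained, the mean healthy disc would
   swell ~70 % axially, because nothing represents the hoop fiber tension
   and lateral constraint of the real annulus.  A tension-only linear
   axial stiffness (2.0 MPa, identical for both conditions, as fiber
   properties do not change with degeneration) is added to the soft cores,
   sized once so healthy free swelling settles near the literature-typical
   ~10 % axial strain (1.03 mm on the mean disc).  It carries no load in
   compression.
2. **Relaxation ramp rate.**  The column has no isochoric deformation
   mode, so displacement control demands fluid efflux at the imposed rate.
   The endplate route is choke-limited: as the drained boundary layer
   compacts, its permeability falls exactly as fast as its Donnan pressure
   rises, saturating the flux near 1e−3 mm/s per face.  At the nominal
   laboratory rate (1 %/s) the model has no bounded solution — the
   reaction force diverges.  Relaxation ramps are therefore applied at
   1/300 of the nominal rate (5/10/15 % in 1500/3000/4500 s), still two
   orders of magnitude shorter than the 30 h holds they precede.  Creep
   and swelling are load-controlled and keep the nominal schedules
   exactly (20 N preload at 1 N/s; 500/1000/1500 N in 1/2/3 s).

Consequences: absolute displacement and force magnitudes are surrogate-
level, not reproductions of 3D finite-element values; every time series
carries a `surrogate` metadata tag saying so.  What the reduction *does*
preserve — and what the test suite checks — is the osmotic/transport
mechanism: conservation, analytic consolidation limits, equilibrium
consistency, and the direction of every degeneration and load contrast.

## Protocols

All protocols begin with 30 h of free swelling (fixed charge activated
over 1 s, then load-free immersion).  The roster per disc instance is
free swelling; creep to 500/1000/1500 N from a 20 N preload; relaxation to
5/10/15 % axial strain (of disc height) from a 50 N preload.  Preload
states are equilibrated for 30 h and cached per disc/condition — the 20 N
and 50 N pre-compressed swelling stages are exactly the chained pre-states
of the creep and relaxation tests, and can also be run as standalone
swelling protocols.  Outputs are sampled on a 200-point log grid from 1 s
to 30 h plus ramp endpoints.

## Numerics

Backward-Euler in time with Newton iteration on the coupled
stretch/pressure/path-stress system (analytic Jacobian, dense solve, ~60
unknowns).  Convergence uses a dimensionless row-scaled residual norm
(stress rows in strain units, continuity rows in stretch-increment units)
to 1e−10 relative with one polishing iteration — an unscaled norm stalls
at the roundoff floor of the 16-GPa bony-endplate rows.  Stretch updates
are clipped per component into the admissible box (J > 1−φ0w), which
survives the compaction boundary layers that defeat global step damping.
Rejected steps halve dt down to a 1e−6 s floor.  Ramps use ≥20 uniform
steps; holds grow dt geometrically (×1.2, capped at 600 s).  Discrete
fluid-content change matches boundary Darcy flux to better than 1e−8 per
step, and halving all step caps moves terminal displacements by <0.1 %.

An independent 0D oracle (`equilibrium_0d`) solves the drained-equilibrium
balance per element by nested bracketed root finding; every protocol's
terminal state on the mean healthy disc lands within 0.24 % of it.  The
degenerated disc does *not* fully equilibrate creep within the 30 h hold
(≈3.7 % short at 500 N) — that is the prolonged-equilibration phenomenon
itself, not solver error; extending the hold closes the gap.  A classical
one-dimensional consolidation series (`terzaghi_reference`) provides the
linear-limit benchmark: with no fixed charge, constant permeability and
≤1 % strain the transient matches it within 1 % over Tv ∈ [0.05, 2].

## Rheological decomposition

Hold-phase displacement histories are fitted with the double Voigt model
u(t) = ue + u1(1−e^(−t/τ1c)) + u2(1−e^(−t/τ2c)); relaxation forces with
the double Maxwell model F(t) = F∞ + F1·e^(−t/τ1s) + F2·e^(−t/τ2s).
Time is re-origined to the end of the loading ramp.  All five parameters
are fitted freely under non-negativity bounds by trust-region least
squares from a deterministic 8-start grid log-spaced in (τ1, τ2) over
[10, 1e5] s, with the elastic/residual term initialized from the data;
components are swapped post-fit so τ1 ≤ τ2.  Unweighted residuals on the
log-spaced grid give early-time emphasis through the grid itself.  Fits
with τ2/τ1 < 3 are flagged weakly identified (Jacobian condition number
reported); non-converged fits are excluded from the indicator table and
logged.  The engineering equilibrium time is the first crossing of 95 %
(configurable) of the total hold-phase change, linearly interpolated, with
a monotone-envelope fallback for noisy series.

## Statistics

Indicators (elastic/short/long-term/total displacement, short/long/
equilibrium time, residual/short/long-term force) are compared with the
two-sided Mann–Whitney U test: exact null enumeration for tie-free samples
with n1·n2 ≤ 400, otherwise the tie-corrected normal approximation with
continuity correction (the n = 50 study groups use the latter, as any
standard implementation would).  Benjamini–Hochberg FDR control at
α = 0.05 is applied within each comparison family — all condition
contrasts of one protocol kind form one family, all within-condition
load-pair contrasts of one kind another (configurable to per-indicator
families).  Raw and adjusted p-values are both reported; zeros are floored
at machine epsilon before adjustment.

## Synthetic fixtures

`ivdflow.synthetic` generates double-exponential curves with known ground
truth plus seeded additive Gaussian noise (the solver's curves are
deterministic; noise exists purely to stress the fitters), and Gaussian
indicator datasets with controllable between-group shifts.  These emulate
the *structure* of pipeline outputs, not disc physics: passing recovery
and error-rate tests demonstrates the estimators work on their model
class, not that the solver's curves are double exponentials (they are
only approximately so, with fit RMS errors around 1–3 % of range).

## Problem sizes and runtime

The default study (50 parameter sets × 2 conditions × 7 protocols)
completes in roughly 8 minutes on one CPU, dominated by the transient
solver (~2000 implicit steps per disc instance); the n = 4 pilot takes
about half a minute.  These sizes are the study's own defaults, chosen to
match the published design.

## Known limitations

* 1D surrogate: no lateral bulging, intradiscal pressure maps, 3D stress
  fields, or mesh-level comparisons; absolute magnitudes differ from 3D
  finite-element results by design.
* The NP/AF load split follows from the parallel-path kinematic coupling,
  an explicit modeling choice that cannot be recovered from a 1D model.
* Intrinsic solid-phase viscoelasticity is absent (as in the parent
  biphasic swelling formulation), so short-time damping is underestimated.
* Relaxation ramps run slower than the nominal laboratory rates (see
  above); rate-dependent peak forces are out of scope.
* Only the healthy and one severe degeneration grade are modeled; there is
  no intermediate-grade continuum, and no variance-based sensitivity
  decomposition of the population outputs.
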