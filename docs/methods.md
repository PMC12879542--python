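# Methods

## Scope and model structure

`batchcryst` simulates batch cooling crystallization of α-LGA from water as
a lumped (well-mixed) or compartmentalized process. The state is the solute
mole fraction plus the per-bin crystal volume fractions of a discrete-method
1-D population balance; temperature is imposed by the cooling schedule. The
model deliberately excludes everything that requires a resolved flow field:
momentum and turbulence closures, spatially distributed species/energy
transport, agglomeration and breakage (not significant for prismatic α-LGA
crystals), secondary nucleation, and dissolution (rates are clamped to zero
for σ ≤ 0). Crystallization enthalpy and the heat input of the impeller are
neglected in the thermal balance, and the solution volume is treated as
constant — the slurry never exceeds ~3 vol% solids in the conditions of
interest.

## Thermodynamics

Solubility is the quadratic polynomial in temperature with coefficients
(0.08131, −0.000595783, +1.10258e-6) for the mole fraction of LGA. The
published convention for this polynomial is ambiguous: read with T in °C it
*decreases* over 10–80 °C, which contradicts both the physical behaviour of
LGA in water and the supersaturation levels the source reports (S ≈ 1.5 at
45 °C for the 43 g/kg-water charge). Read with T absolute it is increasing
on the operating range and reproduces S = 1.5568 at 45 °C for mole fraction
0.0052374, so `absolute_kelvin` is the package default and
`celsius_as_printed` is kept only for literal reproduction. A related,
unresolved inconsistency is inherited from the source data: the 43 g/kg
charge is quoted as saturated at 70 °C, while the polynomial (absolute
convention) saturates it at 60.3 °C. The simulator uses the composition as
the ground truth and treats "70 °C" as the *nominal* saturation point when
reporting the metastable zone width, which is how that width is defined
experimentally.

The composition basis is mole fraction on a fixed water inventory, using
M(LGA) = 147.13 g/mol and M(H₂O) = 18.015 g/mol; 43 g per 1000 g water maps
to x₀ = 0.0052374. Crystal density defaults to 1540 kg/m³ (α-LGA literature
value) and the solution volume to (1.043 kg)/(1000 kg/m³); all are
configurable.

## Kinetics

Primary nucleation ṅ0 = kN·σⁿ and linear growth G = kG·σ^g, with σ = S − 1.
G is interpreted as the rate of change of the volume-equivalent *diameter*
(the alternative radius reading would double the deposition rate; the
diameter convention matches the Sauter-diameter bookkeeping used
throughout). Shipped parameter sets: crash-cooling (kN = 4.02e6 #/m³·s,
n = 1.87, kG = 9.76e-8 m/s, g = 2.34) and slow-cooling growth
(kG = 2.80e-7 m/s, g = 1.43, same nucleation law). The growth-law fitter is
ordinary least squares on ln G vs ln σ — the standard estimator for
power-law rate data — returning standard errors for the exponent directly
and for kG by the delta method. Weighted or errors-in-variables fits are out
of scope.

## Discretization and numerics

The volume grid is geometric, V(i+1)/V(i) = 2^q, with q real-valued so a
grid can be pinned to exact diameter bounds (q = 9·log₂10/39 ≈ 0.7666 for
the default 40 bins over 1–1000 μm); integer q reproduces the classic
doubling grids. Growth is the first-order upwind transfer on the volume
coordinate with no inflow into the smallest bin and a **closed top
boundary**: mass reaching the largest bin stops growing rather than leaving
the books, and a logged warning fires when that bin holds more than 1% of
the crystal volume. The scheme conserves particle number to machine
precision (the transfer telescopes) at the price of numerical diffusion —
a seeded monodisperse pulse advances its volume-weighted mean diameter at
1.06×G over a decade of growth on an 80-bin grid, and doubling the default
bin count moves the final Sauter diameter by 3.6%.

Integration uses `scipy.integrate.solve_ivp` (LSODA default) with relative
tolerance 1e-8, absolute tolerance 1e-14 on the mole fraction and 1e-16 per
bin; the nucleation onset makes the system stiff and fixed-step explicit
integration is not viable. Negative bin values produced by the integrator
are clamped in the rate evaluation and clipped afterwards, with the clipped
volume charged to the mass-balance audit. Every simulation reports that
audit — |Δ(dissolved moles) + ρ_s·V_soln·Δφ_T/M| relative to the initial
charge — and the acceptance script refuses to report numbers if it exceeds
1e-6 (typical values are ~1e-11). Tightening the solver tolerances tenfold
moves the supersaturation peak by less than 1e-3.

Trajectory metrics: the S-peak is refined by a three-point parabola in
time; onset is the first 1% relative drop in concentration, linearly
interpolated (the 1% threshold operationalizes a qualitative "starts to
decrease"); the metastable zone width subtracts the interpolated onset
temperature from a caller-supplied nominal saturation temperature. The CSD
mode uses a three-point parabola in (ln d, volume %), and percentiles
interpolate the cumulative volume curve linearly in log diameter, with a
single occupied bin treated as a point mass.

## Multizonal mode

The compartment model is a framework, not a calibrated geometry: zone
volumes, exchange flows, and the heat-removal split are user inputs (a
three-zone top/bulk/wall template with a cold wall layer is provided as a
fixture). Crystals advect between zones at the sending zone's bin
composition — no slip or settling — and enthalpy exchanges with the same
flows assuming equal volumetric heat capacity, so in the large-flow limit
every state, temperature included, collapses onto the well-mixed solution
(verified at 100× and 10000× a reference flow). The per-zone cooling rates
are scaled so the volume-averaged temperature follows the imposed schedule
exactly regardless of the split. A one-zone network is delegated to the
batch integrator outright, since it *is* the well-mixed model.

## Synthetic fixtures

The fixture generators emulate the shapes of the real inputs, not their
noise structure: growth-rate datasets draw σ log-uniformly and apply
multiplicative lognormal noise to an exact power law (real growth-rate data
carry size- and temperature-dependent systematics that this does not
represent); seed populations are lognormal in log-diameter; the equilibrium
case puts the charge exactly on the solubility curve. All randomness flows
through one seeded generator, so identical seeds give byte-identical files.
Passing tests on these fixtures demonstrates correctness of the estimators
and solvers, not the adequacy of power-law kinetics for any particular
compound.

## Known limitations and the trajectory discrepancy

The well-mixed reduction cannot reproduce the published volume-averaged
*trajectory* of the source CFD study with the stated kinetic constants, and
the discrepancy is worth being explicit about. With kN = 4.02e6 #/m³·s, the
crystal surface area present when the batch reaches 45 °C (42 min) is
orders of magnitude too small for solute consumption to overtake the
cooling-driven generation of supersaturation, so the simulated S keeps
rising to ≈ 2.30 at ≈ 64 min before desupersaturating, the onset falls near
59 min (MSZW ≈ 35 K), and S is still ≈ 1.58 at 20 °C — versus the reported
peak of 1.52 at 42 min, MSZW ≈ 25 K, and residual S ≈ 1.07. This is not a
solver artifact: an independent method-of-moments integration of the same
balance reproduces the discrete solver's trajectory, matching the onset
timing requires inflating the nucleation prefactor by roughly four orders
of magnitude, and doing so destroys the final CSD (mean sizes drop to tens
of microns). Conversely, the stated prefactor *is* consistent with the
reported late-stage nucleation rates (kN·0.07^1.87 ≈ 2.8e4 #/m³·s) and
with the reported final CSD: the simulated distribution peaks at 213 μm
(within one geometric bin of the reported 250 μm) with a final solids
fraction of 0.0155, below the reported 0.03 maximum. The trajectory-level
quantities in the published figures therefore appear mutually inconsistent
with the printed rate constants under any volume-averaged reading, and
this package reports what the stated constants actually produce rather
than tuning toward the figures. If the ramp is stopped at 45 °C the peak
necessarily sits at the end of the ramp (41.7 min, S ≈ 1.56), which is the
one reading under which the published peak timing and magnitude are
recovered.

Other limitations: the power laws carry no agitation or temperature
dependence (no Arrhenius factor on kG), so impeller speed affects nothing
in well-mixed mode — the CLI says so explicitly — and enters only through
user-chosen zone flows in multizonal mode; the closed top bin biases very
long growth runs; and the 1-D volume-equivalent size cannot represent
needle-like habits (acceptable for the prismatic α form, not for β).

## Default problem sizes

The shipped defaults — 40 bins, 1001 output samples, LSODA at rtol 1e-8 —
integrate the 83-minute reference batch in well under a second on one core;
the convergence checks double the grid and tighten tolerances tenfold.
These sizes were chosen because the grid-doubling and tolerance-refinement
deltas quoted above show the defaults already sit in the converged regime.
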