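# Methods

## Model and assumptions

The package chains four small physical models. Each is deliberately the
simplest member of its family; the assumptions below delimit where the
predictions can be trusted.

**Neumann equation of state.** Solid surface energies come from the
one-parameter equation of state

    cos θ + 1 = 2·√(γ_S/γ_L)·exp(−β(γ_L − γ_S)²),

with β = 0.000115 (m²/mJ)², an empirical constant validated for low-energy,
non-metallic solids — which covers cell layers and polystyrene but not
metals or high-energy ceramics. No component decomposition (Owens–Wendt,
van Oss acid–base) is attempted: the whole surface chemistry is collapsed
into one scalar γ_S. The measured contact angle is treated as an equilibrium
Young angle; hysteresis, roughness (Wenzel/Cassie) and substrate hydration
effects are outside the model.

**Forward wettability and Young's equation.** Evaluating the same relation
with an ATPS phase tension predicts that phase's wettability factor
(cos θ + 1) on the cell, and Young's equation converts it to an interfacial
energy γ_SL = γ_L + γ_S − (cos θ + 1)·γ_L. When the predicted factor
exceeds 2 the implied contact angle does not exist (complete wetting); the
factor is still fed through the algebra unclamped, because the resulting
small positive γ_SL is precisely the quantity that makes hydrophilic beads'
near-zero bead–dextran energies come out right, and clamping would silently
zero the driving force. Results carry a `complete_wetting` flag instead.

Algebraically γ_SL = γ_L + γ_S − 2·√(γ_L·γ_S)·exp(−β(γ_L−γ_S)²) ≥ 0 by
AM–GM with equality iff γ_S = γ_L; the non-negativity is a structural
property, not a numerical accident, and is property-tested.

**Translocation energy balance.** A cell of radius R crossing the interface
into its preferred phase releases E_driving = 2πR²|Δγ| and dissipates
E = 6πRμ_avg·v · 2R by Stokes drag over the translocation distance 2R at a
constant terminal velocity — no added mass, no interface deformation, no
film drainage, no contact-line pinning. The two-phase environment enters
only through the arithmetic mean viscosity μ_avg = (μ_PEG + μ_Dex)/2.
Balancing gives v = |Δγ|/(6μ_avg) and τ_p = 12·μ_avg·R/|Δγ|. Δγ is kept
signed for phase preference (negative → PEG) but enters times and energies
as a magnitude, since τ_p is a duration.

**Plug-flow residence time.** t_res ≈ L·A/Q assumes cells ride at the mean
fluid velocity. Laminar velocity profiles, the interface streamline
position, and inlet/outlet effects are ignored; for design purposes the
approximation sets the scale, and the safety margins of a plan absorb the
rest.

## Numerical choices

* **Surface-energy solver.** Brent's method on the bracket
  [0.5, γ_L] mJ/m². The wettability factor is strictly increasing in γ_S on
  that interval (checked numerically on a grid in the tests), and any
  contact angle above 0° forces γ_S < γ_L on this branch, so the root is
  unique. Residual tolerance 1e−9; solved energies are kept at full
  precision and rounded only in reports (2 decimals for energies, 4
  significant figures for times).
* **Degenerate inputs.** θ = 0 is excluded (it pins γ_S = γ_L exactly and
  carries no information); angles whose target factor lies below the
  bracket's range raise a no-solution error reporting both bracket
  endpoints. Δγ = 0 raises rather than returning an infinite τ_p.
* **Separation plans.** The target residence time is the geometric mean
  √(τ_fast·τ_slow), which equalizes — and thereby maximizes the smaller
  of — the two relative margins t_res/τ_fast and τ_slow/t_res. The boundary
  tie τ_p = t_res classifies as partitioned, uniformly.
* **Group statistics.** Donor variability uses the sample standard
  deviation (ddof = 1); SEM = sd/√n; both are absent for single-member
  groups. Donor-paired differencing is the default uncertainty propagation
  for Δγ, with sd-quadrature available behind a flag — paired differencing
  respects the fact that the same donor's energy enters both phases' terms.

## Units

Energies and tensions in mJ/m² (numerically equal to mN/m), viscosity in
Pa·s, lengths in metres, times in seconds. β's units (m²/mJ)² make mJ/m²
the natural working unit; conversion from mN/m, mPa·s, µm etc. happens only
in the measurement-table loader. The CLI accepts flow rates in mL/min (the
unit practitioners quote) and converts at the boundary.

## Built-in reference dataset

The fixtures carry the measured PEG/Dex surface tensions at 5–20 % w/v
(PEG 60.00/58.99/58.71/58.12, Dex 70.13/70.88/70.20/69.99 mJ/m²) and the
solved solid surface energies of three healthy chondrocyte donors
(26.75/33.06/27.22), three osteoarthritic donors (18.06/9.01/9.78) and
carboxylated polystyrene beads (65.93 mJ/m²). The deionized-water tension
defaults to 72.0 mJ/m² and is configurable, since reasonable laboratories
use 72.0–72.8 depending on temperature. Published group SDs were evidently
computed from unrounded donor energies, so recomputed SDs from the
2-decimal fixtures can differ by up to ~0.1 mJ/m²; tests allow that.

Cell radii and phase viscosities are **not** fixture data — they are
required user inputs for any quantitative τ_p. The synthetic defaults
(10 µm radius; μ_PEG = 0.05, μ_Dex = 0.025 Pa·s in tests, reflecting PEG
solutions being roughly twice as viscous as dextran at matched
concentration) are placeholders a warning points at, chosen at the typical
chondrocyte/bead scale. Consequently the package asserts the *ordering* of
partitioning times between phenotypes, never their absolute fold-change,
which depends entirely on the measured radii and viscosities supplied.

## Synthetic cohorts

The generator emulates donor-level variation where it physically arises: as
normal noise on the deionized-water contact angle (goniometry's observable),
truncated to (1, 179)° so the equation of state stays solvable, with
default phenotype means of 85° (healthy-like) and 120° (disease-like)
matching the observed wettability split. Radii are drawn from a truncated
normal; setting the radius SD to zero isolates interfacial-energy effects.
All draws derive from one integer seed via numpy's PCG64 generator, so
cohorts are bit-reproducible.

What passing tests on synthetic cohorts do show: the pipeline inverts its
own forward model exactly at zero noise, and preserves the
smaller-|Δγ| ⇒ larger-τ_p ordering under noise at equal radii. What they do
not show: anything about real measurement artefacts — drop evaporation,
drying-induced surface changes, replicate correlation within a donor, or
radius–phenotype covariation. Real cohorts need real goniometry.

## Known limitations

* A single scalar γ_S per sample; no angle-replicate modelling beyond
  averaging.
* Constant-terminal-velocity crossing; no dynamics within the interfacial
  region.
* Plug flow; no velocity profile or interface-position design.
* Quantitative τ_p values stand or fall with user-supplied radii and
  viscosities; only orderings are asserted internally.
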