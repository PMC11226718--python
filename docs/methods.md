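# Methods

This note documents the physical models, the discretisations, the
numerical choices, and what the test problems do and do not demonstrate.

## Model overview

The package solves the 1D multigroup Boltzmann–Fokker–Planck (BFP)
equation for electrons in slab geometry,

    μ ∂ψ/∂x + Σ_t,g ψ = Σ_x Σ_l (2l+1)/2 P_l(μ) Σ_{l,g'→g}^x ψ_{l,g'}
        − (1/ΔE_g)[β⁺ψ⁺ − β⁻ψ⁻] + (α_g/2) ∂_μ(1−μ²)∂_μ ψ + Q,

splitting collisions into *catastrophic* events (explicit group-to-group
Boltzmann transfers) and *soft* events (continuous slowing down β_g and,
optionally, angular diffusion α_g). A collision is catastrophic when the
surviving electron skips past two group boundaries below its incident
group: for incident group g' (0-based boundaries b[0..G]), the surviving
electron must satisfy `e_e ≤ b[g'−2]`, equivalently the δ-ray or photon
carries at least `e_c = e' − b[g'−2]`. Near the cutoff two further
restrictions apply, both routed to the soft channel: δ-rays below the
cutoff are not produced, and events whose surviving primary would fall
below the cutoff are not treated catastrophically. These exclusions are
required for the transfer-matrix sums to agree with the closed-form
channel totals to 1e−10.

## Cross-section channels

**Møller ionization.** Free-electron two-body collision; the δ-ray is the
less energetic outgoing electron (`e_δ ≤ e'/2`). The kernel is the
standard Møller single-differential cross section,
`2π (r0/β')² [1/e_δ² + 1/e_e² + 1/(e'+1)² − (2e'+1)/((e'+1)² e_e e_δ)]` —
the azimuthal 2π matters: it is what makes the catastrophic channel
commensurate with the Berger–Seltzer collisional stopping power (whose
prefactor is 2π r0² m_ec² N/β²) when the restricted stopping power
subtracts the catastrophic loss. Both outgoing electrons
are assigned the exact two-body kinematic cosine
`μ = sqrt(e_out (e'+2) / e'(e_out+2))`, evaluated *inside* the energy
integrals (not at group midpoints). Closed-form antiderivatives of the
Møller kernel (plain and energy-weighted) provide totals and the
catastrophic energy-loss rates independently of the panel quadrature.

**Bremsstrahlung.** The single-differential cross section is the
Berger–Seltzer-style assembly `σ₁ + σ₂ − σ₃ + ω(σ₄ − σ₂)` of four Born
kernels (exact unscreened Koch–Motz form; screened Born; the unscreened
high-energy logarithmic limit; and the screened form with the
Davies–Bethe–Maximon Coulomb correction f(Z)), multiplied by the Elwert
factor and an atomic correction ξ_r (default 1, per-element hook).
Screening uses Tsai's single smooth Thomas–Fermi fit for Φ₁/Φ₂ with
argument ζ = 100 e_γ/(e_t e_s Z^{1/3}); the smooth fit was chosen over
the common piecewise fit because the assembly demands continuity and the
exact weak-screening reduction σ₂ → σ₃ (verified analytically and in
tests). ω(e') is a smoothstep in total energy from 0 at 15 MeV to 1 at
50 MeV (the Coulomb correction is unreliable below that; both bounds are
configurable). The spectrum is capped at `e_γ^m = e' − b[1]` and the last
1% replaced by a linear ramp to zero, removing the Elwert tip divergence
while keeping the spectrum integrable; negative assembled values are
clamped to zero and counted (none occur over the tested domain). The
surviving electron is emitted strictly forward, so one matrix serves all
Legendre orders.

**Elastic scattering.** Molière-screened Mott kernel: Rutherford with
Nigam's screening parameter η_e and the McKinley–Feshbach Mott ratio
χ(μ,e), plus the empirical ν_e-weighted correction term (ν_e = 1 by
default, hook provided). Goudsmit–Saunderson moments
`G_l = ∫(1−P_l)·kernel dμ` are computed directly by Gauss quadrature in
ln(1−μ+2η) — the (1−P_l) factor regularises the forward peak, so the
transport-corrected moments `σ̄_l = G_L − G_l` never suffer catastrophic
cancellation and the raw (enormous) σ₀ is never formed. A semi-analytic
route through Spencer's integrals P_l^m (with the exact l-recursion)
serves as an independent cross-check at the ~1% level of its small-angle
expansion. The McKinley–Feshbach ratio is used at all Z; its known
degradation above Z ≈ 30 is an accepted accuracy limit of this kernel
family. Below 256 keV the same kernel is extended downward by default;
a Riley-fit kernel reading per-energy coefficient tables
(`energy D B A1..A4 C0..C6`) is available as a plug-in.

**Impact ionization and relaxation.** Gryziński subshell ionization
creates an inner vacancy that relaxes along a chain toward the outermost
eligible subshell (eligibility: K for Z>10, L1 for Z>27, L2/L3 for Z>29,
M for Z>51, N for Z>84 with zero binding). Each step emits either a
fluorescence photon (binding difference) or an Auger electron (binding
minus twice the next binding, floored at zero); the branch probability is
the shell fluorescence yield. At most 5 cascade subshells and 28 lines
are allowed. Auger emission is isotropic and binned to the group
containing the line energy (lower group on exact boundary ties);
sub-cutoff lines deposit locally. The embedded binding energies and
yields are approximate reference values, fully overridable. Zero-binding
subshells use the transport cutoff as the Gryziński energy-transfer
floor.

## Stopping powers and energy bookkeeping

Collisional: the Berger–Seltzer (ICRU-37-form) closed formula with a
generic Sternheimer–Peierls density-effect parameterisation computed
from ρ, ⟨Z/A⟩ and I (Bragg-additivity ln I for compounds; ~30 embedded
element I-values, overridable). Radiative: quadrature of the package's
own bremsstrahlung DDCS over the full spectrum — the same assembly used
for the catastrophic transfers, which makes the restricted
(soft = total − catastrophic) split internally consistent by
construction; closure holds to 1e−8 at every group midpoint.

The energy-deposition cross section has two variants. The default
(`edep`, "electron" mode) books as local deposit: the soft collisional
loss, the catastrophic bookkeeping residuals (incident minus exported
electron and photon energy — zero up to quadrature), minus the energy
exported by Auger electrons and fluorescence photons (which was part of
the locally deposited soft loss). Photon energy — soft radiative,
catastrophic bremsstrahlung, fluorescence — goes to a separate
production tally (`photon_prod`): photons are eliminated at birth and
the dose is strictly electronic. The textbook four-term variant that
instead treats all radiative losses and the Auger first moment as local
deposit is kept as `edep_total`; with it, a "kill photons locally"
dose can be produced, but the global audit then double-counts, which is
why the electron mode is the default. With this bookkeeping a full solve
balances deposited + tallied photon + leakage energy against the
injected energy to 0.1–0.3% at 10–300 MeV.

## Discretisation

*Angles*: N-point Gauss–Legendre; with N = L+1 (the production choice
S16/P15) this is a Galerkin set — the discrete Legendre transform is
exactly invertible, so a forward-delta kernel scatters without
deflection (verified to 1e−10). A boundary beam is injected along the
most forward ordinate, normalised to unit incident current; a
monoenergetic beam can be represented exactly by appending a thin top
group. The injected energy accounted by the audit is the source-group
midpoint (what the multigroup representation actually carries).

*Space*: high-order diamond difference. Cell systems of order M = 0, 1,
2 (orthonormal spatial Legendre moments) are solved in closed form per
cell and direction batch during sweeps; observed convergence orders on
the pure-absorber problem are ≈2 (M=0) and ≥3 (M=1). No negative-flux
fix-up is applied; negative incidences are counted and reported
(`FluxSolution.negative_fraction`).

*Energy*: groups are swept top-down; the weighted-diamond closure
`β⁺ψ⁺ + β⁻ψ⁻ = (β⁺+β⁻)ψ` propagates the slowing-down flux between group
boundaries. Edge fluxes are group-width-scaled energy densities, so on
the logarithmic grid the edge flux is rescaled by ΔE_{g−1}/ΔE_g when
handed to the next group — omitting this amplifies the cascade by the
grid ratio per group and is caught immediately by the energy audit.
Boundary β values are log-log interpolations of the restricted midpoint
values, single-valued at shared boundaries so the CSD current is exactly
continuous. Electrons crossing the cutoff boundary are killed and their
residual kinetic energy deposited locally. Within a group, source
iteration converges the in-group (elastic) scattering to a 1e−5 relative
flux change by default.

## Benchmarks, dose and metrics

Slab stacks use printed thickness percentages of a total sized to
κ = 1.2 times the harmonically mixed CSDA range (κ configurable ≥ 1);
the NM3 stack's printed percentages sum to 170 and are normalised for
sizing while the printed vector is preserved. For *full attenuation*
studies at VHEE the slab must instead be sized on the collisional-only
range: electrons that happen to radiate little penetrate far beyond the
mean CSDA range, and the energy-audit tests size their slabs that way.

Dose is `D_i = Σ_g E_g φ_{g,i} / ρ_i` per source electron plus the
cutoff-kill deposit. Profile comparison regrids both profiles by
monotone piecewise-cubic Hermite interpolation onto a union fine grid;
voxels with reference dose below 0.1% of the maximum are excluded from
the ε statistics (configurable); ε₁/ε₂ are the percentages of voxels
within 1%/2% absolute relative deviation, ε̄ the mean |ε_r|, and a
two-sample Kolmogorov–Smirnov statistic on the normalised cumulative
dose curves gives an equivalence decision (default significance 0.02).

## Known limitations

- The falloff region of the depth-dose curve carries the numerical
  dispersion of the diamond energy scheme: comparing otherwise identical
  solves at 150 vs 300 groups leaves mean deviations of a few percent
  concentrated in the distal falloff and tail, while mesh refinement at
  fixed physics converges below 0.05%. A group-refinement study of the
  falloff therefore requires substantially more than 300 groups (or a
  higher-order energy discretisation, which is out of scope here).
- The solver is 1D; there is no transverse transport, no ray-effect
  question, and no coupled photon transport (photon energy is tallied at
  birth).
- The McKinley–Feshbach Mott ratio and the embedded relaxation data are
  approximate for high Z; both are behind override hooks.
- Source iteration is unaccelerated; at the optical thicknesses of these
  problems inner counts stay modest (tens).

Test problems use reduced group counts (30–150) for the unit oracles and
the production settings (S16/P15, 100 voxels, 150–300 groups) for the
acceptance-style checks; passing them demonstrates internal consistency
of the multigroup formalism and discretisation — agreement with measured
dose or Monte Carlo references requires externally supplied profiles via
the comparison interface.
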