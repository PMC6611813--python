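# Methods

## Model

`zulfsim` treats one exchanging pair of chemical species at a time,
A + B ⇌ C: species C carries the full J-coupled spin system, species A the
residual system after the exchangeable subsystem B (one or more protons, or
the heteroatom partner of a pair) has left.  Chemical kinetics are
first-order in the two species with dissociation rate k_d and
pseudo-first-order association rate W_a = k_a[B]; with the exchange partner
in large excess both are constants, so the combined generator of the joint
spin state is time independent and the solution is a matrix exponential.

Spin dynamics live in Liouville space.  Density matrices are vectorized by
column-wise stacking, and the normative identity
`vec(PρQ) = kron(Qᵀ, P)·vec(ρ)` fixes every superoperator representation
(it is unit-tested; any internal change must preserve it).  The block
generator is

    M = [[ L_A − W_a·1,  k_d·T ],
         [ W_a·D,        L_C − k_d·1 ]]

with L = −i[H,·] + R per species.  T is the partial-trace superoperator
removing the B spins from C; D attaches B to A in a *fixed* bath state,
maximally mixed by default.  The fixed-bath assumption reflects the fast
relaxation of solvated protons: a dissociated proton returns uncorrelated
and unpolarized, which is exactly the mechanism that erodes the
heteronuclear coherences a ZULF spectrometer detects.  An optional polarized
bath state can be supplied to `attach_superop` for sensitivity analysis but
is never the default.  B's state is not propagated.  Total trace
(Tr ρ_A + Tr ρ_C, the mole-fraction normalization) is conserved exactly by
construction and asserted to 1e−12 in tests.

### Exchange mechanisms

For molecules whose exchangeable sites are magnetically equivalent
(ammonium) two mechanisms are implemented:

* **generic / all-sites** — the whole subsystem B (all four protons) leaves
  and returns at once; species A is the bare heteroatom.
* **single-site** — one uniformly chosen proton leaves per event; species A
  is the 4-spin residual.  The "random proton" is realized deterministically
  as the uniform average of the per-site trace and attachment
  superoperators, which is the ensemble average of the stochastic process —
  the master equation is deterministic, so averaging is exact.

In the two-block form the averages T̄ = (1/4)ΣT_j and D̄ = (1/4)ΣD_j are
used independently (dissociation and association are uncorrelated events in
the bookkeeping).  The collapsed form below uses the per-site composition
(1/4)Σ_j D_j∘T_j (re-attachment at the vacancy).  For equivalent sites the
two differ only by a spin relabeling that is a symmetry of the Hamiltonian
and of every detection operator, so all observables agree.

### Fast-reassociation limit

In acidic ammonium solutions the derived association rate
W_a = k_d·10^(pKa−pH) exceeds every other frequency by many orders of
magnitude: a free NH₃ is reprotonated within nanoseconds.  Adiabatic
elimination of species A then yields a generator on C alone,

    M_eff = L_C + k_d·(E − 1),    E = D∘T,

each dissociation acting as an instantaneous dissociation–return event.
`dissociation_return_generator` implements this; its validity condition
(W_a ≫ k_d and all spectral widths) is checked against the full two-block
dynamics in the test suite (agreement to 0.2% at W_a/k_d = 10⁴).  The
fast-exchange mechanism comparison uses this form; everything else uses the
full two-block generator.

### Relaxation

The only relaxation model is isotropic, uncorrelated local fluctuating
fields in extreme narrowing:

    R = −Σ_i b_i Σ_{q∈{x,y,z}} [I_iq, [I_iq, · ]],   b_i = 1/(2 T₁ᵢ),

calibrated so that an isolated spin relaxes its longitudinal deviation with
its known high-field T₁ (verified by propagation, not assumed).  The same
model damps transverse coherences (T₂ = T₁ here), preserves the trace, and
leaves the identity stationary.  T₁ = ∞ disables relaxation per spin.
Dipole–dipole cross terms, anisotropy and cross-correlation are out of
scope; thermal (finite-temperature) driving terms are omitted because they
vanish at zero field and do not affect line positions or widths.

In multiplet-shape analyses that call for a uniform intrinsic linewidth
(the ¹⁵N quintet), the T₁ is placed on the observed ¹⁵N only and the proton
T₁ is left infinite: proton longitudinal flips under the fluctuating-field
model act like a slow spin-state exchange that redistributes multiplet
intensity, whereas ¹⁵N relaxation broadens all five lines identically.

## Protocols

**ZULF**: (i) thermal prepolarization of both species at B_p (default 2 T,
298 K) in the high-temperature limit, weighted by the equilibrium mole
fractions; (ii) evolution for the shuttle time t_s (default 0.5 s) under
J-couplings + Zeeman interaction with the guiding field (default 30 µT along
z), exchange and relaxation active — shuttling is modeled at the constant
guiding field, since the real trajectory through intermediate fields is
unspecified and the dominant physics is exchange-driven equilibration with
the unpolarized bath; (iii) a sudden field drop (the switch is ~50 µs,
far faster than any J evolution, so the density matrix is continuous across
it); (iv) detection of Σ_i γ_i I_iz (normalized to γ_H; amplitudes are
arbitrary units throughout) while the state evolves under the J Hamiltonian
plus any residual field.  The maximally mixed part of the initial state is
dropped before propagation: it neither evolves nor contributes to the
traceless detection operator, and removing it keeps the ~1e−6 thermal
deviation free of accumulated rounding noise.

**High field**: doubly rotating frame, all chemical-shift offsets zero,
heteronuclear couplings truncated to their secular I_z·I_z part (homonuclear
couplings between equivalent spins keep the full scalar form; they commute
with the detection operator and shift no line).  The 90° pulse is ideal and
instantaneous; the initial state is the observed isotope's unit transverse
magnetization, weighted by mole fraction; the FID is Tr(F₊ρ(t)).

Propagation computes U = exp(M·Δt) once per segment (dense
`scipy.linalg.expm`) and applies it iteratively; one-shot long intervals on
large generators go through `scipy.sparse.linalg.expm_multiply`.  Every
protocol validates that the conservative bound on the largest transition
frequency (full eigenvalue spread of the detection Hamiltonian) stays below
the Nyquist frequency, and names the offending frequency otherwise.

## Spectral analysis

FFT with exponential apodization (default rate 1/T_acq; the rate is recorded
in the metadata so tests can correct widths for it), optional zero-filling,
and the customary halving of the first point.  For real (ZULF) signals the
time-domain mean is subtracted by default: the static sample magnetization
is a non-evolving offset whose zero-frequency peak would otherwise dominate
the magnitude spectrum; for complex FIDs it is kept, because a genuine line
may sit at zero offset (the quintet center).  Peak metrics default to the
magnitude spectrum (ZULF phase is protocol dependent) with a real-part mode
for phased high-field spectra; note |Lorentzian| is √3 wider at half height
than its absorption part.  Peaks are local maxima above a relative threshold
outside a configurable zero-frequency exclusion window (default 2 Hz,
motivated by small couplings such as the 1.3 Hz line of
[1-¹³C]pyruvate that would hide under the static peak), refined by
three-point parabolic interpolation; FWHH by linear interpolation at half
height; integrals by the trapezoid rule over each peak's monotonic support.

## Markov chain

The spin-memory analysis is a classical configuration chain: each event
replaces one uniformly chosen site's spin with a bath spin (up with
probability 1/2 for the unpolarized solvent).  Three metrics are reported
side by side — expected never-exchanged-site fraction (analytically
(1−1/n)^k), probability of still occupying the initial |αααα⟩ configuration,
and normalized Shannon entropy of the configuration distribution — because
the single "memory" number quoted for this system is defined through a
supplementary spin-entropy construction that is not public; the three
metrics bracket any reasonable definition, and all collapse within about ten
events for four sites.  With a fully polarized bath and an all-up start the
state-memory metrics stay perfect while site survival still decays; the
package makes that distinction explicit rather than conflating the metrics.
Entangled initial states would lose memory at least as fast; they are the
domain of the Liouville machinery, not this module.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| B_p | 2 T | prepolarizing field |
| t_s | 0.5 s | shuttle time |
| B_g | 30 µT (z) | guiding field during shuttle |
| dwell | 1 ms | sampling interval (fixture-specific values cover each system's Nyquist needs) |
| pKa(NH₄⁺) | 9.25 | ammonium acid constant |
| simulation pH (ammonium) | pKa − 2 | see below |
| J_NH, J_CH(pyruvate), J_CH(formate) | 73.4, 6.25, 222 Hz | fixture couplings |
| bath state | 1/Tr(1) | unpolarized exchanged spins |

Ammonium simulations default to pH = pKa − 2, where the protonated fraction
is 100/101 ≈ 0.990.  The experiments of interest sit at much lower pH where
x_C is even closer to 1, but the derived W_a grows as 10^(pKa−pH) and
reaches ~10¹⁰ s⁻¹ there, adding enormous stiffness to the generator while
the remaining 10⁻⁹ population of NH₃ changes nothing observable; pH = pKa−2
realizes the same physical regime (x_C ≈ 1, W_a ≫ k_d) at benign magnitudes.

Problem sizes: the largest generator is the single-site ammonium pair,
(16² + 32²) = 1280 Liouville dimensions; a spectrum simulation is a few
seconds on one CPU, dominated by the 1280² matrix exponential.  Acquisition
grids in the bundled analyses (e.g. 8 s at 500 Hz for ammonium ZULF, 2–4 s
for high-field FIDs) are chosen to resolve the narrowest line of each
scenario by an order of magnitude while keeping each simulation in seconds.

## What the fixtures do and do not emulate

The fixtures are built from published coupling constants and standard
physical constants only; there is no instrument noise, no field
inhomogeneity or gradients, no magnetometer response function, no
paramagnetic impurities, and no temperature dependence of rates.  Passing
tests therefore demonstrate the spin-dynamics + kinetics model — line
positions, multiplet patterns, exchange broadening/narrowing, protocol-
induced signal loss — not absolute amplitudes or experimental linewidths,
which in real spectra also carry shimming, gradient and sensor
contributions.  The hydrate fixture's ¹³C–OH coupling (1 Hz) is a synthetic
order-of-magnitude value, as the real hydrate couplings are not published.

## Numerical choices

* Dense complex generators throughout (≤ 1280²); sparsity is exploited only
  for one-shot exponential-times-vector products.  Determinism: identical
  inputs give byte-identical outputs; the only randomness in the package is
  the seeded Markov chain.
* Hamiltonians are built and stored in rad/s; every user-facing number is Hz.
* The isotope table is restricted to ¹H, ¹³C, ¹⁵N, ¹⁹F, ³¹P (spin-1/2,
  signed γ); higher spins are rejected rather than approximated.
* Exchange-free, relaxation-free single-species runs use exact Hilbert-space
  propagation (d ≤ 32) instead of the d² Liouville space; the two paths are
  verified to agree to 1e−12.
* Non-Hermitian Hamiltonians warn but compute (useful for effective
  Hamiltonians); non-uniform time grids fall back to per-interval
  exponentials with a warning.
* Degenerate-state (zero-frequency) coherences are excluded from the
  eigen-decomposition transition oracle by a 1e−6 Hz floor.

## Known limitations

Single exchange pair per simulation (no multi-step speciation ladders or
simultaneous exchange at several inequivalent groups); no k_d(pH) kinetic
law — the dissociation rate is an input; sudden field switching only (no
adiabatic ramps); no dipole–dipole relaxation variant; classical Markov
chain only for the memory analysis; amplitudes in arbitrary units (whether a
magnetometer senses magnetization or its derivative is sensor dependent, so
only positions, widths and ratios are contractual).
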