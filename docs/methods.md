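# Methods

## The model

Biomolecular condensates are modeled at two levels that the package keeps
deliberately coupled: a closed-form polymer theory for size exclusion and
recruitment, and a coarse-grained sticker-spacer simulation that the theory
was calibrated against.

### Size-exclusion theory

A condensate rich in intrinsically disordered regions (IDRs) behaves, at the
mesh scale, like a semidilute solution of self-avoiding chains with Flory
exponent ν = 0.588. Its single mesoscopic length is the correlation length
(blob size)

    ξ = c · d · φ^(−ν/(3ν−1)),

with d the monomer diameter (default 0.6 nm, twice the 0.3 nm average
amino-acid radius), φ the IDR volume fraction, and c = 0.68 for fully
flexible self-avoiding chains. Equivalently, ξ follows from the osmotic
pressure through the blob picture, ξ = [kBT/((3ν−1)Π)]^{1/3} — the two
routes agree by construction when Π is the blob-scaling pressure, and on
simulated systems within the scatter of the pressure measurement.

Inserting a hard sphere of radius R costs

    ΔF/kBT = a1 (R/ξ)^(3−1/ν) + a2 (R/ξ)² − ln(1 − φ),

which interpolates the known small-probe and large-probe (surface-area)
scaling limits and adds the pure volume-reduction term that survives at
R = 0. The prefactors a1 = 4.18 and a2 = 7.24 are the global-fit values
from hard-sphere insertion into simulated self-avoiding chain melts. The
partition coefficient of a non-binding particle is P = exp(−ΔF/kBT);
binding sites at density ρ with dissociation constant KD shift the client
free energy by −ρ/KD per site type (strong-binding limit; the
finite-valency Poisson-sum evaluator is also provided and reduces to the
limiting form when the valency cap is generous and KD ≪ 1/Ω).

Composition conversion: φ can be derived from a scaffold concentration
either by the molar route (c·N_A·n_res·(4π/3)r³) or the mass route. Note
that applying the molar route to the conventional LAF-1 inputs (2.6 mM, 250
IDR residues, r = 0.3 nm) yields φ = 4.4 %, somewhat above the 3.6 %
usually quoted for that condensate, and the mass route applied to the
"typical condensate" (250 g/L, 40 % IDR) gives 6.2 % rather than 5 %. The
downstream published numbers are consistent with the quoted φ values, so
the package treats φ as the authoritative input for reproduction and
reports the conversion arithmetic as-is.

### Sticker-spacer simulator

Polymers are linear chains of volume-excluding spacer beads (type C)
carrying small sticker beads (A and B) as bonded satellites. Stickers are
virtual patches: A–B pairs attract through a soft cosine well of depth U0
and range r0 = 0.3 nm, same-type stickers repel (WCA) to enforce one-to-one
binding, and stickers have no volume interaction with spacers or free
particles. Spacers and neutral/client particles (D) repel through the WCA
potential 4ε[(σ/r)¹² − (σ/r)⁶] + ε cut at 2^{1/6}σ with σ = r_i + r_j and
ε = 1 kBT. Client recruitment adds a cosine shell attraction between D and
both sticker types, centred at the particle radius R = 1.5 nm with
half-width ra = 0.3 nm.

Two condensate architectures are built in:

- **compact spacers** — 10 spacers of radius 1 nm per chain, FENE-bonded
  (k = 0.129 kBT/nm², rmax = 14.03 nm), one sticker per spacer
  (harmonic, kb = 100 kBT/nm², rb = 1 nm), U0 = 18.8 kBT;
- **IDR spacers** — 450 spacers of radius 0.3 nm, stiff harmonic backbone
  (kb = 692 kBT/nm², rb = 0.38 nm, the Cα–Cα distance), a sticker on every
  8th spacer (kb = 1111 kBT/nm², rb = 0.3 nm), U0 = 18 kBT.

Spacers-only systems (IDR chains with stickers removed) model homogeneous
semidilute solutions for the pressure/insertion calibration, with the
fast-bead parameters m = 0.0565 ag, τ = 0.01 ns, dt = 10⁻⁴ ns.

Dynamics are underdamped Langevin integrated with the BAOAB splitting;
per-bead friction γ_i = m_i/τ with τ = 1 ns gives every bead the
Stokes–Einstein diffusivity kBT/(6πηr_i) for water viscosity
η = 0.001 kg/(m·s). With the thermostat off the scheme reduces to velocity
Verlet (energy drift < 10⁻⁴ relative over 10⁴ steps at dt/10 in the test
suite). Units are nm, ns, ag; energies in kBT at the configured
temperature (default 300 K), so SI conversions appear only at the pressure
interface.

Conventions that the underlying literature leaves open, decided here:

- **FENE bonds carry their own WCA core** (σ = spacer diameter), the
  standard bead-spring convention; without it, bonded compact spacers
  interpenetrate and the integrator is unstable.
- **Nonbonded exclusions are 1–2 only** (directly bonded pairs); second
  and third neighbors along a chain interact normally. This makes the
  chains slightly stiffer locally than a convention that also excludes
  1–3/1–4 pairs would.
- **Neighbor search** uses a cell list with per-type-pair cutoffs; free
  particles, which are few but long-ranged, are listed by a wide cell
  scan so the cell size can follow the short bulk cutoffs. Rebuilds are
  displacement-triggered (twice the largest displacement since the last
  build approaching the skin, default 0.4 nm); fixed-interval rebuilds
  demonstrably miss fast-closing sticker pairs during annealing.
- **Initial placement** grows each polymer as a self-avoiding random walk
  at the bond length (retrying directions that overlap beads already
  placed in the same molecule), confined to the coexistence slab region
  when walls are active, followed by a capped-force steepest descent to
  remove inter-chain overlaps, then a soft-start dynamics phase at dt/10.
  Only the confinement region is prescribed by the protocol; the rest is
  this package's choice.

### Coexistence protocol and analysis

The phase-separation protocol confines polymers to |x| < x_wall, ramps U0
linearly from 0 to its target, equilibrates, removes the walls,
re-equilibrates, and records production frames. Volume-fraction profiles
along x use 50 bins, per-frame recentering to the polymer center of mass
(circular mean, since the box is periodic) and symmetrization about x = 0.
Bin volume fractions are bead counts × single-bead volume per bin volume —
no partial-overlap apportioning, which matches count-based profiles at
this bin width. Frames whose largest polymer contact cluster (contact =
centers closer than 1.2(r_i + r_j)) holds less than a configurable
fraction of the molecules are excluded and counted.

Partitioning is the ratio of region-averaged volume fractions, dense
|x| < 10 nm and dilute |x| > 40 nm for the full-size 100 nm box (scaled
fractions for smaller boxes). The dissociation constant is extracted as
KD = ρ_client ρ_S,free / ρ_S,bound in the dense region, a sticker counting
as bound when within R + ra = 1.8 nm of a client center — the reach of the
attraction well. The distance criterion is this package's convention; an
energy-threshold criterion would shift KD slightly but not the predicted
ordering.

### Widom insertion

Hard-sphere test particles are inserted on a deterministic uniform grid
(140³ for condensate slabs, 100³ for homogeneous boxes at full scale;
smaller grids at desk scale), restricted to the dense-phase plateau region
when analysing coexistence slabs; a seeded random-sampling mode exists for
convergence checks. A probe of radius R is accepted when no excluding bead
center lies within R + r_C (minimum-image metric); stickers never exclude.
F(R) = −ln⟨acceptance⟩, with standard errors from per-frame scatter.
Radii with zero acceptances are reported as flagged lower bounds
(F > ln n_samples), never as numbers, and must be dropped before fitting.
For pressurized homogeneous boxes the PV work Π(4π/3)R³ is subtracted so
that free energies compare phases at equal pressure.

## Desk-scale study conditions

The full-scale protocols (50 polymers, 100 × 25 × 25 nm box, 10⁷–10⁸-step
schedules, 30–60 replicates) are provided as "cluster" presets but are not
what the test suite runs. The desk-scale ("mini") presets keep every
interaction parameter at its full-scale value and shrink only counts, box
and schedule:

- compact mini: 16 polymers (+ up to 60 particles), 70 × 18 × 18 nm box,
  walls at ±15 nm, 1.5×10⁵-step anneal, 6×10⁵-step production;
- IDR mini: 5 polymers of the full 450-mer architecture, 55 × 14 × 14 nm
  box, 10⁵-step anneal, 10⁵-step production;
- spacers-only mini: 10 chains of 60 monomers (pressure oracle checks) or
  8 × 120-mers (insertion-fit pipeline).

Both mini architectures phase separate into a single dense slab with a
dense-phase polymer volume fraction of 6–8 %, bracketing the 7 % of the
full-scale systems. What the desk-scale runs *do* show: the direction and
rough magnitude of the entropic exclusion difference between IDR and
compact architectures, the intruder→client crossover under increasing
client–sticker attraction, and the internal consistency of the estimators
(Widom vs direct coexistence partitioning within statistical error). What
they *cannot* show: the full-scale quantitative contrasts (the 2.5-fold vs
14-fold exclusion numbers, <3 % Widom-vs-coexistence agreement), which
require the cluster-scale statistics; and the surface prefactor a2, which
is calibrated by probes larger than the mesh size whose acceptance
(e^{-14} and below) is unmeasurable with ~10⁷ insertions — desk-scale fits
pin a1 well (within 10 % in our runs) but recover a2 only to the correct
order of magnitude.

The synthetic-data generators used by the estimator tests (single sphere,
rejection-placed hard-sphere gas, ideal slab) have exactly known insertion
probabilities and therefore validate the estimators absolutely, but they
contain none of the chain connectivity correlations of real condensates;
the simulation fixtures carry those.

## Numerical choices

- BAOAB thermostat coefficients c1 = e^{−dt/τ}, c2 = √((1−c1²)kBT/m); the
  kinetic temperature of the stiff IDR system reads ~4 % low at
  dt = 0.01 ns (standard finite-dt bias); the equipartition check is run
  on the softer compact fluid where the bias is within 2 %.
- FENE overextension (r ≥ rmax) and per-step displacements beyond a
  quarter box edge abort the run with a diagnostic rather than produce
  garbage.
- Identical seeds give bit-identical trajectories; all randomness flows
  from one `numpy` generator per run.
- The (a1, a2) fit is linear least squares in the two basis functions of
  x = R/ξ with ν fixed at 0.588 (exposed for sensitivity analysis);
  weights 1/σ² when per-point errors exist. Rank-deficient designs
  (a single distinct R/ξ) are rejected. The collapse statistic
  interpolates each system's ΔF + ln(1−φ) onto a shared R/ξ grid with
  cubic splines and reports the median cross-system relative spread.
- The xi–phi regression is ordinary least squares in log–log space;
  c = e^{intercept}/d.

## Known limitations

- No hydrodynamic interactions, sequence-specific potentials, or
  interfacial observables; no soft-potential insertion energies.
- The equal-volume statement about the two spacer architectures (10 × 1 nm
  vs 450 × 0.3 nm spheres) is not numerically exact (41.9 vs 50.9 nm³);
  presets follow the bead counts and radii as given and do not enforce
  equal volume.
- Partition coefficients from slabs with empty dilute regions are
  reported as bounds; at strong recruitment (ε ≳ 10 kBT) the dilute phase
  of a mini box can deplete below measurability.
- The −ρ/KD linearization overshoots at large ε (it is a strong-binding
  limit applied outside its window); the package reports it as the theory
  curve and leaves the comparison qualitative, as at full scale.
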