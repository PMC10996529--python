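# Methods

## The model

Each amino acid of the TDP-43 low-complexity domain (LCD) construct is a
single spherical bead carrying four properties: mass *m* (amu), charge
*q* (elementary charges: −1 for Asp/Glu, +1 for Lys/Arg, 0 otherwise,
His neutral), a hydropathy weight λ ∈ [0, 1] on the Kapcha–Rossky scale,
and a diameter σ (nm).  The packaged per-residue table
(`lcd_llps/data/hps_kr_params.tsv`) carries the standard HPS-model
values from the coarse-grained IDP literature; loading validates the
20-row schema and the charge assignments.

The 151-residue construct is `GS` + TDP-43 residues 266–414 (the
thrombin-cleaved expression construct).  Its identity is pinned by an
md5 checksum and by three independent anchors: net charge +3 (six
R/K against E271, E362, D406), extinction coefficient
5500·3 Trp + 1490·1 Tyr = 17 990 M⁻¹cm⁻¹, and the wild-type residues at
the substitution sites (S403/S404/S409/S410, A326, W334).  All variants
(2PM, 4PM, and the A326P / W334G controls on the 4PM background) are
generated programmatically from this single sequence; TDP-43 numbering
maps to construct positions through the fixed offset 263.

Three interaction terms act between beads (units: nm, ps, amu, kJ/mol;
kcal inputs converted at 4.184 kJ/kcal):

* **Bonds** — consecutive beads interact through the harmonic spring
  φ_s(r) = ½ k (r − r₀)² with k = 8305 kJ mol⁻¹ nm⁻² and r₀ = 0.38 nm.
* **Screened electrostatics** — charged bead pairs interact through the
  Yukawa potential φ_E(r) = q_i q_j e²/(4π ε_r ε₀ r) · exp(−r/λ_D),
  truncated (unshifted) at 3.5 nm.  ε_r = 78.4 and T = 298 K by
  default.  The Debye length λ_D = (ε_r ε₀ k_B T / 2 N_A e² I)^½ uses
  the full ionic strength I of NaCl **plus** the 20 mM potassium
  phosphate buffer (70 % dibasic, 30 % monobasic, K⁺ by charge
  balance), which contributes I = 0.048 M on its own.  At 1250 mM NaCl
  this gives λ_D = 0.267 nm.  At 0 mM NaCl the closed form gives
  1.39 nm; we use the formula as written and note that no choice of
  (T, ε_r) consistent with the high-salt value reproduces a 1.64 nm
  low-salt screening length for this buffer.
* **Hydropathy (Ashbaugh–Hatch "MLJ")** — all bead pairs interact
  through a modified Lennard-Jones potential: the full 12–6 LJ shifted
  up by ε(1 − λ_ij) for r ≤ 2^{1/6} σ_ij, and λ_ij-scaled LJ beyond,
  truncated at 2.0 nm.  σ_ij and λ_ij are arithmetic means.  Because λ
  scales only the attractive branch, the λ-weighted component **is**
  the model's hydrophobic interaction.

**Salt-dependent well depth.**  Na⁺ is weakly kosmotropic: it
strengthens the hydrophobic effect.  The well depth is therefore a
linear function of NaCl concentration, ε(c) = ε₀ + (Δε/Δc)·c, with
ε₀ = 0.1985 kcal/mol and ε(1.25 M) = 0.205 kcal/mol (≈ 3.3 % relative
increase over the experimental salt range).  A constant-ε control
(0.205 kcal/mol at all salts) and a large-system recalibration
(0.1875 → 0.1905 kcal/mol) are available as model presets.

**Force decomposition contract.**  "Force between two residues" means
the signed scalar radial force, −dφ/dr, positive repulsive — vector
pair forces summed over a disordered condensate would cancel by
symmetry.  The hydrophobic component of the MLJ force is
λ_ij · (plain 12–6 LJ radial force) at every r inside the cutoff; the
remainder is the (λ-independent) repulsive component.  Beyond the
LJ minimum the hydrophobic component equals the full MLJ force, and it
vanishes identically for λ = 0.

## Dynamics

BAOAB-split Langevin dynamics at a 0.01 ps time step, with per-bead
friction ζ_i = m_i/τ (uniform damping time τ).  The friction is not a
physical observable here — equilibrium averages are independent of it —
so τ is a sampling choice: 1 ps by default, 10 ps in the condensed
preset where configurational mixing matters more than thermostat
stiffness.  For multi-ps damping times the Ornstein–Uhlenbeck (O) part
of the splitting may be applied every k-th step with the exactly
integrated coefficients for a lag of k·dt (k = 5 in the condensed
preset); the remaining splitting error is O(dt²) either way, and the
equipartition test verifies the sampled temperature.  Setting the
damping time ≤ 0 disables the thermostat, reducing the integrator to
velocity Verlet (used by the energy-conservation test).

Nonbonded sums use a Verlet pair list (0.3 nm skin, displacement-based
rebuild) built from a cell grid for the 2 nm MLJ cutoff, and an exact
per-step loop over the precomputed list of charged-bead pairs for the
3.5 nm electrostatic cutoff (~6 % of beads are charged, so this list is
tiny).  Directly bonded pairs are excluded from both nonbonded terms,
the standard convention in residue-level IDP models.  Neighbour-list
forces are contractually identical to an O(N²) double loop; a test
enforces agreement to 1 part in 10¹⁰.  All kernels are single-threaded
and seed-deterministic (bitwise).

**Slab protocol.**  Chains are placed as self-avoiding random walks
(bond length r₀, no contact below 0.7 σ_ij), velocities drawn from the
Maxwell–Boltzmann distribution.  The box is compressed linearly per
edge to a cube (60 nm at full scale) over the squeeze schedule
(10⁵ steps in 100 affine rescale-then-relax segments), then the z edge
is extended instantaneously to the slab length (1200 nm at full
scale), leaving the condensed system centered at the origin.  Chains
are wrapped as whole molecules (by center of mass), never bead-wise —
bead-wise wrapping would tear chains across the old periodic boundary
when the box is extended.  Beads of edge chains may overhang the
nominal cube by up to a chain extent; the slab interface is fuzzy at
that scale.

## Phase classification

Chain centers of mass are computed after unwrapping each chain by
bond-connectivity (minimum-image steps from its first bead), then
folded into the box.  Chains with centers within 10 nm (minimum image)
are connected; clusters are the connected components (single linkage),
and a chain's neighbour count is its cluster size − 1.  A run is
**phase separated** iff the mean neighbour count over chains exceeds 2
at *every* analysed frame of the final window, else **dissolved**.  The
mean-over-chains reading is the default because single free chains are
physically expected in coexistence; a strict per-chain-minimum mode is
available (`mode="min"`).  Per salt concentration, calls along the
protein-concentration axis are made monotone by the fill rule (above
the lowest separated concentration ⇒ separated; below ⇒ dissolved), and
c_sat is that lowest concentration (+∞ when the column never
separates).

## Force analysis

For every frame of the analysis window and every **intermolecular**
bead pair within cutoff, the electrostatic radial force and the
hydrophobic MLJ component are accumulated into 151 × 151
sequence-position maps (unordered-pair convention: mirrored across the
diagonal, diagonal cells counted once) and into per-frame totals (each
unordered pair once).  Negative = attractive.  Confidence intervals on
time-averaged totals come from a block bootstrap: contiguous equal
blocks (remainder to the last block), 50 blocks and 1000 resamples by
default, percentile intervals; blocks are contiguous in time to respect
autocorrelation, and a Monte-Carlo test checks ≈95 % coverage on iid
series.

## Scale presets and what the desk-scale runs show

The full study conditions — N ≤ 50 chains (or 125–250 in the
finite-size control), 60 × 60 × 1200 nm slab, 5 μs runs with the final
1 μs analysed, a 10-salt × 8-protein grid — are retained in the
``study`` preset and are a cluster recipe: one cell is on the order of
days on one CPU at this code's throughput.  Tests and the acceptance
script therefore run two scaled-down regimes, with sizes chosen once
for statistical adequacy at desk scale:

* ``smoke``/``reduced`` presets exercise the full squeeze → slab →
  classify pipeline at small N and short times (plumbing and
  qualitative c_sat ordering).
* the **condensed preset** emulates the *interior* of a condensate
  directly: 4 chains (604 beads) packed at 0.25 g/cm³ in a periodic
  cube (7.3 nm edge, safely above twice the 3.5 nm cutoff), damping
  time 10 ps, 1.0 ns equilibration + 0.5 ns analysis (50 frames).  The
  desk-scale salt grid is {0, 1000 mM} — the firmly-low-salt and
  firmly-high-salt anchor points of the mechanism analysis.

What these runs do and do not show.  They probe the *force balance
inside the dense phase*: the sign of the net intermolecular
electrostatic total (repulsive for WT with its single positive pole,
attractive for the phosphomimetics with their N⁺/C⁻ dipolar charge
pattern), the monotone weakening of electrostatics with salt screening,
and the dominance of hydrophobic over electrostatic totals.  They do
not measure coexistence densities or saturation concentrations (no
dilute phase is present), and absolute force totals are smaller than at
full scale simply because fewer chain pairs are in contact.  One
finite-size caveat is documented and deliberate: the
hydrophobic-to-electrostatic ratio for the phosphomimetic variants at
low salt comes out ~2–3× smaller than the ≥100 reported at full scale,
because each phosphomimetic C-tail finds a countercharged partner
regardless of chain count while hydrophobic contact numbers grow with
neighbours per chain (~3 here vs ~12 in a 54-chain slab).  The
wild-type ratio and all sign/monotonicity statements are
scale-robust in our pilots.

Classification calls at desk scale are initialization-dependent on
short runs (a condensed start stays condensed over hundreds of ps
unless cohesion is removed); the dispersal tests therefore use a
long-damping-time ("burst") preset in which non-cohesive chains
separate measurably within the run.

## Numerical choices

* Unit system nm/ps/amu/kJ/mol (1 amu·nm²/ps² = 1 kJ/mol exactly);
  e²/4πε₀ = 138.935 kJ·nm/mol.
* Potentials are truncated, not shifted, at their cutoffs, matching the
  "calculated only within" convention; the MLJ branch point is exactly
  continuous and the analytic forces equal numerical gradients to
  1 × 10⁻⁶ relative away from the branch point.
* Division guards (max(r, 10⁻¹²)) keep pathological overlapped-bead
  configurations from raising inside compiled kernels; a blown-up run
  is detected by a finiteness check and aborted with the failing step.
* The minimum-image convention is applied to displacement vectors and
  is independent of coordinate wrapping; coordinates are stored
  unwrapped (diffusion and chain geometry read off directly).
* Ties and degenerate inputs: zero ionic strength is rejected for
  screened electrostatics (a pure-Coulomb mode must be requested
  explicitly); a window larger than the chain is rejected for NCPR;
  an all-dissolved phase-diagram column reports c_sat = +∞ ("above
  grid").

## Known limitations

* No cation-π, π-π or aromatic-specific terms; no helicity or
  secondary-structure bias — the transiently α-helical region is
  represented only through its hydropathy pattern.  Authentic
  phosphoserine (−2 charge) is not parameterized; S→D is the
  phosphomimetic model.
* No Ewald summation; electrostatics are cutoff-truncated at 3.5 nm,
  which is > 13 Debye lengths at high salt but only ~2.5 at 0 mM NaCl.
* No barostat: condensed-preset densities are imposed, not
  self-determined; slab runs let the dense phase find its own density
  but need full-scale lengths to equilibrate it.
* Desk-scale runs equilibrate locally (packing, contact statistics,
  chain orientation) but not globally (no chain exchange between
  phases); quantitative force totals at desk scale are indicative, not
  converged estimates of the full-scale values.
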