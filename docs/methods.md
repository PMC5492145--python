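# Methods

This note documents the models behind each analysis, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions used throughout. Units are Å, ns, mV and pS
everywhere; ion charge is in elementary-charge units (q_e =
1.602176634 × 10⁻¹⁹ C) and is always assigned from a species table, never
inferred from the element.

## Permeation counting and conductance

A channel is a slab `[z_lo, z_hi]` along the box z axis. Each selected
ion is tracked by a three-region state machine (below / inside / above the
slab). A **crossing** is a move from one reservoir to the other; partial
entries (below → inside → below) emit nothing. Two edge rules matter:

* **Periodic wraps.** A single-step jump whose raw z displacement exceeds
  Lz/2 passed through the periodic boundary, not through the channel. The
  state machine resets and no event is emitted. This rule is needed
  because an ion leaving the upper reservoir through the box edge
  re-enters the lower reservoir without ever traversing the pore.
* **Fast traversals.** A single-step below → above jump with |Δz| < Lz/2
  is a genuine crossing recorded at coarse frame spacing; it counts, and
  is logged because the time resolution is then marginal.

An optional radial gate (off by default) additionally requires in-slab
frames to stay within `pore_radius` of the pore axis; in a membrane
system the bilayer already blocks off-axis paths, which is why the gate
defaults to off.

The conductance is estimated by ion counting: transported charge
`Q = q_e · Σ valence·direction` (a cation moving +z and an anion moving
−z both contribute +1 with the field applied along +z), current
`I = Q/T`, and `G = I/V` in pS. The estimator is ohmic by construction —
doubling the voltage with the same event record halves G — so estimates
computed at one voltage apply unchanged at another under the ohmic
assumption. Negative G (net flux against the field) is returned as-is
with a warning rather than clipped.

### Block bootstrap

Crossing events in a flexible channel are strongly autocorrelated: the
channel spends long periods open or constricted, so an i.i.d. event
bootstrap would badly understate the uncertainty. The record `[0, T]` is
instead cut into contiguous blocks of `block_length` (default 500 ns; the
trailing remainder forms a shorter block whose events and duration travel
together). Each replicate draws blocks with replacement until the
resampled duration reaches `T` and recomputes G on the concatenated
record; the reported uncertainty is the SD over replicates, and 95 %
percentile intervals are available. Pooling several trajectories of the
same system concatenates their block sets before resampling. The block
length is a free parameter: it must be long compared with the gating
correlation time for the SD to be honest, and 500 ns is a reasonable
default when open/constricted dwells are of order 0.5 µs. With
homogeneous Poisson events the block-bootstrap SD agrees with the
analytic standard error `√(λT)·q_e/(T·V)` to a few per cent (checked in
the acceptance suite), and for clustered records it is strictly larger —
which is the point.

## Pore hydration and flux–water coupling

Pore water is counted as water oxygens inside the cylinder of radius
`pore_radius` (default 6 Å) spanning the slab, minimum image applied in
x/y. To correlate hydration with conduction, crossings are binned into
non-overlapping windows (default 50 ns — long enough to hold a few events
at realistic rates, short against 0.5 µs gating dwells), water counts are
averaged over the same windows, and a Pearson coefficient is reported
with the window count. Spearman is available. Zero variance in either
series is flagged as undefined (NaN), never silently reported as 0.
Both the pore radius and the window length are exposed in config since
neither has a canonical value.

## Region RMSD

Backbone means {N, CA, C}; the carbonyl O is excluded by default but the
atom set is configurable. Superposition uses the least-squares optimal
proper rotation (reflections excluded), computed via
`scipy.spatial.transform.Rotation.align_vectors`; the minimised RMSD is
evaluated from the explicit residuals of the returned rotation because
the library's own residual loses precision near zero. The independent
cross-check in the test suite is Horn's quaternion eigenvalue method,
which never builds a rotation matrix.

Each region is superposed on *its own* atoms of the reference frame
(frame 0, configurable), which is what per-region flexibility profiles
report; fitting on one region (e.g. the rigid core) while measuring
another is available as an option and, by construction, can only give a
larger measured RMSD than the self-fit. Proteins wrapped by the periodic
box are made whole at read time by minimum-image reconnection along the
bonded chain order (`unwrap_chain`), so RMSD never sees wrapping jumps.

For region definitions on the 87-residue ligase-like system the defaults
are core = 18–34 ∪ 57–65 (the two Zn-binding regions) and loop = 35–56.
Published descriptions of such systems sometimes draw the loop/core
boundary a few residues later (e.g. at 59); the boundary is configurable
rather than adjudicated here.

## Coordination and contacts

Metal coordination spheres are the donor atoms (default names OD1, OD2,
OE1, OE2, SG, ND1, NE2, O — carboxylate and carbonyl O, thiolate S,
imidazole N) within a cutoff of the metal, minimum image applied. The
default Zn cutoff of 2.8 Å is a generous upper bound for first-shell
Zn–O/N/S contacts; no universal value exists, so it is configurable.
All cutoff comparisons in the package are inclusive (≤), stated once here.

A **ligand substitution** is called from the per-frame ligand-set series
by run-length compression: compositions persisting at least `persistence`
frames (default 25) are stable; an event is emitted between consecutive
stable compositions when at least one ligand left *and* a different one
entered. Sub-persistence flickers are only logged. The persistence-based
caller is this package's own operational definition — distance-criterion
and by-inspection calls in the literature do not specify one.

Salt bridges are basic–acidic residue pairs (Lys/Arg N atoms NZ, NH1,
NH2, NE vs Asp/Glu O atoms OD1, OD2, OE1, OE2) whose per-frame minimum
N···O distance is ≤ 4.0 Å (a common convention) in at least
`occupancy_min` (default 0.5) of frames; the occupancy itself is always
reported.

## Synthetic generators

Neither generator integrates dynamics or evaluates a force field; they
script geometry with calibrated randomness so that ground truth is exact
and every analysis has a known answer. Identical seed and config give
byte-identical output.

### Gated channel

A hidden two-state continuous-time Markov chain (open / constricted)
controls everything: per-species crossing rates (`rate_open` 20/µs,
`rate_closed` 1/µs), and pore water occupancy (Poisson around 30 open, 5
constricted). Switching rates default to 2/µs each way, i.e. 0.5 µs mean
dwells — a stated convention for "long" high/low-conductance periods, not
a fitted value. The default record is 10 µs at 1 ns/frame, 150 mV,
60 × 60 × 90 Å box, slab (−15, 15) Å, 20 K⁺ and 20 Cl⁻, with crossings
going with the electric driving force with probability 0.9. Expected
yield under the defaults is ≈ 210 crossings per 10 µs.

Each crossing is realised as a monotone z-walk through the slab lasting
`crossing_frames` (default 5) frames, so detectors cannot rely on
single-frame teleports. Ions otherwise idle in the reservoirs with small
jitter; return trips and scheduled idle moves jump across the periodic z
boundary, producing exactly the wrap signature a correct detector must
reject. Reservoir positions are placed so a home-to-home jump always
exceeds Lz/2. If the configured rates are too high for the frame spacing
to host non-overlapping scripted paths, generation fails with an error
advising a smaller dt. Water is represented by oxygen positions only
(counts are all the hydration analysis needs); a fixed allocation of
pore-water atoms moves between the pore cylinder and parking positions in
the reservoirs so the topology is constant. Six static helix-like CA
chains decorate the pore. Setting `water_coupled=False` replaces the
state-driven water mean with its stationary average, giving the
decoupled null used to validate the correlation estimator.

What this emulates: the *statistics* of gated permeation — bursty
crossing times, hydration coupled to the same hidden state, periodic-wrap
traps. What it does not: real ion–water–peptide energetics, diffusive
(non-monotone) pore passages, multi-ion correlations, membrane structure.
Passing tests therefore demonstrate correctness of the estimators under
the stated stochastic model, not force-field realism.

### Ligase mimic

An 87-residue backbone (N, CA, C per residue) lies on a smooth
self-avoiding helical curve with 3.8 Å CA steps. Side chains are reduced
to the scripted donor atoms (NZ, ND1, SG, OE1/OE2, OD1/OD2, NH1) of the
residues that participate in metal binding or salt bridges. Two Zn
particles sit at the centroids of their ligands' CA positions; scripted
ligand donors are placed exactly 2.1 Å from their Zn (released donors at
4.5 Å), and each Zn site jitters rigidly with σ_core so coordination
distances are preserved. A substitution script (frame, lost ligand,
gained ligand) swaps the 2.1 Å and 4.5 Å roles instantaneously at the
scripted frame. Salt-bridge scripts place the donor N at exactly 3.0 Å
from the acceptor OD1 in a exact-count random subset of frames
(occupancy · n_frames, so scripted occupancies are recovered exactly) and
6.0 Å otherwise.

Per-frame displacements: core backbone atoms get i.i.d. Gaussian noise
(σ_core 0.7 Å), tails i.i.d. σ_tail 3.0 Å, and the loop a per-residue
displacement field smoothed along the chain (Gaussian kernel, 2-residue
correlation length) scaled to σ_loop 2.5 Å — nearby loop residues move
together, as a real loop does. The σ defaults are chosen so the
downstream median RMSD contrast reproduces the qualitative rigid-core
(~1.5–2 Å) versus mobile-loop (~4 Å) pattern seen in such proteins.
Note that i.i.d. per-coordinate noise σ on both the frame and the
reference gives a per-atom RMSD of √6·σ before superposition gains, so
the defaults map to ≈1.6 Å core and ≈4 Å loop medians.

The mimic's geometry is statistical, not structural: the curve is not a
fold, Zn–Zn distance is whatever the ligand centroids give (its
*stability*, not its value, is the tested observable), and no
excluded-volume or bonded forces act. It is sufficient ground truth for
RMSD contrasts, coordination tracking, substitution calling and
salt-bridge occupancy — the analyses this package performs.

## Numerical and I/O conventions

* Orthorhombic boxes only; triclinic input raises an explicit
  unsupported-format error. Minimum image is applied per axis.
* PDB parsing follows wwPDB v3.3 fixed columns; ATOM and HETATM are both
  accepted; altloc records other than blank/'A' are skipped with a
  warning; malformed records report their line number. Multi-model files
  expose the model count, with frame 0 = MODEL 1.
* Trajectory time axes are rarely trustworthy in DCD/XTC headers, so
  readers accept an explicit `dt` (ns) and offset; file timestamps (ps)
  are used only as a fallback.
* Round-trip precision: DCD stores float32 (≈1e-4 Å here); XTC quantises
  to 10⁻³ nm, i.e. up to 5e-3 Å error. TSV floats are written at %.6g.
* JSON outputs are sorted-key with fixed indentation so identical runs
  are byte-identical; no timestamps enter result files.
* The block bootstrap and both generators draw all randomness from a
  single `numpy.random.default_rng(seed)`; every CLI entry point with a
  stochastic step requires `--seed`.

## Problem sizes used in validation

The validation suite runs the detector oracle on 1000 random 300-step
wrapped walks, the generator-truth and hydration checks on 10 µs
(10 001-frame) channel records, the Poisson analytics on 50 seeds
(bootstrap n=400) plus a 100-replicate coverage study (n=500), the
superposition oracle on 100 random pairs (n = 4–50 points), and the
ligase analyses on 500–1000-frame mimics. These sizes give comfortable
statistical resolution for every asserted bound while keeping a full run
in the tens of seconds.

## Known limitations

* Conductance by ion counting only; electrodiffusion/PMF-based estimators
  are out of scope, as are multi-level conductance state assignments.
* No RMSF, PCA or secondary-structure analysis; no hydrogen-bond
  networks, coordination-polyhedron classification or protonation logic.
* The wrap-rejection rule assumes an ion cannot physically traverse more
  than half the box in one frame interval; at extremely coarse saving
  intervals this conservative rule would drop genuine crossings.
* Pooled bootstrap records are assumed to sample the same underlying
  system; pooling heterogeneous systems produces a well-defined number
  with no clear physical meaning.
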