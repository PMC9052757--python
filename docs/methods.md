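# Methods

This note documents the models, conventions and numerical choices behind
`allostate`, and what the synthetic generators do and do not emulate.

## Geometric observables and conventions

Dihedrals are signed torsions in the IUPAC convention, reported in
(−180°, 180°] (a value of exactly −180° is reported as +180°). The φ of
residue *i* is built from C(i−1), N(i), Cα(i), C(i). Angles use the
second atom as vertex and lie in [0°, 180°]. Frames whose geometry is
degenerate (collinear or coincident atoms) are flagged undefined and
carry NaN; they are excluded from histograms and classification, never
imputed. The hydrogen-bond criterion defaults to donor–acceptor distance
≤ 3.5 Å and donor–H···acceptor angle ≥ 120°; a heavy-atom-only
(distance-only) mode exists because backbone hydrogen bonds are often
reported without an angular criterion (and crystal structures carry no
hydrogens).

## Oxyanion-strand states

Classification is rule-based (no hidden-Markov smoothing): each frame is
labelled by the first matching state box in priority order, on the
(ϕ-hV51, ϕ-hG50) torus. Published anchors are the inactive ϕ-hV51
interval [−180°, −100°] and the active position near +60°; the remaining
box edges are this package's defaults and are config-overridable:

| state         | ϕ-hV51             | ϕ-hG50          |
|---------------|--------------------|-----------------|
| inactive-OxH  | [−180°, −100°]     | [−180°, 0°]     |
| unblocked-OxH | [−180°, −100°]     | (0°, 120°]      |
| active-OxH    | [20°, 100°]        | any             |

Intervals are closed on the stated brackets; −180° and +180° are the same
point of the circle. The unblocked-OxH ϕ-hG50 band is an explicit guess
guided by the basin topology of the landscape, not a published number.
The interface closure marker is exposed as `PRODUCTIVE_CLOSURE_THETA =
13°` (θ from the fF120/hW123/hG52 Cα triad).

Binding phases follow fixed d_nuc thresholds — unbound > 12 Å (the
recognition distance), recognition (6, 12] Å, captured (3.5, 6] Å, and
catalytic ≤ 3.5 Å *only* in the active-OxH state (otherwise the frame
stays "captured"). Phase labels are monotone in d for a fixed state.
Event detection opens an event when the phase leaves "unbound" and closes
it only when d_nuc returns above the recognition threshold (hysteresis:
threshold chatter around 6 Å cannot fragment one excursion into many
events). Events with fewer than `min_capture_frames` (default 10) frames
at captured-or-deeper are discarded as grazing contacts. The
substrate–hG52 anchor hydrogen bond is reported per event but never used
as a gate; empirically it correlates with the absence of unbinding, but
no rule is published.

## Free-energy landscapes

Population landscapes use F(bin) = −kT ln(count/N), min-shifted, with
k_B = 0.0019872 kcal mol⁻¹ K⁻¹ and a default temperature of 300 K
(kT = 0.5962 kcal/mol); the production simulation temperature is a
config parameter. Never-visited bins are masked, not given pseudo-counts,
and barrier paths cannot cross them — the package does not invent free
energies. The default grid is 72×72 bins (5°) over (−180°, 180°]², fine
enough to resolve the three basins without empty-bin blow-up at
desk-scale sample counts. The 1D profile along one dihedral is the
Boltzmann marginal P(x) = Σ_y exp(−F(x,y)/kT) over unmasked bins,
re-expressed as −kT ln P and min-shifted; fully masked columns stay
masked.

Well-tempered metadynamics bias is summed directly from the deposited
Gaussians, V(s) = Σ_k w_k Π_d exp(−Δ_d²/2σ_d²), with Δ_d the
minimum-image difference on periodic axes. Walkers share one bias: their
hills are concatenated in deposition order with no per-walker
reweighting, matching the multiple-walkers scheme. The landscape
estimator is the asymptotic well-tempered relation F(s) = −(γ/(γ−1)) V(s)
(min-shifted); no time-dependent reweighting estimator and no block-error
analysis are implemented.

Barriers are minimax-path ("lowest pass") quantities: on the 4-connected
periodic grid graph, the pass height between two basins is the minimum
over paths of the maximum F along the path, computed by union-find over
bins inserted in increasing-F order (the F at which the basin minima
first connect is exactly the lowest pass). The barrier is the pass height
minus the minimum F in the origin basin, so forward and reverse barriers
share the pass height.

## Shortest path map

Correlations are Pearson dot-product correlations of 3D Cα displacement
vectors, C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), after iterative
least-squares (Kabsch) superposition of all frames onto the converged
mean structure (tolerance 10⁻⁶ Å). Superposition removes rigid-body
drift that would otherwise inflate correlations; mutual-information
variants are not implemented. Zero-variance residues have no defined
correlation and raise unless explicitly masked.

The SPM graph uses contact edges (mean Cα–Cα distance < 6 Å by default)
weighted d_ij = −log|C_ij| with |C| clamped to [10⁻¹², 1]. For every
residue pair the Dijkstra shortest path is traversed and each edge's
usage incremented; widths are usages normalized to the busiest edge, the
map keeps edges with width ≥ 0.3 (configurable), and node importance is
the sum of incident included-edge widths. Dijkstra ties are broken
deterministically: a node's predecessor is fixed at finalization as the
lowest-index already-finalized neighbour on a shortest path, which keeps
the tree acyclic even across zero-weight (|C| = 1) edges; the number of
degenerate (equal-cost) choices is reported in the result metadata.
Disconnected contact graphs are allowed — unreachable pairs contribute
nothing and a warning reports the component count.

te-SPM windows are [k·stride, k·stride + window] for k = 0, 1, … while
the window end does not exceed the trajectory span; frames on window
boundaries belong to both adjacent windows (strict inclusion, no
smoothing). A 1200 ns trajectory at window 600 / stride 300 gives
exactly [0, 600], [300, 900], [600, 1200].

## Synthetic generators

The generators provide desk-scale stand-ins with known ground truth;
passing tests demonstrate the *machinery* is correct, not that any real
trajectory has been reproduced. None of them emulate solvent, force
fields, atomistic detail, or the boost potentials of accelerated-MD
variants.

**Triple well.** The conformational landscape is modelled as a sum of
periodic (von-Mises-like) Gaussian wells, U(s) = −Σ_i d_i Π_a
exp(κ_ia(cos Δ_a − 1)), exactly 360°-periodic and analytically
differentiable, with wells at (−130°, −70°) "inactive", (−130°, 60°)
"unblocked" and (60°, 60°) "active". Depths and widths were calibrated
once, at construction, against the dense-grid (0.5°) minimax barriers so
that inactive→unblocked = 4 kT and inactive→active = 8 kT at 300 K, the
active basin is 2 kT deep (a genuine but high-energy metastable state, as
in the substrate-free ensemble being emulated) and the unblocked minimum
lies 0.3 kcal/mol above the inactive one. The exact recorded values on
the object (not the nominal 4/8 kT) are the reference for every recovery
test.

**Samplers.** Dynamics are overdamped (Brownian): s ← s − (D/kT)∇U dt +
√(2D dt) η with periodic wrap; one mobility parameter suffices for
testing population, landscape and network machinery, so no inertial
variant is provided. Defaults D = 2000 deg²/ns, dt = 0.002 ns. A drift
step exceeding 30° raises with advice to reduce dt. The WT-MetaD sampler
keeps the accumulated bias and its gradient on an internal 2° grid
(nearest-bin lookup); every `pace` steps each walker deposits, in walker
order, a hill of height h₀ exp(−V(s)/((γ−1)kT)) into the shared bias.
The deposition defaults (h₀ = 0.5 kcal/mol, σ = 10°, pace 500, γ = 10)
are this package's stand-ins — the production metadynamics protocol they
imitate is not published in the text available — and are stated as such.
All generators are seed-deterministic.

**Planted-network ensembles.** The toy protein is an elongated rod: two
2×10 grids of Cα-like beads (3.9 Å lattice) joined end to end across a
4.4 Å interface, so the contact graph is chain-like with exactly four
inter-subunit contacts. The planted communication path runs along the
interface-register row from just inside one tip, across the in-register
interface contact, to just inside the other tip; the tip columns act as
caps whose traffic funnels through the path ends, which keeps every
planted edge — including the terminal ones — busier than any background
edge. The planted path is a *collective mode*: the target correlation is
ρ_path between **all** pairs of path residues (compound symmetry), not
only consecutive ones, because a chain with high correlation restricted
to consecutive pairs is not a positive-semidefinite correlation matrix.
Only consecutive path residues are in contact, so the graph-level signal
is still the path itself. Background correlations are ρ_bg decayed with
3D distance (length 10 Å); the assembled matrix is projected to the
nearest PSD correlation (eigenvalue clipping + renormalization) before
Cholesky sampling. Displacements are isotropic — each Cartesian component
is an independent draw from the same residue–residue correlation — so
the normalized dot-product displacement correlation equals the target
exactly in expectation and is invariant to the fluctuation amplitude.
(An alternative construction, a scalar latent per residue times a fixed
random unit vector, was rejected: it attenuates the realized correlation
by the factor u_i·u_j of the random vectors.) One caveat, visible in the
null control (ρ_path = ρ_bg): the narrow interface is a structural
bottleneck, so the widest single edge tends to sit on an interface rung
regardless of correlations. The planted signal is therefore identified by
the *full-path* ranking criterion (all planted edges within the top
|path| widths), which the null case essentially never satisfies, not by
the single widest edge.

**Binding traces.** Scheduled phases are realized as Gaussian noise
(σ = 0.3 Å) around per-phase target distances (14 / 9 / 4.7 / 3.0 Å)
chosen well inside the threshold bands; the strand label is active-OxH
during catalytic dwells and inactive-OxH otherwise (binding occurs from
the inactive state). Schedules that reach the catalytic phase without an
earlier recognition are rejected as infeasible.

## Problem sizes and tolerances

The shipped analyses and acceptance checks use: 2×10⁴ hills over 10
walkers (10⁶ Langevin steps per walker) for metadynamics recovery, with
a ±0.5 kT acceptance band against the recorded barriers; 10⁶ direct
Boltzmann samples for population-landscape recovery (0.1 kcal/mol band);
5000-frame, 40-residue planted ensembles with ρ_path = 0.9 and ρ_bg =
0.1, 100 seeded repetitions for the recovery rate; 4×10⁵-step unbiased
Langevin runs for Boltzmann-population consistency, judged at 3σ with
the standard error taken from 20 block means (which absorbs trajectory
autocorrelation). Statistical assertions are seeded and deterministic.

## Known limitations

* The well-tempered estimator is asymptotic; no hill-by-hill convergence
  diagnostics or error bars are provided.
* PDB support is deliberately narrow: first MODEL, highest-occupancy
  altloc, insertion codes appended to the residue key; no mmCIF.
* The SPM follows one published construction (contact cutoff 6 Å, weight
  −log|C|, width threshold 0.3); community-network analyses are out of
  scope.
* Timestamps default to a 1 ns stride when a trajectory format carries no
  trustworthy time metadata; te-SPM windowing therefore relies on
  user-supplied strides for real data.
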