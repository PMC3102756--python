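# Methods

This note documents the models and algorithms implemented in `msmbind`, the
parameters that matter, the design choices made where the design was genuinely
open, and what the synthetic-data tests do and do not establish.

## Reaction coordinates

The opening and twisting angles are signed dihedrals between two planes that
share two hinge points; every plane point is the centroid (unit masses — all
atoms are C&alpha;, so mass weighting is moot, and centroids make results
bit-reproducible) of a residue group. Defaults are the LAO-protein groups:
lobe I = residues 6–88 ∪ 195–227 and lobe II = 92–185 as the outer points for
both angles; hinges 162–168 / 121–127 for opening and 83–88 ∪ 194–199 /
92–97 ∪ 156–161 for twisting. The dihedral sign follows the right-hand rule
about the hinge axis oriented from the first to the second hinge centroid.
Raw dihedrals are referenced to the holo (closed) structure, which therefore
scores (0, 0) exactly — raw plane-normal angles would not generically do so.
Residue ids are author numbers as printed; insertion codes are rejected.

Ligand coordinates are meaningful only in a protein-fixed frame; when
trajectories are featurized from structures, frames should be superposed on
the reference protein C&alpha; set first (`featurize.superpose`). The
synthetic generator emits ligand positions directly in that frame.

The toy-structure builder places the two lobe centroids analytically on two
perpendicular hinge axes using half-angle azimuths, so any requested angle
pair strictly inside (−180°, 180°) is realized to machine precision; the
exact ±180° folds are geometrically degenerate on this scaffold and rejected.

## Discretization

k-centers is the deterministic greedy farthest-point (Gonzalez) algorithm:
the first center is the frame at `seed_index` (default 0 — determinism is
preferred over randomized initialization), each next center is the point
farthest from all chosen centers, ties break to the lowest index, and the
covering radius is guaranteed within a factor two of the optimal k-center
radius. Cluster counts default to the published analysis values (protein 50 /
ligand 5000 in the contact regime; 10 / 100 in the diffusing regime, on the
ligand COM) and are capped at the number of distinct points for small data.
The 5 Å minimum heavy-atom distance rule alone defines the regime split;
states with few transitions are reported as a diagnostic, not re-clustered.
Angle space uses plain Euclidean distance without periodic wrapping — observed
hinge angles span far less than 360°.

## Transition counting and the MSM

Counts use a sliding window of the lag over each trajectory separately
(trajectories are never concatenated). Cross-state counts are accepted only if
the destination persists for `min_residence` frames (default 15 frames =
300 ps at 20 ps spacing); windows truncated by the trajectory end are rejected
because the residence cannot be verified. The filter applies to the
destination only, and self-pairs are always counted. Rows with no counts
become absorbing self-loops (flagged); no reversibility is enforced anywhere.
Populations come from the stationary left eigenvector of T restricted to the
single closed communicating class (multiple closed classes are an error);
eigen-decomposition with a power-iteration fallback. Implied timescales use
the real parts of the leading eigenvalues (warning if imaginary parts exceed
1e-8); the working lag is chosen one grid step past the first plateau of the
slowest timescale (relative change < 10% by default).

## Hierarchical lumping (two-regime SHC)

Per regime, microstate densities (frame fractions, renormalized within the
regime) are ranked; a density level L selects the minimal descending-density
prefix with cumulative mass ≥ L. Level ladders default to
[0.50, 0.55, …, 0.95, 0.99] for the contact regime and [0.4, 0.95] for the
diffusing regime (a deliberately coarser two-level hierarchy for diffusive
states). Sweeping levels from the densest prefix outward, each connected
component of the symmetrized-count graph restricted to the level set is
spectral-clustered: the symmetrically normalized affinity's eigenvalue
sequence (negative eigenvalues clipped, padded with a virtual zero so k can
reach the component size) selects the cluster count by the largest gap,
capped at 5 per component; memberships come from k-means (fixed seed) on the
leading-eigenvector embedding, relabeled by lowest member index. Clusters
containing no previously assigned microstate seed new macrostates; unassigned
microstates in clusters that touch existing macrostates are attached to the
macrostate with the largest aggregated symmetrized count, with exact ties
broken by per-capita affinity (coupling per unit of macrostate frame mass —
raw counts alone would systematically hand boundary microstates to the most
populated macrostate) and then by lowest index. Attachment iterates in
descending density order; after the final level, stranded states attach the
same way, and zero-coupling isolates become singleton macrostates (warned).
Seeds created at denser levels are never dissolved later, only grown; the two
regimes keep disjoint macrostate ranges.

The coupling graph for lumping uses lag-1 counts (the finest temporal
connectivity) by default, independent of the MSM lag used for thermodynamics
and kinetics: at a long lag, the only kinetic contacts of a single-frame
microstate adjacent to a basin exchange lie across the jump, which no
attachment rule can repair.

## Kinetics and thermodynamics

MFPTs solve the linear system X = τ + T X off the target set; multi-source
values are stationary-population-weighted means over the sources (target
members contribute zero), and sources that cannot reach the target yield an
infinite MFPT with a warning. Error bars: trajectories are resampled with
replacement (default 100 resamples of n_traj draws), counts and the macro
matrix are re-estimated with the state decomposition frozen, and the
statistic's mean and standard deviation are reported.

Committors are boundary-value linear solves; the backward committor comes
from the time-reversed chain (π_j T_ji/π_i), so net-flux conservation holds
for non-reversible chains too (for reversible chains it reduces to 1 − q⁺).
Pathways are extracted greedily: repeatedly find the source→sink path
maximizing the minimum edge flux (max-min Dijkstra), record it, and subtract
its bottleneck flux from every edge on it.

Constants: R = 1.987×10⁻³ kcal/(mol·K), c° = 1 mol/L; energies in kcal/mol,
times in µs unless stated. ΔG = −RT ln[(1 − α_free)/(α_free² c₀/c°)] treats
all diffusing-regime macrostates as free species. The association timescale
is the pseudo-first-order half-life ln 2/(k_on c₀); k_on is an input, not an
estimate. Free-energy surfaces are −kT ln(n/n_max) on a 2-D histogram (empty
bins NaN, deepest bin exactly 0). Transition-event localization emits the
features at frames where a persistent (residence-filtered) state change
occurs; the residence filter for this diagnostic is a separate parameter from
the counting filter. Medoids minimize the mean pairwise superposed RMSD,
exactly for ≤ 2,000 conformations and on a fixed-seed subsample above.

## The synthetic generator — what it does and does not emulate

`lao_like()` plants four metastable basins — open unbound (40°, −25°, ligand
~30 Å out), partially closed encounter complex (25°, −15°, ~4 Å), closed
bound (0°, 0°, ~1 Å; the dominant state, 84.9% stationary weight), and a
mis-bound state (38°, −22°, ligand attached outside the site) — with
per-frame (20 ps) jump probabilities that make the encounter complex the
gateway to binding (no direct unbound→bound jumps). Emissions are diagonal
Gaussians per basin, with the ligand COM the decisive coordinate (≥ 10σ
between contact-regime basins) so the planted partition is recoverable;
distance-like emissions are clipped at zero (negligible mass). One random
generator per trajectory is derived from (seed, index); start states are
drawn from the planted stationary distribution, emulating an equilibrated
dataset. The default dataset geometry is 65 trajectories × 10,000 frames.

What the generator does **not** emulate: frame-to-frame autocorrelation
within a basin (emissions are i.i.d. given the state), anharmonic or
overlapping basins, barrier-top recrossing artifacts, and atomistic detail.
Consequently, synthetic-data analyses use `min_residence = 1` frame and a
10-frame (0.2 ns) lag: a 300 ps destination-residence filter on i.i.d.
within-basin emissions would annihilate off-diagonal microstate counts, and a
Markov chain needs no recrossing suppression in the first place. Passing
recovery tests therefore validates the estimators and the lumping logic, not
the robustness of the pipeline to non-Markovian MD noise. Pipeline config
defaults nevertheless remain the published analysis parameters (50/5000 and
10/100 clusters, 5 Å, 6 ns lag, 300 ps residence, the density ladders above,
100 bootstrap resamples, 10 pathways).

Test and acceptance problem sizes — 65×10,000 frames for end-to-end recovery,
20×5,000 for lumping recovery, 10⁶ steps for timescale and frequency checks,
10⁶ walkers for the Monte Carlo first-passage oracle — were chosen so that
statistical error sits comfortably inside each stated tolerance.

## Known limitations

- The crystal-structure angle check needs the 2LAO/1LAF PDB entries under
  `data/pdb/` (not redistributed); all other checks are self-contained.
- The recrossing filter interacts badly with discretizations whose states are
  visited for single frames (see above); for real MD data the published
  300 ps default is appropriate, for i.i.d. synthetic data it is not.
- No reversible maximum-likelihood or Bayesian estimators; uncertainty comes
  from trajectory bootstrapping only.
- Exact ±180° hinge angles cannot be realized on the toy scaffold.
- `k_off` is not computed; unbinding kinetics are read from MFPTs.
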