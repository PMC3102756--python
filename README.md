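# msmbind

Markov state model (MSM) analysis of protein–ligand binding for two-lobed
receptors of the periplasmic-binding-protein (PBP) family, which close around
their ligand through large hinge motions. Given per-frame reaction coordinates
— the inter-lobe *opening* and *twisting* hinge dihedrals plus the ligand
position — the package discretizes trajectories into microstates, estimates a
transition matrix, lumps microstates into metastable macrostates, and reads
off the thermodynamics and kinetics of binding. Because suitable MD datasets
are rarely shared, a first-class synthetic-trajectory generator with planted
ground truth makes every stage testable end to end.

## The model

Conformations are described by two signed plane-normal dihedrals between
C&alpha;-centroid groups (lobe I, lobe II, and two hinge segments), referenced
to the closed holo structure so that the holo form scores (0, 0); for the LAO
protein the open apo form then sits near (38.2°, −26.2°). Frames are
discretized by greedy farthest-point (k-centers) clustering, independently for
the protein angles and the ligand position, combined as product states. Two
regimes are distinguished by the minimum protein–ligand heavy-atom distance:
in contact (≤ 5 Å) a fine clustering on ligand heavy-atom coordinates is used;
freely diffusing frames get a coarse clustering on the ligand COM.

Transitions are counted with a sliding window at lag τ; a cross-state count
x→y is accepted only if the trajectory stays in y for a minimum residence time
(recrossing filter). Row-normalizing gives T(τ), whose stationary left
eigenvector π is the equilibrium population and whose eigenvalues yield
implied timescales t_i = −τ/ln λ_i, the Markovianity diagnostic used to choose
τ. Microstates are lumped by super-level-set hierarchical clustering: ranked
by density, nested level sets are swept from the densest prefix outward,
connected components are spectral-split with an eigengap-selected cluster
count, and each new cluster either seeds a macrostate or is absorbed by its
strongest-coupled existing one.

Kinetic/thermodynamic readouts:

- **MFPT**: solve X_f = 0 on the target set and X_i = τ + Σ_j T_ij X_j
  elsewhere; bootstrap over trajectories for error bars.
- **Binding free energy**: ΔG = −RT ln[(1 − α_free)/(α_free² c₀/c°)] with
  α_free the free-species fraction and c₀ the box ligand concentration;
  reference value ΔG = RT ln(K_d/c°).
- **Association timescale**: τ½ = ln 2/(k_on c₀).
- **Transition-path flux**: forward/backward committors, net reactive flux
  F_ij = max(0, f_ij − f_ji) with f_ij = π_i q⁻_i T_ij q⁺_j, decomposed into
  top pathways by repeatedly extracting and subtracting the widest
  (maximum-bottleneck) source→sink path.

## Worked example

`examples/04_lumping_and_kinetics.py` generates the four-basin binding
scenario (open unbound, encounter complex, closed bound, mis-bound; 30
trajectories × 5,000 frames at 20 ps), discretizes, lumps, and analyzes it:

```
microstates: 176
macrostates: 4, populations [0.853 0.084 0.051 0.012]
MFPT unbound -> bound: 5.71 ns (planted truth 5.67 ns)
  path [3, 1, 0]: 87.6% of binding flux
  path [3, 0]: 12.4% of binding flux
```

The lumping recovers exactly the four planted basins; the dominant macrostate
population (0.853) matches the planted bound-state weight (0.849); the MFPT
from the diffusing (unbound) macrostate to the bound one reproduces the
planted frame-resolution truth within 1%; and most binding flux passes
through the encounter-complex gateway (state 1), with the small apparent
direct edge collecting passages that complete both hops inside one lag
window. `examples/05_thermodynamics.py` prints the closed forms: −8.46
kcal/mol from a 1.75% free fraction at c₀ = 4.9 mM and 318 K, against a
−9.95 kcal/mol reference from K_d = 14 nM at 277 K.

The same analysis runs as a shell pipeline with YAML configuration:

```sh
msmbind all -c config.yaml      # simulate|featurize|cluster|msm|lump|analyze|report
```

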