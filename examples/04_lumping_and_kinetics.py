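"""From synthetic trajectories to macrostates, binding MFPT and flux pathways.

Generates the four-basin binding scenario (open unbound, encounter complex,
closed bound, mis-bound), discretizes it with the two-regime product-state
scheme, lumps microstates hierarchically, and reads off binding kinetics and
the transition-path flux decomposition.
"""

import numpy as np

import msmbind as mb
from msmbind import kinetics, lump, msm

spec = mb.lao_like(seed=20260921)
trajs, _ = mb.generate_dataset(spec, 30, 5000, seed=20260921)

asn = mb.two_regime_assign(trajs, k_protein_high=12, k_ligand_high=24,
                           k_protein_low=6, k_ligand_low=12)
print(f"microstates: {asn.K}")

lag_frames = 10
counts = msm.count_transitions(asn.labels, lag_frames, 1)
pi = msm.stationary_distribution(msm.transition_matrix(counts))
coupling = msm.count_transitions(asn.labels, 1, 1)
mapping = lump.shc_lump(coupling, asn.frame_counts(), asn.regime_of_state(), pi=pi)
print(f"macrostates: {mapping.M}, populations "
      f"{np.round(np.sort(mapping.macro_populations)[::-1], 3)}")

T_macro = msm.transition_matrix(lump.aggregate_counts(counts, mapping))
pi_macro = msm.stationary_distribution(T_macro)
regs = asn.regime_of_state()
macro_regs = [set(regs[mapping.micro_to_macro == m]).pop() for m in range(mapping.M)]
bound = int(np.argmax(pi_macro))
unbound = [m for m in range(mapping.M) if macro_regs[m] == "low-res"]

lag_ns = lag_frames * spec.dt_ps / 1000.0
res = kinetics.mfpt(T_macro, lag_ns, unbound, [bound], pi=pi_macro)
print(f"MFPT unbound -> bound: {res.value_us * 1000:.2f} ns "
      f"(planted truth 5.67 ns)")

q = kinetics.committor(T_macro, unbound, [bound])
F, total = kinetics.net_flux(T_macro, pi_macro, q, unbound, [bound])
for path, flux, frac in kinetics.top_flux_paths(F, unbound, [bound], n_paths=5,
                                                total_flux=total):
    print(f"  path {path}: {100 * frac:.1f}% of binding flux")

# Most binding flux funnels through the encounter-complex macrostate before
# reaching the bound state, mirroring the gateway architecture planted in the
# generator; the small apparent direct unbound -> bound edge collects passages
# that complete both hops within a single lag window.
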