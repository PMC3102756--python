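"""Hinge opening/twisting angles of a two-lobed receptor.

Builds synthetic point-set structures with prescribed inter-lobe dihedrals and
recovers them through the featurization, exactly as one would for a pair of
crystal structures (the open apo form of the LAO protein scores roughly
(38.2, -26.2) degrees against the closed holo reference).
"""

import msmbind as mb

reference, groups = mb.build_toy_structure(0.0, 0.0)

for opening, twisting in [(0.0, 0.0), (38.2, -26.2), (90.0, 0.0)]:
    structure, _ = mb.build_toy_structure(opening, twisting)
    got_o, got_t = mb.opening_twisting(structure, groups, reference)
    print(f"planted ({opening:7.1f}, {twisting:7.1f}) deg  ->  "
          f"recovered ({got_o:12.8f}, {got_t:12.8f}) deg")

# The recovered angles match the planted ones to machine precision: the two
# plane-normal dihedrals are referenced to the (0, 0) structure, so the
# reference itself scores exactly zero on both coordinates.
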