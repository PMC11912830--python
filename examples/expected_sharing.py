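"""Expected IBD sharing between haplotypes sampled at different times.

Computes the expected number of IBD segments per haplotype pair in 1-cM
length bins under a constant population of 10,000 diploids, for pairs
sampled 0, 15 and 45 generations apart.  Larger sampling gaps leave less
branch length for recombination, so long segments become rarer.
"""

import numpy as np

from transectne import (ChromosomeMap, NeTrajectory, PairContext,
                        expected_ibd_density)

chroms = ChromosomeMap.default_autosomes()
ne = NeTrajectory.constant(10_000.0, 400)
lengths_cm = np.array([8.0, 10.0, 14.0, 20.0])

print("expected segments per haplotype pair per cM (22 autosomes)")
print("length_cM  " + "  ".join(f"dt={dt:>2}" for dt in (0, 15, 45)))
for l_cm in lengths_cm:
    row = []
    for dt in (0, 15, 45):
        dens = expected_ibd_density(l_cm / 100.0, PairContext(0, dt), ne,
                                    chroms, 300)
        row.append(dens / 100.0)  # per Morgan -> per cM
    print(f"{l_cm:8.1f}  " + "  ".join(f"{v:.2e}" for v in row))

print("\nEach column is one sampling gap; rates fall roughly as e^(-l*dt),")
print("so a 45-generation gap suppresses 20 cM segments ~10x more than 8 cM.")
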