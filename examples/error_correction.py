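"""Effect of IBD detection errors and their model-based correction.

Corrupts ground-truth bottleneck-scenario segments with false positives
(constant-Ne 25,000 sharing), length-dependent recall and 1.5 cM Gaussian
length noise, then fits the trajectory with and without folding the error
model into the likelihood.
"""

import numpy as np

from transectne import (ChromosomeMap, ErrorModel, LengthGrid, PenaltyConfig,
                        SampleSet, SamplingScheme, bin_segments,
                        bottleneck_scenario, build_scenario, fit_trajectory,
                        haplotype_pair_count, inject_errors,
                        sample_ibd_from_model)
from transectne.synthetic import histogram_to_segments

chroms = ChromosomeMap.default_autosomes()
grid = LengthGrid.from_cm(8, 20, 0.25)
ext = LengthGrid.from_cm(3, 25, 0.25)  # wider range so noise can cross 8 cM
scheme = SamplingScheme([SampleSet(0, 180)])
G = 150
truth = build_scenario(bottleneck_scenario(), scheme.tmax(G))
em = ErrorModel.for_simulation(chroms)
nhap = haplotype_pair_count(scheme.sets[0])

segs = histogram_to_segments(
    sample_ibd_from_model(truth, scheme, ext, chroms, G, seed=7))
noisy = inject_errors(segs, em, cutoff_cm=8.0, chroms=chroms, nhap=nhap, seed=8)
clean = bin_segments(segs, grid, scheme, chroms)
observed = bin_segments(noisy, grid, scheme, chroms)
print(f"true segments in [8, 20) cM: {clean.total()}; after errors: "
      f"{observed.total()} (false positives roughly double the counts)")

cfg = PenaltyConfig(alpha=1000.0)
ref = fit_trajectory(clean, scheme, grid, chroms, cfg, G=G, seed=1)
cor = fit_trajectory(observed, scheme, grid, chroms, cfg, G=G, seed=1,
                     error_model=em)
unc = fit_trajectory(observed, scheme, grid, chroms, cfg, G=G, seed=1)

a = ref.trajectory.values[:51]
for name, fit in (("corrected", cor), ("uncorrected", unc)):
    dev = np.exp(np.abs(np.log(fit.trajectory.values[:51] / a))).max()
    print(f"{name}: max fold-deviation from the error-free fit "
          f"(gens 0-50) = {dev:.2f}")
print("\nWithout correction the spurious sharing drags recent Ne far below")
print("the error-free estimate; the convolution correction removes most of")
print("that bias.")
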