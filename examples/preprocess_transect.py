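"""Preprocessing an aDNA transect: relatedness filter and time grouping.

Builds a small metadata table with radiocarbon-style dates, flags a close
pair through its IBD sharing, removes the lower-coverage member, and groups
the rest into sample sets of five generations (29 years per generation).
"""

from transectne import (IBDSegmentRecord, SampleMeta, group_by_generations,
                        relatedness_filter)

metas = [SampleMeta(f"ind{k}", 4000.0 + 40.0 * k, "BP", coverage=1.0 + 0.1 * k)
         for k in range(10)]
# ind0 and ind1 are close relatives: three shared segments > 12 cM
records = [IBDSegmentRecord("ind0", "ind1", "1", 13.0),
           IBDSegmentRecord("ind0", "ind1", "5", 14.5),
           IBDSegmentRecord("ind0", "ind1", "9", 16.0),
           IBDSegmentRecord("ind2", "ind3", "2", 9.0)]

kept, removed = relatedness_filter(records, metas)
for drop, keep, n, total in removed:
    print(f"removed {drop} (shares {n} segments, {total:.1f} cM, with {keep};"
          " kept the higher-coverage member)")

metas = [m for m in metas if m.id in set(kept)]
scheme, report = group_by_generations(metas, window=5, generation_time=29.0)
print("\nsample sets (generations before most recent -> diploid count):")
for t, size in report.items():
    print(f"  t={t:3d}: {size}")
print("\nThese sets and times feed the likelihood; within- and cross-set")
print("sharing jointly constrain the Ne trajectory.")
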