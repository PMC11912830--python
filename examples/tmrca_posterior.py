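"""Posterior age of an IBD segment under an inferred demography.

For segments of 8, 12 and 20 cM shared by two contemporaneous haplotypes in
a constant population of 5,000, prints the posterior mean and 95% interval
of the coalescence generation.  Longer segments coalesce more recently, and
almost all signal sits in the last ~50 generations.
"""

from transectne import NeTrajectory, PairContext, tmrca_posterior

ne = NeTrajectory.constant(5_000.0, 400)
print("length_cM  mean_gen  2.5%  median  97.5%")
for l_cm in (8.0, 12.0, 20.0):
    post = tmrca_posterior(l_cm / 100.0, PairContext(0, 0), ne, 350)
    q = post.quantile([0.025, 0.5, 0.975])
    print(f"{l_cm:8.1f}  {post.mean():8.1f}  {q[0]:4d}  {q[1]:6d}  {q[2]:5d}")

print("\nA 20 cM segment is typically only ~7 generations old; an 8 cM one")
print("can date back 40+ generations — this bounds the method's time depth.")
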