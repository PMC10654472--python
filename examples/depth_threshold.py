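"""Why a minimum read depth of 25 for pools of 25 individuals?

Each read at a site comes from one pooled individual, so low depth means
the allele-frequency estimate only "sees" a few fish.  This example runs
the resampling simulation behind the depth filter and prints how many
distinct individuals a given depth represents.
"""

from domescan.depth_calibration import DepthCalibConfig, choose_min_depth, distinct_individuals

res = distinct_individuals(DepthCalibConfig(pool_size=25, depth=25, replicates=200_000, seed=1))
print(f"pool of 25, depth 25: mean distinct individuals = {res.mean:.2f}")
print(f"lower 95% confidence limit = {res.lower_ci:.0f} individuals")

min_depth = choose_min_depth(pool_size=25, target_fraction=0.5, replicates=50_000, seed=2)
print(f"smallest depth whose lower bound covers half the pool: {min_depth}")

# The mean ~16 and lower bound >= 13 say that 25 reads reliably sample more
# than half of a 25-fish pool, which is what justifies filtering sites with
# depth < 25 before calling SNPs.
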