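"""Generate a synthetic sediment-core community, filter it, and rarefy it.

The generator plays the role of the sequenced core: a sample-by-family
count table over 25 time-ordered samples whose composition is driven by
two anticorrelated environmental trajectories (sea-ice-like and
SST-like).  We then apply the standard normalisation: keep families seen
in >= 3 samples with >= 10 reads, and resample every sample 500 times to
a common depth.
"""

import sedanet as sn

cm, ann, truth = sn.generate_community(seed=7)
print(f"community: {cm.shape[0]} samples x {cm.shape[1]} families, "
      f"depths {cm.sample_totals().min()}-{cm.sample_totals().max()}")

pelagic, benthic = sn.split_by_habitat(cm, ann)
print(f"habitat split: {len(pelagic.families)} pelagic, "
      f"{len(benthic.families)} benthic families")

filtered = sn.filter_families(pelagic, min_samples=3, min_total=10)
print(f"prevalence/abundance filter: {len(pelagic.families)} -> "
      f"{len(filtered.families)} pelagic families")

depth = int(filtered.sample_totals().min())
rs = sn.rarefy(filtered, depth=depth, n_iter=500, seed=8)
print(f"rarefied 500x to {depth} reads/sample; aggregate row totals all "
      f"~{rs.aggregate.sum(axis=1).iloc[0]:.1f}")
# The aggregate (mean over iterations) is the depth-normalised matrix all
# downstream correlation stages consume.
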