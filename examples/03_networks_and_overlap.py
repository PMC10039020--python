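"""Build the Spearman and copula networks and test their agreement.

The Spearman network links families whose rank correlation exceeds 0.4
at BH-adjusted p < 0.1 (positive edges only).  The Gaussian copula
graphical model instead fits a negative-binomial regression of every
family on IP25 and SST, maps counts to normal scores (Dunn-Smyth
residuals), and estimates a sparse precision matrix by graphical lasso —
its edges are conditional associations with the environmental signal
removed.  Agreement is the Jaccard index of the edge sets, judged
against a degree-preserving double-edge-swap null.
"""

import pandas as pd

import sedanet as sn

cm, ann, truth = sn.generate_community(seed=7)
ip25, sst = sn.generate_proxies(truth, noise_sd=0.05, seed=8,
                                truncate_young=True)
pelagic, _ = sn.split_by_habitat(cm, ann)
filtered = sn.filter_families(pelagic)
rs = sn.rarefy(filtered, int(filtered.sample_totals().min()), seed=9)
ages = rs.ages.to_numpy()

cr = sn.pairwise_spearman(rs.aggregate)
spearman_net = sn.build_network(cr, rho_min=0.4, alpha=0.1)
modules = sn.find_modules(spearman_net)
print(f"Spearman network: {spearman_net.number_of_nodes()} nodes, "
      f"{spearman_net.number_of_edges()} edges, "
      f"{len(set(modules.values()))} modules")

env = pd.DataFrame({
    "IP25": sn.tail_fill(sn.interpolate_to_ages(ip25, ages)),
    "SST": sn.tail_fill(sn.interpolate_to_ages(sst, ages)),
}, index=rs.aggregate.index)
counts = rs.aggregate.round().astype(int)
fits = sn.fit_marginals(counts, env)
scores = sn.dunn_smyth_residuals(fits, counts, seed=10)
graphs = sn.lambda_path(scores)  # 0.1 .. 1.0 plus the headline 0.51

report = sn.null_overlap(spearman_net.edges(), graphs, n_reps=10, seed=11)
print(report.to_frame().to_string(index=False, float_format="%.3f"))
# observed_jaccard far above null_max (exceedance 0) at moderate lambda
# means the two network methods agree on far more edges than degree
# structure alone explains.
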