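"""Patient-cohort RBP-target network, hub calling and severity analysis.

Simulates a 30-patient cohort where one hub RBP's footprint abundance drives
the translational efficiency of its 50 targets, correlates every candidate
pair, calls hubs by permutation, stratifies patients into four fibrosis
severity levels from marker genes and compares hub expression low vs high.
"""

import riboshift as rs

cohort, truth = rs.generate_cohort(
    n_patients=30, n_rbps=21, n_targets_per_hub=50, hub_strength=1.0,
    seed=8, severity_separation=2.0, rbp_severity_shift=0.45)

pairs = [(rbp, t) for rbp, ts in truth.rbp_targets.items() for t in ts]
edges = rs.correlate_pairs(cohort, pairs, pair_alpha=0.05)
print(f"{len(edges)} candidate RBP:target pairs, "
      f"{int(edges['significant'].sum())} significantly correlated")

hubs = rs.hub_test(edges, cohort, analyzed_genes=truth.target_genes,
                   n_perm=10_000, seed=9)
called = hubs.loc[hubs["hub"]]
print(f"hub RBPs (adjusted p < 0.05): {list(called['rbp'])} "
      f"(planted: {truth.hub_rbps})")
print(called[["rbp", "observed", "null_mean", "empirical_p", "padj"]]
      .to_string(index=False, float_format="%.4g"))

strat = rs.stratify_patients(cohort.tpm_mrna.loc[truth.marker_genes])
print("\npatients per severity level:",
      strat["severity"].value_counts().sort_index().to_dict())

ttests = rs.compare_rbp_by_severity(cohort.tpm_mrna.loc[truth.rbp_genes],
                                    strat)
hub = truth.hub_rbps[0]
print(f"{hub} low-vs-high severity t-test: t = "
      f"{ttests.loc[hub, 't']:.2f}, p = {ttests.loc[hub, 'p']:.4f}")
print("\nA hub correlates with more of its targets' TE than random gene sets "
      "do. A positive t means the hub is higher in high-fibrosis patients; "
      "with 7-8 patients per extreme group the planted shift is near the "
      "detection limit, so p fluctuates around 0.05 across simulations.")
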