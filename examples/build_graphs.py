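"""Turn one weighted connectome into binary graphs by all four schemes.

Generates a synthetic control-group SC and FC matrix (26 DMN ROIs), then
applies percentage thresholding, adaptive thresholding, partial correlation
and the Chow-Liu tree, printing the edge count and the cutoff each scheme
actually used.
"""

import connectoctrl as cc

cfg = cc.GeneratorConfig(seed=7)
sc = cc.generate_sc_matrix(cfg, "control")
fc = cc.generate_fc_matrix(cfg, "control")

print(f"SC matrix: {sc.n_nodes} nodes")
for frac in cc.STUDY_FRACTIONS:
    g = cc.percentage_threshold(sc, cc.ThresholdSpec(fraction=frac))
    print(f"  percentage {frac:>5}: {g.n_edges:3d} edges "
          f"(cutoff {g.provenance['cutoff']:.4f})")

g, cutoff = cc.adaptive_threshold(sc)
print(f"  adaptive        : {g.n_edges:3d} edges (largest connected cutoff "
      f"{cutoff:.4f})")

tree = cc.chow_liu_tree(sc)
print(f"  chow-liu        : {tree.n_edges:3d} edges (maximum-weight spanning tree)")

g = cc.partial_correlation_graph(fc, cc.ThresholdSpec(soft_threshold=0.1))
print(f"FC partial corr   : {g.n_edges:3d} edges (|rho| > 0.1)")

# A higher removal fraction can only shrink the edge set; the cutoff grows.
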