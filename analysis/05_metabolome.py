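"""Metabolome analysis: normalisation, PCA, PLS-DA/VIP, PMI clusters.

Sum-normalised, Pareto-scaled tissue features; PCA and PLS-DA across PMI
groups; VIP > 1.5 & P < 0.05 selects discriminating metabolites; Spearman
|r| > 0.6 & P < 0.001 selects PMI-correlated metabolites, split into a
negative cluster (1) and positive cluster (2).
"""

from common import run_config
from qmpdecomp.pipeline import run_stage

config = run_config(__doc__)
res = run_stage("metabolome", config)
print(f"PCA: PC1 explains {100 * res['pca_explained'][0]:.1f}% of variance")
print(f"PLS-DA: comp1 explains {100 * res['plsda'].explained_y[0]:.1f}% of group variance")
vip = res["vip"]
print(f"VIP-selected metabolites: {int(vip['selected'].sum())} "
      f"(top: {', '.join(vip.head(3).index)})")
corr = res["pmi_clusters"]
print(f"PMI-correlated metabolites: {int(corr['selected'].sum())}")
for c, comp in res["cluster_composition"].items():
    label = "positive" if c == 2 else "negative"
    top = comp.head(2)
    print(f"  cluster {c} ({label}, n={int((corr['cluster'] == c).sum())}): "
          + "; ".join(f"{k} {v:.1f}%" for k, v in top.items()))
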