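"""Microbiota-metabolite integration: Procrustes, Mantel, RDA, RF ranking.

Procrustes superimposes each domain's Bray-Curtis PCoA onto the metabolite
PCA; Mantel/partial Mantel correlate the distance matrices (each domain
controlling for the other); RDA apportions metabolite variance to total
loads, alpha diversity and phylum abundances; random forests rank the
metabolites most associated with each domain's total load.
"""

from common import run_config
from qmpdecomp.pipeline import run_stage

config = run_config(__doc__)
res = run_stage("integrate", config)
for domain in res["procrustes"]:
    pr = res["procrustes"][domain]
    ma = res["mantel"][domain]
    line = (f"{domain}: Procrustes r={pr.r:.3f} (M2={pr.m2:.3f}, P={pr.p_value}), "
            f"Mantel r={ma.r:.3f} (P={ma.p_value})")
    if domain in res["partial_mantel"]:
        pm = res["partial_mantel"][domain]
        line += f", partial Mantel r={pm.r:.3f} (P={pm.p_value})"
    print(line)
rda = res["rda"]
print(f"RDA: constrained fraction {rda['constrained_fraction']:.3f}; "
      f"top variable {rda['top_variable']}")
if "class_intersection" in res:
    print(f"metabolite classes shared across both domains' top-20: {len(res['class_intersection'])}")
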