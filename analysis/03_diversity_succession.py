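"""Alpha/beta diversity, key decomposers, and time-decay succession rates.

Shannon diversity and Bray-Curtis/PCoA per sample type; key decomposers as
genera with Spearman r > 0.6 and P < 0.001 against PMI on tissue QMP;
succession rates as the slope of community similarity vs time interval.
"""

from common import run_config
from qmpdecomp.pipeline import run_stage

config = run_config(__doc__)
res = run_stage("diversity", config)
for domain in ("bacteria", "fungi"):
    kd = res.get(f"key_decomposers_{domain}")
    if kd is not None:
        print(f"{domain}: {int(kd['key_decomposer'].sum())} key decomposers in tissue "
              f"(top: {', '.join(kd[kd['key_decomposer']].sort_values('r', ascending=False).head(5).index)})")
decay = res["time_decay"]
if len(decay):
    print("succession rates (|slope| of similarity vs day interval):")
    for _, row in decay.iterrows():
        print(f"  {row['domain']:8s} {row['sample_type']:12s} {row['mode']}: "
              f"slope {row['slope']:+.4f} (P={row['p_value']:.2g})")
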