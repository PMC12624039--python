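"""Simulate the decomposition cohort and write the tabular bundle.

The cohort mirrors the buried-carcass design: 7 exhumation days x 6
replicates for grave soil and tissue, 8 days (incl. day 0) for regular
soil — 132 samples, bacteria and fungi profiled separately with 3
spike-ins each, plus a tissue metabolome with planted PMI trends.
"""

from common import run_config
from qmpdecomp.pipeline import run_stage

config = run_config(__doc__)
bundle = run_stage("simulate", config)
meta = bundle.metadata
print(f"simulated {len(meta)} samples: " + ", ".join(f"{k}={v}" for k, v in meta['sample_type'].value_counts().items()))
for domain, counts in bundle.counts.items():
    print(f"  {domain}: {len(counts.taxa)} rows x {len(counts.samples)} samples (incl. spike rows)")
print(f"bundle written to {config.outdir}")
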