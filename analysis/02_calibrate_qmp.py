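"""Fit per-sample spike-in standard curves and derive QMP + RMP profiles.

QMP: log10(reads) regressed on log10(input spike copies) per sample, the
curve inverted for every taxon, and copies divided by the documented
extract mass. RMP: spike rows removed, reads rarefied to the minimum
sample total.
"""

from common import run_config
from qmpdecomp.pipeline import run_stage

config = run_config(__doc__)
profiles = run_stage("calibrate", config)
for domain, p in profiles.items():
    rep = p["report"]
    print(
        f"{domain}: {int(rep['usable'].sum())}/{len(rep)} samples calibrated; "
        f"slope {rep['slope'].mean():.3f} +/- {rep['slope'].std():.3f}, "
        f"median R^2 {rep['r_squared'].median():.4f}"
    )
    print(f"  rarefied depth: {int(p['rmp'].data.sum(axis=0).iloc[0])} reads/sample")
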