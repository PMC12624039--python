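"""QMP-vs-RMP comparison: trend discordance and network edge overlap.

For the top 100 genera, early (days 1-7) vs late (days 14-35) Wilcoxon
tests are run separately on absolute (QMP) and relative (RMP) profiles and
each genus classified; a genus whose RMP trend is unsupported or opposed
by QMP is 'contrasting' — the compositional artifact the study exposes.
"""

from common import run_config
from qmpdecomp.pipeline import run_stage

config = run_config(__doc__)
res = run_stage("diversity", config)
for key, table in res.items():
    if key.startswith("discordance_"):
        counts = table["classification"].value_counts().to_dict()
        print(f"{key.removeprefix('discordance_')}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
net = run_stage("network", config)
for domain in ("bacteria", "fungi"):
    ov = net.get(f"overlap_{domain}")
    if ov is not None:
        print(f"{domain} tissue networks: {ov['shared']} shared edges "
              f"({ov['pct_of_b']:.1f}% of RMP edges overlap QMP)")
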