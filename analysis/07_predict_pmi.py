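"""PMI prediction: optimized random-forest models per feature set.

Stratified 2:1 split within each exhumation day; features ranked by
out-of-bag IncMSE and the top-k subset chosen by repeated 10-fold CV;
the final model refit repeatedly on the fixed split, reporting MAE and
R^2 (mean +/- SD in days) for QMP, RMP, metabolite and multi-omics
feature sets.
"""

from common import run_config
from qmpdecomp.pipeline import run_stage

config = run_config(__doc__)
res = run_stage("predict", config)
rec = res["records"]
print(f"null predictor test MAE: {rec['null_test_mae']:.2f} days")
for name, r in rec.items():
    if name == "null_test_mae":
        continue
    tm, ts = r["test_mae"]
    print(f"{name:14s} k*={r['best_k']:>3}  test MAE {tm:.2f} +/- {ts:.2f}  "
          f"R^2 {r['test_r2'][0]:.2f}")
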