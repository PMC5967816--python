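"""Compute the four scalar injury metrics and their logistic classifiers.

BrIC summarizes the impact kinematics (root-sum-square of per-axis peak
angular velocity over the critical values 30.4/35.6/23.5 rad/s); CSDM-WB and
CSDM-CC are the volume fractions of brain / corpus callosum with MPS above
0.2; Peak-CC is the maximum fiber strain in the corpus callosum. Each metric
is fit to the injury labels by univariate logistic regression and scored by
its training AUC — the traditional single-training-set protocol.
"""

from strainclass import (fit_univariate_logistic, generate_dataset,
                         metric_table, predict_logistic, roc_auc)
from strainclass.presets import desk_generator_config

dataset = generate_dataset(desk_generator_config(seed=1))
table = metric_table(dataset)
print(table.head(6).round(3).to_string(index=False))

y = table["label"].to_numpy()
for metric in ("BrIC", "CSDM_WB", "CSDM_CC", "Peak_CC"):
    x = table[metric].to_numpy()
    model = fit_univariate_logistic(x, y, metric_name=metric)
    probs = predict_logistic(model, x)
    auc = roc_auc(probs, y)[0]
    acc = ((probs >= 0.5).astype(int) == y).mean()
    print(f"{metric:8s} slope={model.slope:+.3f}  training AUC={auc:.3f}  "
          f"training accuracy={acc:.3f}")
# Training AUC overstates generalization: compare with the cross-validated
# numbers from examples/03_loocv_compare.py.
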