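"""Cross-endpoint SHAP-quintile selection of fingerprint bits.

Generates a synthetic panel with 20 fingerprint bits planted as informative
for all three endpoint groups (the shared core) plus 15 endpoint-private
bits each, runs the selection, and reports how much of the planted
structure survives the quintile intersection.
"""

import pandas as pd

from woeqsar import SyntheticConfig, generate_panel, select_features, \
    split_train_test
from woeqsar.dataset import ModelingDataset

cfg = SyntheticConfig(n_compounds=900, seed=11)
fp, records, truth = generate_panel(cfg)

X = fp.to_frame()
X.index = X.index.astype(str)
Y = pd.DataFrame({ep: truth.labels[ep] for ep in ("Y1", "Y2", "Y3")},
                 index=X.index)
ds = split_train_test(ModelingDataset(X=X, Y=Y), ratio=0.8, seed=11)

result = select_features(ds, fraction=0.2, seed=11)

core = set(truth.core)
private = set().union(*truth.private.values())
selected = set(result.selected)

print(f"Per-endpoint quintile size: {len(next(iter(result.top_sets.values())))} "
      f"of {cfg.n_features} bits")
print(f"Selected (intersection of the three quintiles): {len(selected)} bits")
print(f"Planted shared core recovered: {len(selected & core)}/{len(core)}")
print(f"Endpoint-private bits leaking in: {len(selected & private)}/{len(private)}")
print()
print("Top 10 selected bits by mean importance:")
names = list(X.columns)
for i in result.selected[:10]:
    flag = "core" if i in core else ("private" if i in private else "null")
    mean_imp = sum(result.rankings[ep].importance[i] for ep in result.rankings) / 3
    print(f"  {names[i]:<14} mean |SHAP| = {mean_imp:.4f}  [{flag}]")
print()
print("Bits informative for all three evidence groups dominate the"
      " intersection; bits driving only one endpoint are filtered out.")
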