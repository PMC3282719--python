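"""Differentiation-stage classification from chromatin states.

Three classifiers over the decoded state matrix:
- LOOCV SVM (linear and radial kernels) on the 24 labeled normal lines,
  compared against the majority-class null model;
- the three-number module-fraction multinomial logit (fraction of Core / PRC /
  MYC module genes in the non-active state) with the >0.5 / "unknown" rule;
- average-linkage hierarchical clustering on state Hamming distance.
The 3 cancer lines are held out of all training and classified afterwards.
"""

from chromstage import SimConfig, simulate_dataset
from chromstage.classify import (
    classify_module_logit, classify_new_lines, fit_module_logit,
    hierarchical_cluster_cell_lines, loocv_svm, module_fractions,
    null_model_accuracy,
)
from chromstage.hmm import decode_states, fit_common_model

ds = simulate_dataset(SimConfig(seed=0))
model = fit_common_model(ds.gene_scores, ds.annotation, seed=0)
states = decode_states(model, ds.gene_scores, ds.annotation)

normal = ds.metadata[ds.metadata["label"] != "C"]
cancer = ds.metadata[ds.metadata["label"] == "C"]
X = states[normal["cell_line"]].T
y = normal["label"].to_numpy()

print(f"null model (always predict the largest class): "
      f"{null_model_accuracy(y):.1f}%")
for kernel in ("linear", "radial"):
    rep = loocv_svm(X, y, kernel=kernel, seed=0, representation="state")
    print(f"LOOCV SVM, {kernel:>6} kernel, state representation: "
          f"{rep.accuracy:.1f}%")

Xc = states[cancer["cell_line"]].T
calls = classify_new_lines(X, y, Xc, kernel="linear", seed=0)
print(f"cancer lines (held out of training) classified as: {calls.to_dict()}\n")

# -- module-fraction logit --------------------------------------------------
fracs, _ = module_fractions(states, ds.modules)
print("non-active fraction per ES-cell module (first lines):")
print(fracs.head(6).round(3).to_string())
logit = fit_module_logit(fracs.loc[normal["cell_line"]], y)
pred = classify_module_logit(logit, fracs)
train_acc = (pred.loc[normal["cell_line"]].to_numpy() == y).mean()
print(f"\nmodule-logit training accuracy (>0.5 rule, 'unknown' excluded "
      f"from neither side): {100 * train_acc:.1f}%")
print(f"cancer-line module-logit calls: "
      f"{pred.loc[cancer['cell_line']].to_dict()}\n")

# -- hierarchical clustering ------------------------------------------------
_, leaves, flat = hierarchical_cluster_cell_lines(states[normal["cell_line"]],
                                                  n_clusters=3)
print("dendrogram leaf order (normal lines):")
print("  " + " ".join(leaves))
print("flat 3-way clusters:", flat.to_dict())
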