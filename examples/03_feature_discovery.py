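"""Two-pronged feature refinement on a known marker panel.

Simulates core-level spectra with 5 marker features among 200, screens every
feature with the likelihood-ratio test and the Kruskal-Wallis test (with
Benjamini-Hochberg FDR control), and compares the overlap-selected panel to
the generator's ground truth.
"""

import numpy as np

from msitma import MassAxis, SimulationConfig, select_and_refit, simulate_core_table
from msitma.classify import CoreFeatureTable
from msitma.preprocessing import median_fold_change_normalize

cfg = SimulationConfig(seed=11, cores_per_slide=50, n_features=200, n_markers=5,
                       marker_log2_effect=1.0, noise_sd=0.3)
X, y, slides, patients, truth = simulate_core_table(cfg)
Xn, _ = median_fold_change_normalize(X)
table = CoreFeatureTable(Xn, y, slides, patients, MassAxis(truth["true_mz"]))

result = select_and_refit(table, cv_seed=0, alpha=0.05)
sel = result.selection

print(f"features screened: {table.n_features}")
print(f"LRT-significant (p < 0.05):        {sel.multivariate_significant.size}")
print(f"KW + BH significant (q < 0.05):    {sel.univariate_significant.size}")
print(f"selected (overlap of both):        {sel.selected.size}")
print(f"true marker indices: {sorted(truth['marker_indices'])}")
print(f"selected indices:    {sorted(sel.selected)}")
print(f"selected m/z:        {np.round(table.axis.mz[sel.selected], 3)}")
print(f"AUC full model:    {result.cv_full.roc.auc:.3f}")
print(f"AUC reduced model: {result.cv_reduced.roc.auc:.3f}")
print()
print("-> the intersection rule keeps the features both screens agree on;")
print("   with a 2-fold marker effect it recovers the planted panel with few")
print("   or no false selections, and the reduced model keeps the full")
print("   model's discrimination.")
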