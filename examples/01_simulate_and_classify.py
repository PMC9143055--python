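"""End-to-end demo: synthetic TMA -> preprocessing -> per-core diagnosis.

Simulates the bundled demo conditions (3 slides, 132 annotated cores at
~8:1 tumour:normal, 5 marker m/z features with a 2-fold tumour effect),
runs the full pipeline and prints the cross-validated metrics of the
cost-weighted logistic regression before and after feature refinement.
"""

import json

from msitma.pipeline import demo_run_metrics

metrics = demo_run_metrics(seed=1)

print(json.dumps(metrics, indent=2))
print()
print(f"Cores classified: {metrics['n_cores']}; the model recovered "
      f"{metrics['n_selected']} features (of {metrics['n_markers_true']} true markers).")
print("metrics_full are out-of-fold rates of the all-features model at "
      "threshold 0.5; metrics_reduced are the same after keeping only the "
      "features significant in both the LRT and Kruskal-Wallis screens. "
      "F1 near 1.0 means essentially every core is called correctly despite "
      "the 8:1 class imbalance and per-slide batch effects.")
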