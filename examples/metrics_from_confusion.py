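"""Compute the full metric suite from a 4-class confusion matrix.

The matrix below is a published multiclass motor-imagery result (rows = true
class, columns = predicted).  Per class the script prints precision, recall
and F1; overall it prints accuracy, the exact macro-F1 and Cohen's kappa.
"""

import numpy as np

from mseienet import ConfusionMatrix, metrics_report

cm = ConfusionMatrix(
    np.array([
        [242, 8, 6, 3],
        [4, 247, 4, 4],
        [4, 4, 248, 3],
        [6, 7, 6, 240],
    ]),
    class_names=("L", "R", "F", "T"),
)
report = metrics_report(cm)
rounded = report.rounded()

print("class   PR      RE      F1")
for name, vals in rounded["per_class"].items():
    print(f"{name}     {vals['PR']:6.2f}  {vals['RE']:6.2f}  {vals['F1']:6.2f}")
print(f"\nACC   = {report.accuracy:.4f} %")
print(f"MF1   = {rounded['MF1']:.2f} % (exact mean of unrounded per-class F1)")
print(f"kappa = {rounded['kappa']:.2f}")
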