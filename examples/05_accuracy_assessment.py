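"""Confusion-matrix accuracy assessment.

Builds the error matrix from reference and predicted labels and reports
producer's accuracy (omission-error complement), user's accuracy
(commission-error complement), overall accuracy, and the chance-corrected
kappa coefficient.
"""

import numpy as np

from marshphen import ConfusionMatrix, accuracy_metrics
from marshphen.synthetic import CLASS_NAMES

# rows = reference, columns = predicted; 4 classes
counts = np.array(
    [[65, 2, 3, 0],
     [1, 50, 0, 4],
     [5, 0, 52, 0],
     [0, 6, 1, 61]]
)
cm = ConfusionMatrix(counts, class_order=("PA", "SS", "TC", "TF"))
report = accuracy_metrics(cm)

print(f"{'class':<22} {'PA':>7} {'UA':>7}")
for label in cm.class_order:
    print(f"{CLASS_NAMES[label]:<22} {report.pa[label]:7.4f} {report.ua[label]:7.4f}")
print(f"overall accuracy: {100 * report.oa:.2f}%")
print(f"kappa           : {report.kappa:.4f}  (po {report.po:.4f}, pe {report.pe:.4f})")
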