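"""Combine detection indices into the Weighted Discriminator.

WD = 0.4*TPR + 0.6*Acc - FPR, with TPR and Acc per-unit and
FPR = FP/min x duration of one false positive (4/60 min offline,
1/60 min pseudo-online).  WD = 1 is perfect; negative values mean false
activations outweigh the detections.
"""

from neurogait import weighted_discriminator
from neurogait.evaluate import FP_DURATION_MIN

cases = [
    ("clean offline stop model", "offline", 87.50, 0.38, 98.00),
    ("perfect pseudo-online run", "pseudo_online", 100.00, 0.00, 100.00),
    ("high TPR but noisy", "pseudo_online", 100.00, 5.14, 83.57),
    ("conservative detector", "pseudo_online", 62.50, 0.00, 100.00),
]
print("case                        TPR%   FP/min  Acc%    WD")
for label, protocol, tpr, fpmin, acc in cases:
    wd = weighted_discriminator(tpr, acc, fpmin, FP_DURATION_MIN[protocol])
    print(f"{label:26s}  {tpr:6.2f}  {fpmin:5.2f}  {acc:6.2f}  {wd:5.2f}")
print("\nNote how 100% Acc with 0 FP/min still scores only 0.85 when TPR is 62.5%:")
print("WD penalizes missed events, not just false alarms.")
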