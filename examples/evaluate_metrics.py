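"""Confusion-matrix metrics and the rank-based AUC on a worked example.

Shows how a sensitivity/specificity pair on a balanced independent split
pins down the full confusion matrix, and hence ACC and MCC.
"""

import pvpstack as pv

# A balanced 63 + 63 split where Sn = 0.810 and Sp = 0.952 force
# tp=51, fn=12, tn=60, fp=3.
c = pv.ConfusionCounts(tp=51, fn=12, tn=60, fp=3)
acc, sn, sp, mcc = pv.metrics_from_confusion(c)
print(f"tp={c.tp} fn={c.fn} tn={c.tn} fp={c.fp}  (n={c.n})")
print(f"ACC {acc:.3f}  Sn {sn:.3f}  Sp {sp:.3f}  MCC {mcc:.3f}")

labels = [1, 1, 1, 0, 0, 0]
scores = [0.9, 0.8, 0.4, 0.6, 0.2, 0.1]
print(f"AUC of a small score set: {pv.auc(labels, scores):.3f}")
print()
print("MCC balances all four confusion counts; AUC is the probability a")
print("random positive outscores a random negative (ties count half).")
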