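"""Encode a protein sequence with the sequence and profile descriptors.

Builds one short synthetic protein plus a synthetic PSI-BLAST-style profile,
runs every encoder and prints the dimension and a few leading values of
each feature vector.
"""

import pvpstack as pv

cfg = pv.SyntheticConfig(n_pos=1, n_neg=1, length_range=(60, 60), seed=42)
record = pv.generate_labeled_sequences(cfg)[0]
profile = pv.generate_synthetic_pssm(record, concentration=7.0, seed=42)

print(f"sequence ({len(record.sequence)} aa): {record.sequence[:40]}...")
feats = pv.encode_all([record], {record.id: profile}, pv.ALL_DESCRIPTORS)
for desc, frame in feats.items():
    head = ", ".join(f"{v:.3f}" for v in frame.iloc[0, :4])
    print(f"{desc:>9s}  dim {frame.shape[1]:>3d}  first values: {head}")

print()
print("AAC entries are residue frequencies (sum to 1); CTD blocks describe")
print("physicochemical group composition/transitions/positions; the PSSM")
print("descriptors summarize the logistic-squashed evolutionary profile.")
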