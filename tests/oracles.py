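"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain explicit loops, deliberately avoiding
the vectorized code paths of the package. Shared constant tables (group
definitions, property scales) are imported; the computations are not.
"""

import math

import numpy as np

from pvpstack._tables import (
    CTD_GROUPS,
    DEFAULT_AAINDEX,
    PAAC_HYDROPHILICITY,
    PAAC_HYDROPHOBICITY,
    PAAC_SIDECHAIN_MASS,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
PSSM_ORDER = "ARNDCQEGHILKMFPSTWYV"

# synonymous-codon counts of the standard genetic code, restated here
CODONS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}


def aac(seq):
    return [seq.count(a) / len(seq) for a in AA]


def dpc(seq):
    out = []
    for a in AA:
        for b in AA:
            c = sum(1 for i in range(len(seq) - 1) if seq[i] == a and seq[i + 1] == b)
            out.append(c / (len(seq) - 1))
    return out


def dde(seq):
    out = []
    freqs = dpc(seq)
    i = 0
    for a in AA:
        for b in AA:
            tm = (CODONS[a] / 61) * (CODONS[b] / 61)
            tv = tm * (1 - tm) / (len(seq) - 1)
            out.append((freqs[i] - tm) / math.sqrt(tv))
            i += 1
    return out


def _group_of(prop, ch):
    for g, members in enumerate(CTD_GROUPS[prop]):
        if ch in members:
            return g
    raise KeyError(ch)


def ctdc(seq):
    out = []
    for prop in CTD_GROUPS:
        for g in range(3):
            out.append(sum(1 for ch in seq if _group_of(prop, ch) == g) / len(seq))
    return out


def ctdt(seq):
    out = []
    for prop in CTD_GROUPS:
        for pair in [(0, 1), (0, 2), (1, 2)]:
            c = 0
            for i in range(len(seq) - 1):
                gs = {_group_of(prop, seq[i]), _group_of(prop, seq[i + 1])}
                if gs == set(pair):
                    c += 1
            out.append(c / (len(seq) - 1))
    return out


def ctdd(seq):
    out = []
    for prop in CTD_GROUPS:
        for g in range(3):
            pos = [i + 1 for i, ch in enumerate(seq) if _group_of(prop, ch) == g]
            if not pos:
                out.extend([0.0] * 5)
                continue
            n = len(pos)
            for q in [None, 0.25, 0.5, 0.75, 1.0]:
                k = 1 if q is None else max(1, math.ceil(q * n))
                out.append(100.0 * pos[k - 1] / len(seq))
    return out


def _standardize(table):
    vals = [table[a] for a in AA]
    mean = sum(vals) / 20
    std = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20)
    return {a: (table[a] - mean) / std for a in AA}


def paac(seq, lam=1, w=0.05):
    props = [
        _standardize(t)
        for t in [PAAC_HYDROPHOBICITY, PAAC_HYDROPHILICITY, PAAC_SIDECHAIN_MASS]
    ]
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(len(seq) - k):
            a, b = seq[i], seq[i + k]
            total += sum((p[b] - p[a]) ** 2 for p in props) / 3
        thetas.append(total / (len(seq) - k))
    denom = 1 + w * sum(thetas)
    comp = [seq.count(a) / len(seq) / denom for a in AA]
    return comp + [w * t / denom for t in thetas]


def apaac(seq, lam=1, w=0.05):
    props = [_standardize(t) for t in [PAAC_HYDROPHOBICITY, PAAC_HYDROPHILICITY]]
    taus = []
    for k in range(1, lam + 1):
        for p in props:
            total = sum(p[seq[i]] * p[seq[i + k]] for i in range(len(seq) - k))
            taus.append(total / (len(seq) - k))
    denom = 1 + w * sum(taus)
    comp = [seq.count(a) / len(seq) / denom for a in AA]
    return comp + [w * t / denom for t in taus]


def eaac(seq, window=5):
    n_win = len(seq) - window + 1
    out = []
    for a in AA:
        acc = 0.0
        for s in range(n_win):
            acc += seq[s : s + window].count(a) / window
        out.append(acc / n_win)
    return out


def aai(seq, indices=None):
    indices = DEFAULT_AAINDEX if indices is None else indices
    out = []
    for table in indices.values():
        vals = [table[a] for a in AA]
        lo, hi = min(vals), max(vals)
        out.append(sum((table[ch] - lo) / (hi - lo) for ch in seq) / len(seq))
    return out


def _sig(x):
    return 1.0 / (1.0 + math.exp(-x))


def pssm_aac(scores):
    L = len(scores)
    out = []
    for a in AA:
        j = PSSM_ORDER.index(a)
        out.append(sum(_sig(scores[i][j]) for i in range(L)) / L)
    return out


def pssm_com(scores, residues):
    out = []
    for r in AA:
        rows = [i for i, ch in enumerate(residues) if ch == r]
        for a in AA:
            j = PSSM_ORDER.index(a)
            if rows:
                out.append(sum(_sig(scores[i][j]) for i in rows) / len(rows))
            else:
                out.append(0.0)
    return out


def pssm_dp(scores):
    L = len(scores)
    out = []
    for a in AA:
        j = PSSM_ORDER.index(a)
        for b in AA:
            k = PSSM_ORDER.index(b)
            total = sum(_sig(scores[i][j]) * _sig(scores[i + 1][k]) for i in range(L - 1))
            out.append(total / (L - 1))
    return out


def auc_trapezoid(labels, scores):
    """AUC by explicit trapezoidal integration of the ROC curve."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = scores >= t
        tpr.append(np.sum(pred & (labels == 1)) / n_pos)
        fpr.append(np.sum(pred & (labels == 0)) / n_neg)
    return float(np.trapezoid(tpr, fpr))


def random_sequence(rng, min_len=2, max_len=30):
    L = int(rng.integers(min_len, max_len + 1))
    return "".join(AA[i] for i in rng.integers(0, 20, size=L))
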