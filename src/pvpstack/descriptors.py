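"""Fixed-length numeric descriptors of protein sequences and PSSM profiles.

Thirteen encoders from four views of a protein: composition (AAC, DPC, DDE,
PAAC, APAAC, EAAC), composition-transition-distribution over physicochemical
groupings (CTDC, CTDT, CTDD), profile-derived position-specific information
(PSSM_AAC, PSSM_DP, PSSM_COM) and physicochemical indices (AAI). Each
encoder returns a :class:`FeatureVector` with stable, human-readable column
names; :func:`encode_all` assembles per-descriptor feature matrices.

Composition vectors index residues alphabetically (A, C, D, ..., Y). PSSM
encoders consume profiles in PSI-BLAST column order and re-order internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._tables import (
    CODON_COUNTS,
    CTD_GROUPS,
    DEFAULT_AAINDEX,
    PAAC_HYDROPHILICITY,
    PAAC_HYDROPHOBICITY,
    PAAC_SIDECHAIN_MASS,
)
from .seqio import PSSM_AA_ORDER, STANDARD_AA, PssmProfile, ProteinRecord

ALL_DESCRIPTORS = (
    "AAC", "AAI", "APAAC", "CTDC", "CTDD", "CTDT", "DDE", "DPC", "EAAC",
    "PAAC", "PSSM_AAC", "PSSM_COM", "PSSM_DP",
)
PSSM_DESCRIPTORS = ("PSSM_AAC", "PSSM_COM", "PSSM_DP")

#: Declared output dimension of each descriptor (at default parameters).
DESCRIPTOR_DIMS = {
    "AAC": 20, "AAI": 11, "APAAC": 22, "CTDC": 39, "CTDT": 39, "CTDD": 195,
    "DDE": 400, "DPC": 400, "EAAC": 20, "PAAC": 21, "PSSM_AAC": 20,
    "PSSM_COM": 400, "PSSM_DP": 400,
}

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
_DIPEPTIDES = tuple(a + b for a in STANDARD_AA for b in STANDARD_AA)


@dataclass(frozen=True)
class FeatureVector:
    descriptor: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.names):
            raise ValueError(
                f"{self.descriptor}: {len(self.names)} names for shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{self.descriptor}: non-finite feature values")


def _counts(seq: str) -> np.ndarray:
    c = np.zeros(20)
    for ch in seq:
        c[_AA_INDEX[ch]] += 1
    return c


def _require_length(seq: str, n: int, who: str) -> None:
    if len(seq) < n:
        raise ValueError(f"{who}: sequence length {len(seq)} < required {n}")


def encode_aac(seq: str) -> FeatureVector:
    """Amino-acid composition: frequency of each of the 20 residues (sums to 1)."""
    _require_length(seq, 1, "AAC")
    vals = _counts(seq) / len(seq)
    return FeatureVector("AAC", tuple(STANDARD_AA), vals)


def encode_dpc(seq: str) -> FeatureVector:
    """Dipeptide composition: frequency of the 400 ordered residue pairs."""
    _require_length(seq, 2, "DPC")
    vals = np.zeros(400)
    for i in range(len(seq) - 1):
        vals[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + 1]]] += 1
    vals /= len(seq) - 1
    return FeatureVector("DPC", _DIPEPTIDES, vals)


def encode_dde(seq: str) -> FeatureVector:
    """Dipeptide deviation from expected mean.

    For dipeptide ij: Dc = observed frequency, Tm = (Ci/61)(Cj/61) the
    codon-usage-expected mean, Tv = Tm(1-Tm)/(L-1) its variance, and
    DDE = (Dc - Tm)/sqrt(Tv), with Ci the synonymous-codon count of residue i.
    """
    _require_length(seq, 2, "DDE")
    dc = encode_dpc(seq).values
    n_pairs = len(seq) - 1
    vals = np.empty(400)
    for idx, (a, b) in enumerate(_DIPEPTIDES):
        tm = (CODON_COUNTS[a] / 61.0) * (CODON_COUNTS[b] / 61.0)
        tv = tm * (1.0 - tm) / n_pairs
        vals[idx] = (dc[idx] - tm) / math.sqrt(tv)
    return FeatureVector("DDE", _DIPEPTIDES, vals)


def _ctd_group_index(prop: str) -> dict[str, int]:
    groups = CTD_GROUPS[prop]
    out: dict[str, int] = {}
    for g, members in enumerate(groups):
        for aa in members:
            out[aa] = g
    return out


def encode_ctdc(seq: str) -> FeatureVector:
    """CTD composition: fraction of residues in each of 3 groups x 13 properties."""
    _require_length(seq, 1, "CTDC")
    names, vals = [], []
    for prop in CTD_GROUPS:
        gi = _ctd_group_index(prop)
        counts = [0, 0, 0]
        for ch in seq:
            counts[gi[ch]] += 1
        for g in range(3):
            names.append(f"{prop}.G{g + 1}")
            vals.append(counts[g] / len(seq))
    return FeatureVector("CTDC", tuple(names), np.array(vals))


def encode_ctdt(seq: str) -> FeatureVector:
    """CTD transition: fraction of adjacent pairs crossing each group boundary.

    Per property, the three unordered group pairs (1-2, 1-3, 2-3) are counted
    in either direction and divided by L-1.
    """
    _require_length(seq, 2, "CTDT")
    names, vals = [], []
    for prop in CTD_GROUPS:
        gi = _ctd_group_index(prop)
        trans = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        for i in range(len(seq) - 1):
            a, b = gi[seq[i]], gi[seq[i + 1]]
            if a != b:
                trans[(min(a, b), max(a, b))] += 1
        for (a, b), c in trans.items():
            names.append(f"{prop}.T{a + 1}{b + 1}")
            vals.append(c / (len(seq) - 1))
    return FeatureVector("CTDT", tuple(names), np.array(vals))


_CTD_QUANTILES = (("first", None), ("p25", 0.25), ("p50", 0.50), ("p75", 0.75), ("p100", 1.0))


def encode_ctdd(seq: str) -> FeatureVector:
    """CTD distribution: positional percentiles of each group's occurrences.

    For each property and group, the 1-based positions of the 1st and the
    ceil(q*n)-th occurrence (q = 25/50/75/100 %) are reported as 100*pos/L;
    a group absent from the sequence contributes five zeros.
    """
    _require_length(seq, 1, "CTDD")
    L = len(seq)
    names, vals = [], []
    for prop in CTD_GROUPS:
        gi = _ctd_group_index(prop)
        positions: list[list[int]] = [[], [], []]
        for i, ch in enumerate(seq, start=1):
            positions[gi[ch]].append(i)
        for g in range(3):
            occ = positions[g]
            for qname, q in _CTD_QUANTILES:
                names.append(f"{prop}.G{g + 1}.{qname}")
                if not occ:
                    vals.append(0.0)
                else:
                    k = 1 if q is None else max(1, math.ceil(q * len(occ)))
                    vals.append(100.0 * occ[k - 1] / L)
    return FeatureVector("CTDD", tuple(names), np.array(vals))


def encode_ctd(seq: str) -> tuple[FeatureVector, FeatureVector, FeatureVector]:
    """Composition, transition and distribution vectors (39 + 39 + 195)."""
    return encode_ctdc(seq), encode_ctdt(seq), encode_ctdd(seq)


def _standardized(table: Mapping[str, float]) -> dict[str, float]:
    vals = np.array([table[aa] for aa in STANDARD_AA])
    mean = vals.mean()
    std = math.sqrt(float(np.mean((vals - mean) ** 2)))
    return {aa: (table[aa] - mean) / std for aa in STANDARD_AA}


_PAAC_PROPS = tuple(
    _standardized(t)
    for t in (PAAC_HYDROPHOBICITY, PAAC_HYDROPHILICITY, PAAC_SIDECHAIN_MASS)
)
_APAAC_PROPS = tuple(
    _standardized(t) for t in (PAAC_HYDROPHOBICITY, PAAC_HYDROPHILICITY)
)


def encode_paac(seq: str, lam: int = 1, w: float = 0.05) -> FeatureVector:
    """Pseudo amino-acid composition (20 + lam entries, sums to 1).

    theta_k is the mean over sequence positions of the average squared
    difference of three standardized properties (hydrophobicity,
    hydrophilicity, side-chain mass) between residues k apart.
    """
    if lam < 1:
        raise ValueError("PAAC: lam must be >= 1")
    if len(seq) <= lam:
        raise ValueError(f"PAAC: sequence length {len(seq)} must exceed lam={lam}")
    freqs = _counts(seq) / len(seq)
    thetas = []
    for k in range(1, lam + 1):
        s = 0.0
        for i in range(len(seq) - k):
            a, b = seq[i], seq[i + k]
            s += sum((p[b] - p[a]) ** 2 for p in _PAAC_PROPS) / len(_PAAC_PROPS)
        thetas.append(s / (len(seq) - k))
    denom = 1.0 + w * sum(thetas)
    vals = np.concatenate([freqs / denom, w * np.array(thetas) / denom])
    names = tuple(STANDARD_AA) + tuple(f"theta{k}" for k in range(1, lam + 1))
    return FeatureVector("PAAC", names, vals)


def encode_apaac(seq: str, lam: int = 1, w: float = 0.05) -> FeatureVector:
    """Amphiphilic pseudo amino-acid composition (20 + 2*lam entries).

    The 2*lam sequence-order factors are gap-k mean products of standardized
    hydrophobicity and hydrophilicity; normalization as in PAAC.
    """
    if lam < 1:
        raise ValueError("APAAC: lam must be >= 1")
    if len(seq) <= lam:
        raise ValueError(f"APAAC: sequence length {len(seq)} must exceed lam={lam}")
    freqs = _counts(seq) / len(seq)
    taus = []
    for k in range(1, lam + 1):
        for p in _APAAC_PROPS:
            s = sum(p[seq[i]] * p[seq[i + k]] for i in range(len(seq) - k))
            taus.append(s / (len(seq) - k))
    denom = 1.0 + w * sum(taus)
    vals = np.concatenate([freqs / denom, w * np.array(taus) / denom])
    names = tuple(STANDARD_AA) + tuple(
        f"tau{k}.{p}" for k in range(1, lam + 1) for p in ("hydrophobicity", "hydrophilicity")
    )
    return FeatureVector("APAAC", names, vals)


def encode_eaac(seq: str, window: int = 5) -> FeatureVector:
    """Enhanced amino-acid composition: AAC averaged over sliding windows.

    Window AACs (size ``window``, stride 1) are averaged into a single
    20-vector so the dimension is sequence-length independent.
    """
    if window < 1:
        raise ValueError("EAAC: window must be >= 1")
    _require_length(seq, window, "EAAC")
    acc = np.zeros(20)
    n_windows = len(seq) - window + 1
    for start in range(n_windows):
        acc += _counts(seq[start : start + window]) / window
    return FeatureVector("EAAC", tuple(STANDARD_AA), acc / n_windows)


def _minmax(table: Mapping[str, float]) -> dict[str, float]:
    vals = [table[aa] for aa in STANDARD_AA]
    lo, hi = min(vals), max(vals)
    return {aa: (table[aa] - lo) / (hi - lo) for aa in STANDARD_AA}


def encode_aai(
    seq: str, index_set: Mapping[str, Mapping[str, float]] | None = None
) -> FeatureVector:
    """Mean per-residue value of 11 physicochemical indices.

    Each index is min-max normalized to [0, 1] over the 20 residues before
    averaging over sequence positions. The default set covers hydropathy,
    hydrophilicity, mass, volume, polarity, isoelectric point, flexibility,
    accessibility and helix/sheet/turn propensity; any mapping of
    ``name -> {residue: value}`` with full residue coverage may be supplied.
    """
    _require_length(seq, 1, "AAI")
    index_set = DEFAULT_AAINDEX if index_set is None else index_set
    names, vals = [], []
    for name, table in index_set.items():
        missing = set(STANDARD_AA) - set(table)
        if missing:
            raise ValueError(f"AAI index {name!r} missing residues {sorted(missing)}")
        norm = _minmax(table)
        names.append(name)
        vals.append(sum(norm[ch] for ch in seq) / len(seq))
    return FeatureVector("AAI", tuple(names), np.array(vals))


# --- PSSM-profile descriptors ----------------------------------------------

_SQUASHERS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "identity": lambda x: x,
    "minmax": lambda x: (x - x.min()) / (x.max() - x.min()) if x.max() > x.min()
    else np.zeros_like(x),
}


def _squashed_alphabetical(profile: PssmProfile, squash: str) -> np.ndarray:
    """Profile squashed to [0,1] and re-ordered to alphabetical columns."""
    try:
        fn = _SQUASHERS[squash]
    except KeyError:
        raise ValueError(f"unknown squash {squash!r}") from None
    order = [PSSM_AA_ORDER.index(aa) for aa in STANDARD_AA]
    return fn(profile.scores)[:, order]


def encode_pssm_aac(profile: PssmProfile, squash: str = "sigmoid") -> FeatureVector:
    """Column-wise mean of the logistic-squashed profile (profile-level AAC)."""
    m = _squashed_alphabetical(profile, squash)
    names = tuple(f"pssm.{aa}" for aa in STANDARD_AA)
    return FeatureVector("PSSM_AAC", names, m.mean(axis=0))


def encode_pssm_com(profile: PssmProfile, squash: str = "sigmoid") -> FeatureVector:
    """Residue-grouped profile composition: 20 x 20 block, flattened row-major.

    Row r is the mean squashed profile row over positions carrying residue r
    (zero if r is absent from the sequence).
    """
    m = _squashed_alphabetical(profile, squash)
    block = np.zeros((20, 20))
    for r, aa in enumerate(STANDARD_AA):
        mask = np.array([ch == aa for ch in profile.residues])
        if mask.any():
            block[r] = m[mask].mean(axis=0)
    names = tuple(f"pssm.{a}.{b}" for a in STANDARD_AA for b in STANDARD_AA)
    return FeatureVector("PSSM_COM", names, block.ravel())


def encode_pssm_dp(profile: PssmProfile, squash: str = "sigmoid") -> FeatureVector:
    """Dipeptide-style products of consecutive squashed profile rows.

    value[(j,k)] = mean over positions i of squash(S[i,j]) * squash(S[i+1,k]).
    """
    m = _squashed_alphabetical(profile, squash)
    if m.shape[0] < 2:
        raise ValueError("PSSM_DP: profile needs at least 2 rows")
    block = m[:-1].T @ m[1:] / (m.shape[0] - 1)
    names = tuple(f"pssm.{a}{b}" for a in STANDARD_AA for b in STANDARD_AA)
    return FeatureVector("PSSM_DP", names, block.ravel())


# --- batch encoding ---------------------------------------------------------

def _encode_one(
    descriptor: str,
    record: ProteinRecord,
    profile: PssmProfile | None,
    paac_lam: int,
    paac_w: float,
    eaac_window: int,
    aai_indices: Mapping[str, Mapping[str, float]] | None,
    squash: str,
) -> FeatureVector:
    if descriptor in PSSM_DESCRIPTORS:
        if profile is None:
            raise ValueError(
                f"descriptor {descriptor} needs a PSSM profile for record {record.id!r}"
            )
        if descriptor == "PSSM_AAC":
            return encode_pssm_aac(profile, squash)
        if descriptor == "PSSM_COM":
            return encode_pssm_com(profile, squash)
        return encode_pssm_dp(profile, squash)
    seq = record.sequence
    if descriptor == "AAC":
        return encode_aac(seq)
    if descriptor == "AAI":
        return encode_aai(seq, aai_indices)
    if descriptor == "APAAC":
        return encode_apaac(seq, paac_lam, paac_w)
    if descriptor == "CTDC":
        return encode_ctdc(seq)
    if descriptor == "CTDT":
        return encode_ctdt(seq)
    if descriptor == "CTDD":
        return encode_ctdd(seq)
    if descriptor == "DDE":
        return encode_dde(seq)
    if descriptor == "DPC":
        return encode_dpc(seq)
    if descriptor == "EAAC":
        return encode_eaac(seq, eaac_window)
    if descriptor == "PAAC":
        return encode_paac(seq, paac_lam, paac_w)
    raise ValueError(f"unknown descriptor {descriptor!r}")


def encode_all(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, PssmProfile] | None = None,
    descriptor_list: Iterable[str] = ALL_DESCRIPTORS,
    *,
    paac_lam: int = 1,
    paac_w: float = 0.05,
    eaac_window: int = 5,
    aai_indices: Mapping[str, Mapping[str, float]] | None = None,
    squash: str = "sigmoid",
) -> dict[str, pd.DataFrame]:
    """Encode records with each requested descriptor.

    Returns one DataFrame per descriptor, indexed by record id in input
    order, with the descriptor name stored in ``DataFrame.attrs``. PSSM
    descriptors require a profile for every record.
    """
    descriptor_list = list(descriptor_list)
    unknown = set(descriptor_list) - set(ALL_DESCRIPTORS)
    if unknown:
        raise ValueError(f"unknown descriptors {sorted(unknown)}")
    out: dict[str, pd.DataFrame] = {}
    for desc in descriptor_list:
        rows, names = [], None
        for rec in records:
            prof = (profiles or {}).get(rec.id)
            fv = _encode_one(
                desc, rec, prof, paac_lam, paac_w, eaac_window, aai_indices, squash
            )
            if names is None:
                names = fv.names
            rows.append(fv.values)
        frame = pd.DataFrame(
            np.asarray(rows), index=[r.id for r in records], columns=list(names or ())
        )
        frame.attrs["descriptor"] = desc
        out[desc] = frame
    return out
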