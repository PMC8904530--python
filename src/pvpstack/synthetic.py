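"""Synthetic labeled protein datasets with controllable class separability.

The generator emulates a balanced virion / non-virion benchmark: negatives
draw residues uniformly; positives add ``delta`` probability mass to each of
a small set of biased residues (renormalized), so compositional descriptors
carry signal by construction. ``delta = 0`` yields two indistinguishable
classes (a null dataset). An optional dipeptide-bias mode plants signal
visible only to order-aware descriptors. Synthetic PSI-BLAST-style profiles
put the largest log-odds score at the true residue, plus integer-rounded
Gaussian noise to mimic the ASCII format's integer scores.

Defaults mirror a balanced benchmark of 250 sequences per class with
lengths 50-500 and bias on {C, H, K}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    STANDARD_AA,
    PssmProfile,
    ProteinRecord,
    write_fasta,
    write_pssm,
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_pos: int = 250
    n_neg: int = 250
    length_range: tuple[int, int] = (50, 500)
    bias_residues: frozenset[str] = frozenset({"C", "H", "K"})
    delta: float = 0.15
    seed: int = 0
    #: if True, positives are biased toward dipeptides (bias residue followed
    #: by bias residue) instead of single-residue composition.
    dipeptide_bias: bool = False

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length_range must satisfy 10 <= min <= max")
        if not 0.0 <= self.delta <= 0.2:
            raise ValueError("delta must lie in [0, 0.2]")
        bad = set(self.bias_residues) - set(STANDARD_AA)
        if bad:
            raise ValueError(f"bias residues not standard: {sorted(bad)}")
        if self.delta > 0 and not self.bias_residues:
            raise ValueError("delta > 0 requires at least one bias residue")


def _positive_probs(cfg: SyntheticConfig) -> np.ndarray:
    p = np.full(20, 1 / 20)
    for aa in cfg.bias_residues:
        p[STANDARD_AA.index(aa)] += cfg.delta
    return p / p.sum()


def _draw_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(STANDARD_AA[i] for i in idx)


def _draw_dipeptide_biased(
    rng: np.random.Generator, length: int, cfg: SyntheticConfig
) -> str:
    """First-order chain: after a bias residue, the next residue is a bias
    residue with extra probability delta*len(bias); marginal composition stays
    near-uniform so only order-aware descriptors see the signal."""
    bias = sorted(cfg.bias_residues)
    uniform = np.full(20, 1 / 20)
    boosted = uniform.copy()
    extra = cfg.delta
    for aa in bias:
        boosted[STANDARD_AA.index(aa)] += extra
    boosted /= boosted.sum()
    out = [STANDARD_AA[rng.choice(20)]]
    for _ in range(length - 1):
        probs = boosted if out[-1] in cfg.bias_residues else uniform
        out.append(STANDARD_AA[rng.choice(20, p=probs)])
    return "".join(out)


def generate_labeled_sequences(cfg: SyntheticConfig) -> list[ProteinRecord]:
    """Draw ``n_pos`` positive and ``n_neg`` negative records, reproducibly."""
    rng = np.random.default_rng(cfg.seed)
    pos_probs = _positive_probs(cfg)
    neg_probs = np.full(20, 1 / 20)
    records: list[ProteinRecord] = []
    lo, hi = cfg.length_range
    for i in range(cfg.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = (
            _draw_dipeptide_biased(rng, length, cfg)
            if cfg.dipeptide_bias
            else _draw_sequence(rng, length, pos_probs)
        )
        records.append(ProteinRecord(id=f"pos_{i + 1:04d}", sequence=seq, label=1))
    for i in range(cfg.n_neg):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            ProteinRecord(
                id=f"neg_{i + 1:04d}",
                sequence=_draw_sequence(rng, length, neg_probs),
                label=0,
            )
        )
    return records


def generate_synthetic_pssm(
    record: ProteinRecord, concentration: float = 7.0, seed: int = 0
) -> PssmProfile:
    """A plausible log-odds profile for a sequence.

    Each row is integer-rounded Gaussian noise (sd 2) with ``concentration``
    added at the true residue's column, so large concentrations make the row
    argmax coincide with the sequence. Columns follow PSI-BLAST order.
    """
    from .seqio import PSSM_AA_ORDER

    rng = np.random.default_rng(seed)
    L = len(record.sequence)
    scores = rng.normal(0.0, 2.0, size=(L, 20))
    for i, ch in enumerate(record.sequence):
        scores[i, PSSM_AA_ORDER.index(ch)] += concentration
    return PssmProfile(
        record_id=record.id,
        scores=np.rint(scores),
        residues=record.sequence,
    )


def generate_profiles(
    records, concentration: float = 7.0, seed: int = 0
) -> dict[str, PssmProfile]:
    """One synthetic profile per record, each with a record-derived substream."""
    rng = np.random.default_rng(seed)
    return {
        rec.id: generate_synthetic_pssm(
            rec, concentration, seed=int(rng.integers(0, 2**31 - 1))
        )
        for rec in records
    }


def write_dataset(
    records,
    out_dir: str | Path,
    profiles: dict[str, PssmProfile] | None = None,
    basename: str = "synthetic",
) -> dict[str, Path]:
    """Write FASTA + label TSV (+ per-record ``<id>.pssm`` files) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{basename}.fasta"
    labels = out_dir / f"{basename}.labels.tsv"
    write_fasta(records, fasta)
    with open(labels, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\n")
    paths = {"fasta": fasta, "labels": labels}
    if profiles is not None:
        pssm_dir = out_dir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        for rid, prof in profiles.items():
            write_pssm(prof, pssm_dir / f"{rid}.pssm")
        paths["pssm_dir"] = pssm_dir
    return paths
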