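"""Reading and writing protein sequences and PSI-BLAST profiles.

Sequences travel as :class:`ProteinRecord` (id, validated sequence, optional
binary label; 1 = phage virion protein). Profiles travel as
:class:`PssmProfile`, an L x 20 log-odds matrix in PSI-BLAST column order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: The 20 standard residues, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: PSI-BLAST profile column order.
PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_AMBIGUOUS_MAP = {"B": "D", "Z": "E", "U": "C"}


class SequenceError(ValueError):
    """Raised for invalid or unparseable sequence data."""


class PssmError(ValueError):
    """Raised for unparseable or inconsistent PSSM files."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional binary class label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set(STANDARD_AA)
        if bad:
            raise SequenceError(
                f"{self.id}: non-standard residues {sorted(bad)}; "
                "run validate_sequence first"
            )
        if self.label is not None and self.label not in (0, 1):
            raise SequenceError(f"{self.id}: label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class PssmProfile:
    """An L x 20 position-specific scoring matrix aligned to a sequence.

    ``scores`` columns follow PSI-BLAST order (``PSSM_AA_ORDER``);
    descriptor code re-orders to alphabetical where needed.
    """

    record_id: str
    scores: np.ndarray = field(repr=False)
    residues: str

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise PssmError(
                f"{self.record_id}: profile must be L x 20, got {scores.shape}"
            )
        if scores.shape[0] != len(self.residues):
            raise PssmError(
                f"{self.record_id}: {scores.shape[0]} score rows for "
                f"{len(self.residues)} residues"
            )
        if scores.shape[0] == 0:
            raise PssmError(f"{self.record_id}: empty profile")


def validate_sequence(raw: str, policy: str = "map-ambiguous") -> str:
    """Normalize a raw amino-acid string to the 20 standard letters.

    ``map-ambiguous`` uppercases, maps B->D, Z->E, U->C and drops every other
    non-standard letter (X, J, O, ``*``, gaps). ``strict`` raises on any
    non-standard letter instead.
    """
    if not raw:
        raise SequenceError("empty sequence")
    if policy not in ("strict", "map-ambiguous"):
        raise ValueError(f"unknown policy {policy!r}")
    up = raw.upper()
    out = []
    for ch in up:
        if ch in STANDARD_AA:
            out.append(ch)
        elif policy == "strict":
            raise SequenceError(f"non-standard residue {ch!r} under strict policy")
        elif ch in _AMBIGUOUS_MAP:
            out.append(_AMBIGUOUS_MAP[ch])
        # other letters (X etc.) dropped under map-ambiguous
    if not out:
        raise SequenceError("sequence empty after removing non-standard residues")
    return "".join(out)


def read_fasta(
    path: str | Path,
    label: int | None = None,
    policy: str = "map-ambiguous",
) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited header token. ``label``,
    if given, is attached to every record.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise SequenceError(
                f"{path}: line {lineno}: expected FASTA header before sequence data"
            )
        break  # first non-blank line is a header; hand off to Bio.SeqIO
    records = []
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = validate_sequence(str(entry.seq), policy=policy)
        records.append(ProteinRecord(id=entry.id, sequence=seq, label=label))
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise SequenceError(f"{path}: duplicate ids {dups}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of (id, label in {0,1})."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SequenceError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        rid, lab = parts[0].strip(), parts[1].strip()
        if lab not in ("0", "1"):
            raise SequenceError(f"{path}: line {lineno}: label must be 0 or 1, got {lab!r}")
        if rid in labels:
            raise SequenceError(f"{path}: line {lineno}: duplicate id {rid!r}")
        labels[rid] = int(lab)
    return labels


def attach_labels(records: Sequence[ProteinRecord], labels: dict[str, int]) -> list[ProteinRecord]:
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise SequenceError(f"no label for ids {missing[:5]}{'...' if len(missing) > 5 else ''}")
    return [replace(r, label=labels[r.id]) for r in records]


def read_pssm(path: str | Path, record_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20 score columns (the log-odds block) are kept; trailing
    weighted-percentage and information-content columns are ignored. Data rows
    look like ``  1 M  -2 -3 ... `` (position, residue, >=20 numbers).
    """
    path = Path(path)
    residues: list[str] = []
    rows: list[list[float]] = []
    expected_pos = 1
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 22:
            continue
        if not parts[0].isdigit():
            continue
        pos, res = int(parts[0]), parts[1]
        if len(res) != 1 or not res.isalpha():
            continue
        try:
            vals = [float(x) for x in parts[2:22]]
        except ValueError as exc:
            raise PssmError(f"{path}: line {lineno}: bad score field ({exc})") from exc
        if pos != expected_pos:
            raise PssmError(
                f"{path}: line {lineno}: position {pos}, expected {expected_pos}"
            )
        expected_pos += 1
        residues.append(res.upper())
        rows.append(vals)
    if not rows:
        raise PssmError(f"{path}: no PSSM data rows found")
    return PssmProfile(
        record_id=record_id or path.stem,
        scores=np.asarray(rows, dtype=float),
        residues="".join(residues),
    )


def write_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect that :func:`read_pssm` reads."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write(" " * 11 + "  ".join(PSSM_AA_ORDER) + "   "
                 + "  ".join(PSSM_AA_ORDER) + "\n")
        for i, (res, row) in enumerate(zip(profile.residues, profile.scores), start=1):
            scores = " ".join(f"{v:4.0f}" if float(v).is_integer() else f"{v:6.2f}" for v in row)
            # pad a dummy weighted-percentage block so the row has >= 22 fields
            pct = " ".join("0" for _ in range(20))
            fh.write(f"{i:5d} {res}  {scores}  {pct}  0.00 0.00\n")


def read_pssm_dir(
    directory: str | Path, records: Sequence[ProteinRecord], suffix: str = ".pssm"
) -> dict[str, PssmProfile]:
    """Load ``<id><suffix>`` profiles for every record; error on any missing file."""
    directory = Path(directory)
    profiles: dict[str, PssmProfile] = {}
    for rec in records:
        f = directory / f"{rec.id}{suffix}"
        if not f.exists():
            raise PssmError(f"missing PSSM file for record {rec.id!r}: {f}")
        prof = read_pssm(f, record_id=rec.id)
        if len(prof.residues) != len(rec.sequence):
            raise PssmError(
                f"{rec.id}: profile length {len(prof.residues)} != sequence "
                f"length {len(rec.sequence)}"
            )
        profiles[rec.id] = prof
    return profiles
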