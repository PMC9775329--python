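"""Alignment reading and per-column amino-acid frequency profiles.

An MSA column is summarized as a 20-vector ``p`` of canonical amino-acid
fractions.  Columns where the 20 canonical residues make up less than a
configurable share of all rows (default 75%) are discarded; surviving
columns are renormalized over the canonical residues only so that
``sum(p) == 1``.  Profiles may be kept in fixed alphabet order (residue
identity matters) or sorted descending (only the variability pattern
matters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, in the fixed order used by every p-vector.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard one-letter codes: counted in the coverage
#: denominator but never part of a profile.
AMBIGUOUS_AA = "BZXUO"
GAP_CHARS = "-."

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#: Column names of the profile TSV, in order.
PROFILE_TABLE_COLUMNS = (
    ["alignment_id", "column_index"]
    + [f"p_{aa}" for aa in CANONICAL_AA]
    + ["sorted"]
)


class AlignmentFormatError(ValueError):
    """Raised for ragged, empty, or otherwise malformed alignments."""


class ProfileTableError(ValueError):
    """Raised when a profile TSV fails validation."""


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: equal-length residue strings."""

    id: str
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentFormatError(f"alignment {self.id!r} has no sequences")
        length = len(self.sequences[0])
        if length < 1:
            raise AlignmentFormatError(f"alignment {self.id!r} has zero length")
        for k, seq in enumerate(self.sequences):
            if len(seq) != length:
                raise AlignmentFormatError(
                    f"ragged alignment {self.id!r}: sequence {k + 1} has length "
                    f"{len(seq)}, expected {length}"
                )

    @property
    def n_seq(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class ColumnProfile:
    """One MSA column as canonical amino-acid fractions.

    ``p`` sums to 1 over canonical residues.  If ``sorted`` is true the
    entries are in descending order and no longer tied to residue identity;
    otherwise entry ``i`` is the fraction of ``CANONICAL_AA[i]``.
    ``canonical_coverage`` is the share of all rows (gaps and ambiguity
    codes included in the denominator) that are canonical residues.
    """

    alignment_id: str
    column_index: int  # 1-based
    p: np.ndarray
    sorted: bool
    canonical_coverage: float

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (20,):
            raise ValueError(f"profile must be a 20-vector, got shape {p.shape}")
        if (p < 0).any():
            raise ValueError("profile fractions must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile fractions sum to {p.sum()!r}, expected 1")
        if self.sorted and (np.diff(p) > 1e-12).any():
            raise ValueError("sorted profile must be non-increasing")
        if self.column_index < 1:
            raise ValueError("column_index is 1-based and must be >= 1")


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    Sequences are upper-cased; ``.`` (common in Stockholm) is mapped to the
    gap character ``-``.  Ragged or empty files raise
    :class:`AlignmentFormatError`.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    names: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), format):
        names.append(record.id)
        seqs.append(str(record.seq).upper().replace(".", "-"))
    if not seqs:
        raise AlignmentFormatError(f"{path}: no sequences found ({format})")
    length = len(seqs[0])
    for name, seq in zip(names, seqs):
        if len(seq) != length:
            raise AlignmentFormatError(
                f"{path}: ragged alignment, record {name!r} has length "
                f"{len(seq)}, expected {length}"
            )
    return Alignment(id=path.stem, sequences=tuple(seqs))


def column_counts(aln: Alignment, col: int) -> dict[str, int]:
    """Raw residue counts of 1-based column ``col``.

    Returns counts for each canonical amino acid present, plus ``"gap"``
    and ``"other"`` (ambiguity/unknown codes).  Counts sum to ``n_seq``.
    """
    if not 1 <= col <= aln.length:
        raise IndexError(
            f"column {col} out of range for alignment of length {aln.length}"
        )
    counts: dict[str, int] = {}
    gap = other = 0
    for seq in aln.sequences:
        ch = seq[col - 1]
        if ch in _AA_INDEX:
            counts[ch] = counts.get(ch, 0) + 1
        elif ch in GAP_CHARS:
            gap += 1
        else:
            other += 1
    counts["gap"] = gap
    counts["other"] = other
    return counts


def canonical_coverage(counts: dict[str, int]) -> float:
    """Fraction of rows in a column that are canonical amino acids."""
    total = sum(counts.values())
    if total < 1:
        raise ValueError("empty column: no residues counted")
    canonical = sum(n for aa, n in counts.items() if aa in _AA_INDEX)
    return canonical / total


def sort_profile(p: np.ndarray) -> np.ndarray:
    """Descending profile; stable, so ties keep canonical-alphabet order."""
    order = np.argsort(-np.asarray(p, dtype=float), kind="stable")
    return np.asarray(p, dtype=float)[order]


def extract_profiles(
    aln: Alignment,
    min_canonical: float = 0.75,
    sort: bool = True,
) -> list[ColumnProfile]:
    """Per-column profiles of ``aln`` surviving the canonical-coverage filter.

    A column is removed iff its canonical coverage is strictly below
    ``min_canonical``; surviving columns are renormalized over the canonical
    residues.  Returns an empty list (not an error) if nothing survives.
    """
    if not 0.0 <= min_canonical <= 1.0:
        raise ValueError("min_canonical must be in [0, 1]")
    profiles: list[ColumnProfile] = []
    n_removed = 0
    for col in range(1, aln.length + 1):
        counts = column_counts(aln, col)
        coverage = canonical_coverage(counts)
        if coverage < min_canonical:
            n_removed += 1
            continue
        vec = np.zeros(20)
        for aa, n in counts.items():
            if aa in _AA_INDEX:
                vec[_AA_INDEX[aa]] = n
        total = vec.sum()
        if total == 0:  # possible only when min_canonical == 0
            n_removed += 1
            continue
        vec /= total
        if sort:
            vec = sort_profile(vec)
        profiles.append(
            ColumnProfile(
                alignment_id=aln.id,
                column_index=col,
                p=vec,
                sorted=sort,
                canonical_coverage=coverage,
            )
        )
    logger.info(
        "alignment %s: %d columns read, %d removed (coverage < %.3g), %d kept",
        aln.id, aln.length, n_removed, min_canonical, len(profiles),
    )
    if not profiles:
        logger.warning("alignment %s: no columns survived filtering", aln.id)
    return profiles


def profiles_to_matrix(profiles: Sequence[ColumnProfile]) -> np.ndarray:
    """Stack profiles into an (n, 20) float array."""
    return np.stack([pr.p for pr in profiles]) if profiles else np.empty((0, 20))


def write_profile_table(
    profiles: Iterable[ColumnProfile], path: str | Path
) -> None:
    """Write profiles as TSV (documented header, '.' decimal, UTF-8)."""
    rows = []
    for pr in profiles:
        row: dict[str, object] = {
            "alignment_id": pr.alignment_id,
            "column_index": pr.column_index,
            "sorted": int(pr.sorted),
        }
        for aa, frac in zip(CANONICAL_AA, pr.p):
            row[f"p_{aa}"] = repr(float(frac))
        rows.append(row)
    df = pd.DataFrame(rows, columns=PROFILE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_profile_table(path: str | Path) -> list[ColumnProfile]:
    """Read a profile TSV written by :func:`write_profile_table`.

    Rows whose fractions do not sum to 1 within 1e-6 raise
    :class:`ProfileTableError` naming the row.
    """
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = [c for c in PROFILE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileTableError(f"{path}: missing columns {missing}")
    frac_cols = [f"p_{aa}" for aa in CANONICAL_AA]
    profiles: list[ColumnProfile] = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        p = np.array([float(d[c]) for c in frac_cols])
        if abs(p.sum() - 1.0) > 1e-6:
            raise ProfileTableError(
                f"{path}: row {row_num} fractions sum to {p.sum():.8g}, expected 1"
            )
        p = p / p.sum()  # remove residual round-off so invariants hold exactly
        profiles.append(
            ColumnProfile(
                alignment_id=str(d["alignment_id"]),
                column_index=int(d["column_index"]),
                p=p,
                sorted=bool(int(d["sorted"])),
                canonical_coverage=1.0,
            )
        )
    return profiles
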