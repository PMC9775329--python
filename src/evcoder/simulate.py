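"""Synthetic column profiles and alignments with controlled EV structure.

Each column is generated in two independent steps: the variability v (the
number of occupied residue types) is drawn from a weight vector over
v = 1..20, then the fractions of the v occupied types are drawn from a
symmetric Dirichlet.  Support size and Dirichlet concentration control
variability and entropy independently, which are exactly the two axes the
bottleneck features are expected to recover.  Alignments are emitted by
multinomial sampling from each profile, optionally corrupted with gaps and
non-canonical codes to exercise the coverage filter.  No phylogeny or
substitution model is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .msa import AMBIGUOUS_AA, CANONICAL_AA, Alignment, ColumnProfile, sort_profile


def _default_weights() -> tuple[float, ...]:
    # Uniform over v = 1..14, the variability range of a typical deep MSA
    # corpus; v = 15..20 are essentially unobserved in real alignments.
    return tuple([1.0] * 14 + [0.0] * 6)


@dataclass(frozen=True)
class GeneratorSpec:
    """Settings for synthetic profile / alignment generation."""

    n_columns: int = 50_000
    variability_weights: tuple[float, ...] = field(default_factory=_default_weights)
    concentration: float = 1.0
    n_sequences: int = 100
    gap_rate: float = 0.0
    noncanonical_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        w = np.asarray(self.variability_weights, dtype=float)
        object.__setattr__(self, "variability_weights", tuple(float(x) for x in w))
        if w.shape != (20,):
            raise ValueError("variability_weights must have 20 entries (v = 1..20)")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("variability_weights must be nonnegative, not all zero")
        if self.n_columns < 1 or self.n_sequences < 1:
            raise ValueError("n_columns and n_sequences must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not (0 <= self.gap_rate < 1 and 0 <= self.noncanonical_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.gap_rate + self.noncanonical_rate >= 1:
            raise ValueError("gap_rate + noncanonical_rate must be < 1")


def gen_profiles(spec: GeneratorSpec, sort: bool = False,
                 alignment_id: str = "synthetic") -> list[ColumnProfile]:
    """Generate ``spec.n_columns`` Dirichlet-over-support column profiles.

    Profiles are in fixed alphabet order unless ``sort`` is true.
    Deterministic for a fixed spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    weights = np.asarray(spec.variability_weights) / sum(spec.variability_weights)
    vs = rng.choice(np.arange(1, 21), size=spec.n_columns, p=weights)
    profiles: list[ColumnProfile] = []
    for col, v in enumerate(vs, start=1):
        support = rng.choice(20, size=v, replace=False)
        fractions = rng.dirichlet(np.full(v, spec.concentration))
        p = np.zeros(20)
        p[support] = fractions
        p /= p.sum()
        if sort:
            p = sort_profile(p)
        profiles.append(
            ColumnProfile(
                alignment_id=alignment_id,
                column_index=col,
                p=p,
                sorted=sort,
                canonical_coverage=1.0,
            )
        )
    return profiles


def profiles_matrix(spec: GeneratorSpec, sort: bool = False) -> np.ndarray:
    """Convenience: generated profiles stacked into an (n, 20) array."""
    return np.stack([pr.p for pr in gen_profiles(spec, sort=sort)])


def gen_alignment(
    spec: GeneratorSpec, alignment_id: str = "synthetic"
) -> tuple[Alignment, list[ColumnProfile]]:
    """Emit an alignment by multinomial sampling from generated profiles.

    Each position is then independently overwritten with a gap or a
    non-canonical code at the configured rates.  Returns the alignment and
    the true generating profiles (fixed order, uncorrupted).
    """
    profiles = gen_profiles(spec, sort=False, alignment_id=alignment_id)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    letters = np.array(list(CANONICAL_AA))
    noncanonical = np.array(list(AMBIGUOUS_AA))
    columns = []
    for pr in profiles:
        col = rng.choice(letters, size=spec.n_sequences, p=pr.p)
        u = rng.random(spec.n_sequences)
        col[u < spec.gap_rate] = "-"
        mask = (u >= spec.gap_rate) & (u < spec.gap_rate + spec.noncanonical_rate)
        if mask.any():
            col[mask] = rng.choice(noncanonical, size=int(mask.sum()))
        columns.append(col)
    grid = np.stack(columns, axis=1)  # (n_sequences, n_columns)
    sequences = tuple("".join(row) for row in grid)
    return Alignment(id=alignment_id, sequences=sequences), profiles


def write_alignment_fasta(aln: Alignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, seq in enumerate(aln.sequences, start=1):
            fh.write(f">{aln.id}_{k}\n{seq}\n")
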