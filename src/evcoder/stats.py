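"""Classical entropy-variability statistics for MSA column profiles.

For a column with amino-acid fractions ``p`` the Shannon entropy is
``H = -sum(p_i * ln p_i)`` (nats) and the variability ``v`` is the number
of residue types observed.  Entropy is bounded by ``ln v``, so the
normalized entropy ``H / ln v`` lies in [0, 1] and measures how evenly the
observed types are used, independent of how many there are.  The five-box
EV classification (11, 12, 22, 23, 33, from conserved/core-function to
unconstrained positions) bins columns along the diagonal of a
variability-band x entropy-band grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .msa import ColumnProfile

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class EVPoint:
    """Entropy (nats), variability (1-20) and normalized entropy of a column."""

    entropy: float
    variability: int
    normalized_entropy: float

    def __post_init__(self) -> None:
        if not 1 <= self.variability <= 20:
            raise ValueError("variability must be in [1, 20]")
        if self.entropy < -1e-12:
            raise ValueError("entropy must be nonnegative")
        if self.entropy > math.log(self.variability) + 1e-9:
            raise ValueError("entropy exceeds ln(variability)")


@dataclass(frozen=True)
class BoxBoundaries:
    """Band cuts for the five-box EV classification.

    ``variability_cuts`` are two increasing integers splitting v into three
    bands; ``entropy_cuts`` are two increasing thresholds on normalized
    entropy.  The defaults are guideline values only: the original box
    boundaries were family-dependent and deliberately loose, so they are
    fully configurable.
    """

    variability_cuts: tuple[int, int] = (2, 9)
    entropy_cuts: tuple[float, float] = (0.33, 0.67)

    def __post_init__(self) -> None:
        v1, v2 = self.variability_cuts
        e1, e2 = self.entropy_cuts
        if not (1 <= v1 < v2 <= 20):
            raise ValueError("variability cuts must be strictly increasing in [1, 20]")
        if not e1 < e2:
            raise ValueError("entropy cuts must be strictly increasing")


def _validate(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (20,):
        raise ValueError(f"expected a 20-vector, got shape {p.shape}")
    if (p < 0).any():
        raise ValueError("fractions must be nonnegative")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"fractions sum to {p.sum():.8g}, expected 1")
    return p


def entropy(p: np.ndarray | Sequence[float], base: float | None = None) -> float:
    """Shannon entropy -sum(p ln p) of a fraction vector, with 0 ln 0 := 0.

    Natural log by default; pass ``base`` (e.g. 2) for other units.
    """
    p = _validate(p)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    h = max(h, 0.0)  # clip -0.0 / round-off on one-hot inputs
    if base is not None:
        h /= math.log(base)
    return h


def variability(p: np.ndarray | Sequence[float], min_fraction: float = 0.0) -> int:
    """Number of residue types with fraction strictly above ``min_fraction``."""
    p = _validate(p)
    v = int((p > min_fraction).sum())
    if v == 0:
        raise ValueError("no residue type exceeds min_fraction; variability undefined")
    return v


def normalized_entropy(
    p: np.ndarray | Sequence[float], min_fraction: float = 0.0
) -> float:
    """Entropy divided by its maximum ln(v) at the column's variability.

    Defined as 0 for fully conserved columns (v = 1).  Base-invariant.
    """
    v = variability(p, min_fraction)
    if v == 1:
        return 0.0
    return min(entropy(p) / math.log(v), 1.0)


def ev_point(p: np.ndarray | Sequence[float], min_fraction: float = 0.0) -> EVPoint:
    """Bundle entropy, variability and normalized entropy for one profile."""
    return EVPoint(
        entropy=entropy(p),
        variability=variability(p, min_fraction),
        normalized_entropy=normalized_entropy(p, min_fraction),
    )


_DIAGONAL = {(1, 1): "11", (1, 2): "12", (2, 2): "22", (2, 3): "23", (3, 3): "33"}


def _band(value: float, cuts: tuple[float, float]) -> int:
    # Lower-edge inclusive: a value exactly on a cut joins the higher band.
    if value < cuts[0]:
        return 1
    if value < cuts[1]:
        return 2
    return 3


def classify_box(ev: EVPoint, boundaries: BoxBoundaries | None = None) -> str:
    """Five-box EV label of a column: 11, 12, 22, 23, 33, or "other".

    Bands run bottom-left (conserved, box 11) to top-right (variable and
    even, box 33); cells off the diagonal path map to "other" rather than
    being forced into a nearest box.
    """
    b = boundaries or BoxBoundaries()
    e_band = _band(ev.normalized_entropy, b.entropy_cuts)
    v_band = _band(float(ev.variability), (float(b.variability_cuts[0]),
                                           float(b.variability_cuts[1])))
    return _DIAGONAL.get((e_band, v_band), "other")


def ev_table(
    profiles: Iterable[ColumnProfile],
    boundaries: BoxBoundaries | None = None,
    base: float | None = None,
    min_fraction: float = 0.0,
) -> pd.DataFrame:
    """EV statistics for a list of profiles, one row per column, order kept.

    Columns: alignment_id, column_index, entropy, variability,
    normalized_entropy, box.
    """
    rows = []
    for pr in profiles:
        ev = ev_point(pr.p, min_fraction)
        h = ev.entropy if base is None else ev.entropy / math.log(base)
        rows.append(
            {
                "alignment_id": pr.alignment_id,
                "column_index": pr.column_index,
                "entropy": h,
                "variability": ev.variability,
                "normalized_entropy": ev.normalized_entropy,
                "box": classify_box(ev, boundaries),
            }
        )
    if not rows:
        raise ValueError("ev_table requires at least one profile")
    return pd.DataFrame(rows)


def write_ev_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_ev_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8", dtype={"box": str})
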