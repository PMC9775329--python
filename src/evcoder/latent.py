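"""Relating bottleneck neurons to entropy and variability.

After training, each MSA column has a latent coordinate (neuron1, neuron2,
and optionally neuron3).  This module quantifies how closely those learned
axes track the classical statistics: Spearman rank correlation of each
neuron against normalized entropy and against variability, an optimal
injective neuron-to-statistic assignment, a silhouette score for the
separation of low-variability columns, and plot-ready tables for EV and
neural scatter plots.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

from .autoencoder import TrainedAutoencoder
from .msa import CANONICAL_AA, ColumnProfile

_STATS = ("normalized_entropy", "variability")


@dataclass(frozen=True)
class AxisMatch:
    """Neuron-to-statistic correspondence.

    ``correlations[i, j]`` is the Spearman correlation of neuron i with
    statistic j (0 = normalized entropy, 1 = variability).  ``assignment``
    maps each statistic name to the neuron index it is matched with; the
    injective assignment maximizes the total absolute correlation.
    ``signs`` give the orientation of each matched axis.
    """

    correlations: np.ndarray
    assignment: dict[str, int]
    signs: dict[str, int]

    @property
    def matched_abs_rho(self) -> dict[str, float]:
        return {
            stat: abs(float(self.correlations[idx, j]))
            for j, stat in enumerate(_STATS)
            for idx in [self.assignment[stat]]
        }


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant column: Spearman correlation undefined, using 0")
        return 0.0
    rho = spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def match_axes(latents: np.ndarray, ev: pd.DataFrame) -> AxisMatch:
    """Match bottleneck neurons to normalized entropy and variability.

    ``latents`` is (n, d) with d in {2, 3}; ``ev`` must carry
    ``normalized_entropy`` and ``variability`` columns of the same length.
    All injective assignments of the two statistics to neurons are scored
    exhaustively and the one maximizing the summed |Spearman rho| wins.
    """
    L = np.atleast_2d(np.asarray(latents, dtype=float))
    n, d = L.shape
    if d not in (2, 3):
        raise ValueError(f"latents must have 2 or 3 neurons, got {d}")
    if len(ev) != n:
        raise ValueError(f"length mismatch: {n} latents vs {len(ev)} EV rows")
    if n < 10:
        raise ValueError("need at least 10 points for a meaningful correlation")
    targets = np.column_stack([ev["normalized_entropy"], ev["variability"]])
    corr = np.array(
        [[_rank_corr(L[:, i], targets[:, j]) for j in range(2)] for i in range(d)]
    )
    best_score, best = -np.inf, None
    for neurons in itertools.permutations(range(d), 2):
        score = sum(abs(corr[neuron, j]) for j, neuron in enumerate(neurons))
        if score > best_score:
            best_score, best = score, neurons
    assignment = {stat: best[j] for j, stat in enumerate(_STATS)}
    signs = {
        stat: int(np.sign(corr[assignment[stat], j]) or 1)
        for j, stat in enumerate(_STATS)
    }
    return AxisMatch(correlations=corr, assignment=assignment, signs=signs)


def neural_plot_table(
    latents: np.ndarray,
    ev: pd.DataFrame,
    boxes: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Join latent coordinates with EV statistics; one row per column.

    A pure join: values pass through unmodified.  The ``box`` column is
    present only when ``boxes`` is supplied (or already part of ``ev``).
    """
    L = np.atleast_2d(np.asarray(latents, dtype=float))
    if len(ev) != L.shape[0]:
        raise ValueError(f"length mismatch: {L.shape[0]} latents vs {len(ev)} EV rows")
    out = pd.DataFrame(
        {f"neuron{i + 1}": L[:, i] for i in range(L.shape[1])}
    )
    for col in ("alignment_id", "column_index", "entropy", "variability",
                "normalized_entropy"):
        if col in ev.columns:
            out[col] = np.asarray(ev[col])
    if boxes is not None:
        out["box"] = np.asarray(boxes)
    elif "box" in ev.columns:
        out["box"] = np.asarray(ev["box"])
    return out


def low_variability_separation(latents: np.ndarray, ev: pd.DataFrame,
                               v_split: int = 2) -> float:
    """Silhouette score of {v <= v_split} vs {v > v_split} in latent space.

    In trained models the conserved and nearly-conserved columns
    (variability 1-2) sit apart from the continuum, at the corner of the
    neural plot; a positive score reflects that separation.  Requires at
    least 5 points on each side.
    """
    L = np.atleast_2d(np.asarray(latents, dtype=float))
    v = np.asarray(ev["variability"])
    labels = (v <= v_split).astype(int)
    if (labels == 1).sum() < 5 or (labels == 0).sum() < 5:
        raise ValueError(
            f"need at least 5 columns on each side of variability {v_split}"
        )
    return float(silhouette_score(L, labels))


def fixed_order_summary(model: TrainedAutoencoder) -> pd.DataFrame:
    """Embed the 20 pure (fully conserved) columns of a fixed-order model.

    Each canonical amino acid is encoded as a one-hot profile; the result
    maps residue identity into the latent plane.  Only meaningful — and only
    allowed — for models trained with sorting disabled, since every one-hot
    column has the same sorted representation.
    """
    if model.config.mode != "fixed":
        raise ValueError(
            "fixed_order_summary requires a model trained in fixed-order mode "
            f"(this model was trained in {model.config.mode!r} mode)"
        )
    onehots = np.eye(20)
    codes = model.encode(onehots)
    out = pd.DataFrame({"amino_acid": list(CANONICAL_AA)})
    for i in range(codes.shape[1]):
        out[f"neuron{i + 1}"] = codes[:, i]
    return out
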