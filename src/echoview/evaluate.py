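"""Agreement evaluation of the view classifier.

The classifier's output is judged against the true views via a 5x5
contingency (confusion) table: rows are true views, columns predicted
views, both in the canonical order PLAX, PSAX, AP3, AP4, AP2.  From it we
report overall accuracy (trace over total) and Cohen's weighted kappa —
a chance-corrected agreement statistic

    kappa = 1 - sum(w_ij o_ij) / sum(w_ij e_ij)

with observed proportions ``o``, marginal-product expected proportions
``e`` and a disagreement weight matrix ``w`` (linear weights over the
canonical ordering by default; unweighted and quadratic selectable).  The
large-sample standard error follows the classical delta-method formula
for weighted kappa, giving a ``kappa +/- 1.96 SE`` 95% confidence
interval.

Note: views are nominal, so the choice of weighting (and the class
ordering it acts on) is a reporting convention; it is therefore recorded
in every result rather than silently assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import VIEW_ORDER, ViewLabel

__all__ = [
    "ConfusionTable", "KappaResult",
    "confusion", "accuracy", "weighted_kappa",
    "misclassification_report",
]

log = logging.getLogger(__name__)

VIEW_NAMES = [v.value for v in VIEW_ORDER]


@dataclass
class ConfusionTable:
    """5x5 count matrix of true (rows) vs predicted (cols) views."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5):
            raise ValueError("confusion table must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=VIEW_NAMES, columns=VIEW_NAMES)


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    weighting: str

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.kappa <= hi):
            raise ValueError("kappa must lie inside its confidence interval")


def confusion(predictions: pd.DataFrame | list) -> ConfusionTable:
    """Tabulate (true view, argmax view) counts.

    ``predictions`` is either a DataFrame with ``true_view`` and either
    ``predicted_view`` or probability columns ``p_<VIEW>``, or a list of
    ``(true: ViewLabel, prob: length-5 array)`` pairs.
    """
    counts = np.zeros((5, 5), dtype=np.int64)
    if isinstance(predictions, pd.DataFrame):
        if "true_view" not in predictions.columns:
            raise ValueError("predictions need a true_view column")
        if predictions["true_view"].isna().any():
            raise ValueError("missing true label in predictions")
        for _, row in predictions.iterrows():
            i = ViewLabel(row["true_view"]).index
            if "predicted_view" in predictions.columns:
                j = ViewLabel(row["predicted_view"]).index
            else:
                p = np.array([row[f"p_{v}"] for v in VIEW_NAMES], dtype=float)
                j = int(np.argmax(p))
            counts[i, j] += 1
    else:
        for true, prob in predictions:
            if true is None:
                raise ValueError("missing true label in predictions")
            counts[ViewLabel(true).index, int(np.argmax(prob))] += 1
    return ConfusionTable(counts)


def accuracy(table: ConfusionTable) -> float:
    """Overall accuracy: trace / total."""
    if table.total == 0:
        raise ValueError("empty confusion table")
    return float(np.trace(table.counts) / table.total)


def _disagreement_weights(k: int, weighting: str) -> np.ndarray:
    i, j = np.mgrid[0:k, 0:k]
    if weighting == "unweighted":
        return (i != j).astype(float)
    if weighting == "linear":
        return np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        return ((i - j) / (k - 1)) ** 2
    raise ValueError(f"unknown weighting {weighting!r}")


def weighted_kappa(table: ConfusionTable, weighting: str = "linear") -> KappaResult:
    """Weighted Cohen's kappa with large-sample SE and 95% CI.

    Classes whose row *and* column are both empty are dropped (logged);
    a fully empty table is an error.
    """
    counts = table.counts.astype(float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion table")
    keep = ~((counts.sum(axis=0) == 0) & (counts.sum(axis=1) == 0))
    if not keep.all():
        dropped = [VIEW_NAMES[i] for i in np.flatnonzero(~keep)]
        log.info("weighted_kappa: dropping empty classes %s", dropped)
        counts = counts[np.ix_(keep, keep)]
    k = counts.shape[0]
    p = counts / n
    row, col = p.sum(axis=1), p.sum(axis=0)
    w = _disagreement_weights(k, weighting)
    v = 1.0 - w  # agreement weights
    e = np.outer(row, col)
    de, do = float((w * e).sum()), float((w * p).sum())
    if de == 0:  # degenerate single-class table: perfect trivially
        kappa = 1.0
        se = 0.0
    else:
        kappa = 1.0 - do / de
        po, pe = float((v * p).sum()), float((v * e).sum())
        vbar_i = v @ col          # E_j[v_ij] over predicted marginal
        vbar_j = row @ v          # E_i[v_ij] over true marginal
        term = v * (1 - pe) - (vbar_i[:, None] + vbar_j[None, :]) * (1 - po)
        var = ((p * term ** 2).sum() - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
        se = float(np.sqrt(max(var, 0.0)))
    lo = max(min(kappa - 1.96 * se, kappa), -1.0)
    hi = min(max(kappa + 1.96 * se, kappa), 1.0)
    return KappaResult(kappa=float(kappa), se=se, ci95=(lo, hi), weighting=weighting)


#: Adjacent-apical confusions flagged first in the report: a small change
#: of probe angle turns AP3 into AP2 or AP4, the clinically expected
#: failure mode.
_ADJACENT_APICAL = {
    (ViewLabel.AP3, ViewLabel.AP2), (ViewLabel.AP2, ViewLabel.AP3),
    (ViewLabel.AP3, ViewLabel.AP4), (ViewLabel.AP4, ViewLabel.AP3),
}


def misclassification_report(predictions: pd.DataFrame,
                             framesets: dict[str, "object"] | None = None,
                             out_dir: str | Path | None = None) -> pd.DataFrame:
    """Every misclassified clip, adjacent-apical confusions first.

    Returns a DataFrame (clip_id, true/predicted views, ensemble
    probabilities); with ``out_dir`` also writes it as CSV and saves the
    averaged-frame image of each misclassified clip for manual review.
    """
    bad = predictions[predictions["true_view"] != predictions["predicted_view"]].copy()
    if len(bad):
        bad["adjacent_apical"] = [
            (ViewLabel(t), ViewLabel(q)) in _ADJACENT_APICAL
            for t, q in zip(bad["true_view"], bad["predicted_view"])
        ]
        bad = bad.sort_values(["adjacent_apical", "clip_id"],
                              ascending=[False, True]).reset_index(drop=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bad.to_csv(out_dir / "misclassified.csv", index=False)
        if framesets is not None and len(bad):
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            for _, row in bad.iterrows():
                fs = framesets.get(row["clip_id"])
                if fs is None:
                    continue
                fig, ax = plt.subplots(figsize=(3, 3))
                ax.imshow(fs.averaged, cmap="gray", vmin=0, vmax=255)
                ax.set_title(f"{row['clip_id']}: {row['true_view']} -> "
                             f"{row['predicted_view']}", fontsize=8)
                ax.axis("off")
                fig.savefig(out_dir / f"{row['clip_id']}.png", dpi=80,
                            bbox_inches="tight")
                plt.close(fig)
    return bad
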