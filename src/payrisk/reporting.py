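"""Calibration diagnostics and distribution summaries.

Predictive ratios (mean predicted over mean actual payment within deciles
of predicted payment) should sit near 1.0 for a well-calibrated model;
quintile shift tables show how two models redistribute patients across the
predicted-payment spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "predictive_ratios", "quintile_shift", "QuintileShiftTable",
    "payment_distribution_summary",
]


def _bin_assign(pred: np.ndarray, bins: int) -> np.ndarray:
    """Near-equal rank bins (sizes differ by at most one); ties broken by
    stable input order."""
    order = np.argsort(pred, kind="stable")
    assign = np.empty(len(pred), dtype=np.int64)
    for b, chunk in enumerate(np.array_split(order, bins)):
        assign[chunk] = b
    return assign


def predictive_ratios(pred, actual, bins: int = 10) -> pd.DataFrame:
    """Per-decile calibration table: mean predicted, mean actual, ratio.

    Bin 1 holds the lowest predicted payments. The per-bin ratios satisfy
    the exact identity: weighting each bin's ratio by its actual total
    recovers overall mean(pred)/mean(actual).
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual lengths differ")
    if len(pred) < bins:
        raise ValueError(f"need at least {bins} observations")
    assign = _bin_assign(pred, bins)
    rows = []
    for b in range(bins):
        m = assign == b
        mp, ma = float(pred[m].mean()), float(actual[m].mean())
        rows.append({
            "decile": b + 1, "n": int(m.sum()),
            "mean_predicted": mp, "mean_actual": ma, "ratio": mp / ma,
        })
    return pd.DataFrame(rows).set_index("decile")


@dataclass
class QuintileShiftTable:
    """Admission counts cross-classified by predicted-payment quintile
    under two models."""

    counts: pd.DataFrame  # rows = model A quintile, cols = model B quintile
    pct_reclassified: float

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def quintile_shift(pred_a, pred_b, bins: int = 5) -> QuintileShiftTable:
    """Cross-tabulate quintile membership of two prediction vectors."""
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    if pred_a.shape != pred_b.shape:
        raise ValueError("prediction vectors differ in length")
    if len(pred_a) < bins:
        raise ValueError(f"need at least {bins} observations")
    qa = _bin_assign(pred_a, bins) + 1
    qb = _bin_assign(pred_b, bins) + 1
    tab = pd.crosstab(pd.Series(qa, name="model_a"),
                      pd.Series(qb, name="model_b"))
    tab = tab.reindex(index=range(1, bins + 1),
                      columns=range(1, bins + 1)).fillna(0).astype(int)
    total = tab.to_numpy().sum()
    off = total - np.trace(tab.to_numpy())
    return QuintileShiftTable(counts=tab,
                              pct_reclassified=100.0 * off / total)


def payment_distribution_summary(pred) -> dict[str, float]:
    """Median and range of a predicted-payment vector."""
    pred = np.asarray(pred, dtype=float)
    if pred.size == 0:
        raise ValueError("empty input")
    return {
        "median": float(np.median(pred)),
        "min": float(np.min(pred)),
        "max": float(np.max(pred)),
    }
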