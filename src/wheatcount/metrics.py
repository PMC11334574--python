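"""Counting metrics (MAE, RMSE, R^2), stratified reports and table arithmetic.

    MAE  = (1/N) sum_i |Chat_i - C_i|
    RMSE = sqrt((1/N) sum_i (Chat_i - C_i)^2)
    R^2  = 1 - sum_i (Chat_i - C_i)^2 / sum_i (Cbar - C_i)^2

R^2 follows the definition literally and may be negative for a model worse
than predicting the mean; it requires non-constant true counts.  Reports can
be stratified at a count threshold (default 40) to separate sparse from
dense scenes.  Display rounding is 2 decimals for metrics and averages and
1 decimal for percentages; raw values are kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricsReport",
    "mae",
    "rmse",
    "r_squared",
    "compute_report",
    "stratified_report",
    "mean_count_from_totals",
    "relative_change_pct",
]


def _validate(preds, trues) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(preds, dtype=np.float64)
    t = np.asarray(trues, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"predictions and truths must be equal-length vectors, "
                         f"got {p.shape} and {t.shape}")
    if p.size == 0:
        raise ValueError("empty evaluation set")
    return p, t


def mae(preds, trues) -> float:
    p, t = _validate(preds, trues)
    return float(np.mean(np.abs(p - t)))


def rmse(preds, trues) -> float:
    p, t = _validate(preds, trues)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def r_squared(preds, trues) -> float:
    p, t = _validate(preds, trues)
    ss_tot = float(np.sum((t.mean() - t) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined for constant true counts")
    return 1.0 - float(np.sum((p - t) ** 2)) / ss_tot


@dataclass
class StratumMetrics:
    n: int
    mae: float
    rmse: float
    r2: float | None  # None when the stratum's truths are constant


@dataclass
class MetricsReport:
    """Metrics for one evaluation run, optionally stratified by density."""

    n: int
    mae: float
    rmse: float
    r2: float | None
    strata: dict[str, StratumMetrics] = field(default_factory=dict)

    def to_frame(self):
        """One row per scope (overall + strata), suitable for CSV export."""
        import pandas as pd
        rows = [{"scope": "overall", "n": self.n, "mae": round(self.mae, 2),
                 "rmse": round(self.rmse, 2),
                 "r2": None if self.r2 is None else round(self.r2, 2)}]
        for name, s in self.strata.items():
            rows.append({"scope": name, "n": s.n, "mae": round(s.mae, 2),
                         "rmse": round(s.rmse, 2),
                         "r2": None if s.r2 is None else round(s.r2, 2)})
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [f"N = {self.n}",
                 f"MAE  = {self.mae:.2f}",
                 f"RMSE = {self.rmse:.2f}"]
        if self.r2 is not None:
            lines.append(f"R^2  = {self.r2:.2f}")
        for name, s in self.strata.items():
            lines.append(f"[{name}] n={s.n}  MAE={s.mae:.2f}  RMSE={s.rmse:.2f}")
        return "\n".join(lines)


def _stratum(p: np.ndarray, t: np.ndarray) -> StratumMetrics:
    ss_tot = float(np.sum((t.mean() - t) ** 2))
    return StratumMetrics(
        n=int(t.size), mae=mae(p, t), rmse=rmse(p, t),
        r2=None if ss_tot == 0.0 else r_squared(p, t))


def compute_report(preds, trues) -> MetricsReport:
    p, t = _validate(preds, trues)
    s = _stratum(p, t)
    return MetricsReport(n=s.n, mae=s.mae, rmse=s.rmse, r2=s.r2)


def stratified_report(preds, trues, threshold: float = 40.0) -> MetricsReport:
    """Report on the full set plus the sparse (<= threshold) and dense
    (> threshold) strata; an empty stratum is simply omitted."""
    p, t = _validate(preds, trues)
    report = compute_report(p, t)
    low, high = t <= threshold, t > threshold
    if low.any():
        report.strata[f"counts<={threshold:g}"] = _stratum(p[low], t[low])
    if high.any():
        report.strata[f"counts>{threshold:g}"] = _stratum(p[high], t[high])
    return report


def mean_count_from_totals(total: int, n_images: int) -> float:
    """Average objects per image from table totals, rounded to 2 decimals."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    return round(total / n_images, 2)


def relative_change_pct(reference: float, value: float) -> float:
    """Percent reduction of `value` relative to `reference`, 1 decimal."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return round(100.0 * (reference - value) / reference, 1)
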