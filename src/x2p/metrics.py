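"""Landmark localization metrics: PCL@tau, MPE, AUC of the PCL curve.

An evaluation pair matches a prediction with its ground-truth landmark by
slot index.  Predictions filtered out by the validity rule still count as
misses at every threshold; they are excluded from MPE (the exclusion count
is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvalPair", "pcl", "mpe", "auc_pcl", "per_level_report", "summarize"]


@dataclass
class EvalPair:
    """One matched (prediction, ground truth) landmark, 2D px or 3D mm."""

    pred: np.ndarray
    gt: np.ndarray
    level: str = ""
    valid: bool = True

    def __post_init__(self):
        self.pred = np.asarray(self.pred, dtype=np.float64)
        self.gt = np.asarray(self.gt, dtype=np.float64)

    @property
    def error(self) -> float:
        return float(np.linalg.norm(self.pred - self.gt))


def _check_nonempty(pairs):
    if len(pairs) == 0:
        raise ValueError("empty evaluation: no landmark pairs")


def pcl(pairs, tau: float) -> float:
    """Fraction of landmarks with error strictly below tau (misses count in Nt)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    _check_nonempty(pairs)
    hits = sum(1 for p in pairs if p.valid and p.error < tau)
    return hits / len(pairs)


def mpe(pairs) -> float:
    """Mean Euclidean error over valid pairs (invalid ones are excluded)."""
    _check_nonempty(pairs)
    errors = [p.error for p in pairs if p.valid]
    if not errors:
        raise ValueError("empty evaluation: no valid predictions to average")
    return float(np.mean(errors))


def n_excluded(pairs) -> int:
    return sum(1 for p in pairs if not p.valid)


def auc_pcl(
    pairs, lower: float = 10.0, upper: float = 50.0, step: float = 1.0, normalize: bool = True
) -> float:
    """Trapezoidal integral of tau -> PCL@tau over [lower, upper].

    Normalized by (upper - lower) by default so the value lies in [0, 1].
    """
    if not lower < upper:
        raise ValueError("lower must be < upper")
    if step <= 0:
        raise ValueError("step must be positive")
    taus = np.arange(lower, upper + step / 2, step)
    if taus[-1] < upper:
        taus = np.append(taus, upper)
    values = [pcl(pairs, float(t)) for t in taus]
    area = float(np.trapezoid(values, taus))
    return area / (upper - lower) if normalize else area


def per_level_report(pairs, tau: float = 10.0) -> pd.DataFrame:
    """PCL@tau and MPE grouped by vertebral level label."""
    _check_nonempty(pairs)
    rows = []
    levels = sorted({p.level for p in pairs})
    for level in levels:
        group = [p for p in pairs if p.level == level]
        has_valid = any(p.valid for p in group)
        rows.append(
            {
                "level": level,
                "n": len(group),
                f"pcl@{tau:g}": pcl(group, tau),
                "mpe": mpe(group) if has_valid else np.nan,
                "n_excluded": n_excluded(group),
            }
        )
    return pd.DataFrame(rows)


def summarize(pairs, taus=(10.0, 20.0), auc_range=(10.0, 50.0)) -> dict:
    """Headline metric dict: PCL at each tau, MPE, AUC, exclusion count."""
    out = {f"pcl@{t:g}": pcl(pairs, t) for t in taus}
    excluded = n_excluded(pairs)
    out["mpe"] = mpe(pairs) if excluded < len(pairs) else float("nan")
    out["auc"] = auc_pcl(pairs, *auc_range)
    out["n"] = len(pairs)
    out["n_excluded"] = excluded
    return out
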