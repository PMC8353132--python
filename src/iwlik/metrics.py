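"""Monte-Carlo evaluation criteria and summary tables.

All moments use population (1/N) denominators, so the exact decomposition
``rmse**2 == bias**2 + rmsd**2`` holds, where ``bias`` is the signed mean
deviation, ``rmse`` the root mean squared error about the truth and
``rmsd`` the root mean squared deviation of the estimates about their own
mean (estimator variability, not error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "abs_bias",
    "rmse",
    "rmsd",
    "correlation_true_est",
    "SimulationSummary",
    "summarize_records",
]


def _clean(estimates) -> np.ndarray:
    v = np.asarray(estimates, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty estimate vector")
    return v


def abs_bias(estimates, theta_true: float) -> float:
    """Absolute value of the mean deviation from the truth,
    ``|mean(theta_hat) - theta|``."""
    return float(abs(_clean(estimates).mean() - theta_true))


def rmse(estimates, theta_true: float) -> float:
    """Root mean squared deviation from the truth (1/N denominator)."""
    v = _clean(estimates)
    return float(np.sqrt(np.mean((v - theta_true) ** 2)))


def rmsd(estimates) -> float:
    """Root mean squared deviation of the estimates about their own mean
    (1/N denominator); invariant under adding a constant."""
    v = _clean(estimates)
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def correlation_true_est(theta_true, theta_hat) -> float:
    """Pearson correlation between true and estimated abilities, pooled
    over whatever (level x replication) pairs are supplied."""
    t = np.asarray(theta_true, dtype=float).ravel()
    e = np.asarray(theta_hat, dtype=float).ravel()
    if t.size != e.size:
        raise ValueError("length mismatch")
    if np.unique(t).size < 2:
        raise ValueError("need at least two distinct truth values")
    if np.std(t) == 0 or np.std(e) == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(t, e)[0, 1])


@dataclass
class SimulationSummary:
    """Per-condition metric tables of a simulation run.

    ``metrics`` has one row per (condition, estimator, parameter, theta1
    level) with columns ``abs_bias``, ``rmse``, ``rmsd`` and ``n_used``;
    ``correlations`` one row per (condition, estimator, parameter) with
    the pooled true-vs-estimated Pearson correlation.
    """

    metrics: pd.DataFrame
    correlations: pd.DataFrame
    exclusions: pd.DataFrame
    records: Optional[pd.DataFrame] = None
    design: Optional[dict] = None

    def table(self, condition: str, param: str = "theta1") -> pd.DataFrame:
        """Wide per-level table for one condition: columns
        ``<EST>_abs_bias`` / ``<EST>_rmsd`` per estimator, one row per
        theta1 level (the attached theta2 level is carried alongside)."""
        sub = self.metrics[
            (self.metrics["condition"] == condition)
            & (self.metrics["param"] == param)
        ]
        wide = sub.pivot_table(
            index="theta1", columns="estimator", values=["abs_bias", "rmsd"]
        )
        wide.columns = [f"{est}_{stat}" for stat, est in wide.columns]
        wide.insert(0, "theta2", sub.groupby("theta1")["theta2"].first())
        return wide.reset_index().sort_values("theta1").reset_index(drop=True)

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        if self.records is not None:
            self.records.to_csv(out / "records.csv", index=False)


def summarize_records(
    records: pd.DataFrame,
    exclusions: Optional[pd.DataFrame] = None,
    design: Optional[dict] = None,
    keep_records: bool = False,
) -> SimulationSummary:
    """Aggregate long-format replication records into metric tables.

    ``records`` needs columns ``condition``, ``estimator``, ``theta1``,
    ``theta2``, ``theta1_hat`` and (longitudinal) ``theta2_hat``.
    Correlations are pooled across all theta levels and replications per
    condition, separately for each ability dimension.
    """
    rows = []
    corr_rows = []
    has_t2 = "theta2_hat" in records.columns and records["theta2_hat"].notna().any()
    params = [("theta1", "theta1_hat")] + ([("theta2", "theta2_hat")] if has_t2 else [])
    for (cond, est), g in records.groupby(["condition", "estimator"], sort=True):
        for param, hat in params:
            for (t1, t2), gg in g.groupby(["theta1", "theta2"], sort=True, dropna=False):
                truth = t1 if param == "theta1" else t2
                v = gg[hat].to_numpy()
                rows.append(
                    {
                        "condition": cond,
                        "estimator": est,
                        "param": param,
                        "theta1": t1,
                        "theta2": t2,
                        "n_used": v.size,
                        "abs_bias": abs_bias(v, truth),
                        "rmse": rmse(v, truth),
                        "rmsd": rmsd(v),
                    }
                )
            truth_all = g[param].to_numpy()
            corr_rows.append(
                {
                    "condition": cond,
                    "estimator": est,
                    "param": param,
                    "correlation": correlation_true_est(
                        truth_all, g[hat].to_numpy()
                    )
                    if np.unique(truth_all).size >= 2
                    else np.nan,
                    "n_pairs": len(g),
                }
            )
    metrics = pd.DataFrame(rows)
    correlations = pd.DataFrame(corr_rows)
    if exclusions is None:
        exclusions = pd.DataFrame(
            columns=["condition", "theta1", "n_total", "n_excluded"]
        )
    return SimulationSummary(
        metrics=metrics,
        correlations=correlations,
        exclusions=exclusions,
        records=records if keep_records else None,
        design=design,
    )
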