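"""Pearson-correlation screening of candidate predictors against volume.

A predictor survives when |r| >= 0.4 and its two-sided t-test p-value
(t = r sqrt((n-2)/(1-r^2)), n-2 df) is below 0.05.  No multiple-testing
correction is applied, matching the original screening protocol; the
report flags that as a limitation.  The study text prints the p-value
comparison in the "greater than" direction, which contradicts the notion
of a significance screen; the significant direction (p < alpha) is the
default here and the direction is configurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson_r_p", "screen_features"]

logger = logging.getLogger(__name__)


def pearson_r_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def screen_features(table: pd.DataFrame, response: str = "M",
                    threshold: float = 0.4, alpha: float = 0.05,
                    p_direction: str = "less") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every predictor column of ``table`` against the response.

    Returns ``(report, reduced)``: a per-predictor report with columns
    ``predictor, r, p, selected`` (column order of the input preserved) and
    the reduced table of surviving predictors plus the response.  Constant
    predictors are excluded with a warning; zero survivors raise.
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} missing from table")
    if p_direction not in ("less", "greater"):
        raise ValueError("p_direction must be 'less' or 'greater'")
    y = table[response].to_numpy(dtype=float)
    rows = []
    for col in table.columns:
        if col == response:
            continue
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or not np.isfinite(x).all():
            logger.warning("predictor %s constant or non-finite; excluded from screening",
                           col)
            rows.append({"predictor": col, "r": np.nan, "p": np.nan, "selected": False})
            continue
        r, p = pearson_r_p(x, y)
        sig = p < alpha if p_direction == "less" else p > alpha
        rows.append({"predictor": col, "r": r, "p": p,
                     "selected": bool(abs(r) >= threshold and sig)})
    report = pd.DataFrame(rows)
    survivors = report.loc[report["selected"], "predictor"].tolist()
    logger.info("screening kept %d of %d predictors (|r| >= %.2f, p %s %.2f)",
                len(survivors), len(report), threshold,
                "<" if p_direction == "less" else ">", alpha)
    if not survivors:
        raise ValueError("no predictor survived screening; lower the threshold "
                         "or relax alpha")
    reduced = table[survivors + [response]].copy()
    return report, reduced
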