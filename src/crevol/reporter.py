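"""Reporter-assay statistics.

Luciferase-style construct activities are compared with the empty-vector
control by the Wilcoxon rank-sum (Mann-Whitney) test: exact null
enumeration when both samples have at most 25 replicates and no ties,
normal approximation with tie correction otherwise.  Significant
constructs are classified as activators (median above control) or
repressors (median below control).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import bh_adjust

EXACT_N_MAX = 25


def wilcoxon_vs_control(
    construct: Sequence[float], control: Sequence[float]
) -> float:
    """Two-sided rank-sum p-value for construct vs control activities."""
    x = np.asarray(construct, dtype=float)
    y = np.asarray(control, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 replicates per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= EXACT_N_MAX and len(y) <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def classify_direction(
    construct: Sequence[float],
    control: Sequence[float],
    p: float,
    alpha: float = 0.05,
) -> str:
    """'activator' / 'repressor' / 'ns' from the test and median ratio."""
    if p >= alpha:
        return "ns"
    med_c = float(np.median(np.asarray(construct, dtype=float)))
    med_0 = float(np.median(np.asarray(control, dtype=float)))
    if med_c > med_0:
        return "activator"
    if med_c < med_0:
        return "repressor"
    return "ns"


def analyze_reporter(
    activities: pd.DataFrame, alpha: float = 0.05, adjust: bool = False
) -> pd.DataFrame:
    """Per-construct rank-sum tests against the pooled control wells.

    ``activities`` columns: construct_id, replicate, activity, is_control.
    Returns one row per non-control construct with p, optional BH column,
    direction, and the two medians.  Direction uses raw p-values by
    default, matching per-construct reporting; set ``adjust=True`` to
    classify on BH-adjusted p instead.
    """
    required = {"construct_id", "activity", "is_control"}
    if not required <= set(activities.columns):
        raise ValueError(f"activities table needs columns {sorted(required)}")
    control = activities.loc[activities["is_control"].astype(bool), "activity"].to_numpy(float)
    if len(control) < 2:
        raise ValueError("need at least 2 control replicates")
    rows = []
    for cid, grp in activities[~activities["is_control"].astype(bool)].groupby("construct_id"):
        vals = grp["activity"].to_numpy(float)
        p = wilcoxon_vs_control(vals, control)
        rows.append(
            {
                "construct_id": cid,
                "n_replicates": len(vals),
                "median_activity": float(np.median(vals)),
                "median_control": float(np.median(control)),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["p"])
        crit = out["padj"] if adjust else out["p"]
        out["direction"] = [
            classify_direction(
                activities.loc[
                    (~activities["is_control"].astype(bool))
                    & (activities["construct_id"] == r.construct_id),
                    "activity",
                ].to_numpy(float),
                control,
                c,
                alpha,
            )
            for r, c in zip(out.itertuples(), crit)
        ]
    return out
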