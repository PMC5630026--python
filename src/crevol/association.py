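"""Association statistics linking regulatory and expression divergence.

Three tests connect the conservation calls to genomic covariates:

* Cochran-Mantel-Haenszel common odds ratio over stratified 2x2 tables
  (one stratum per species comparison) — is a differentially expressed
  gene more likely to carry a differentially modified CRE?
* Fisher's exact test for single 2x2 tables (e.g. conserved x TE overlap).
* Logistic regression of a binary conservation outcome on a continuous or
  quantile-binned covariate (sequence divergence, TSS distance, TFBS
  counts, cell-type specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass
class AssociationResult:
    test_name: str
    statistic: float
    odds_ratio: Optional[float]
    ci95: Optional[Tuple[float, float]]
    p: Optional[float]
    stratum_count: int = 1
    flagged: bool = False
    note: str = ""


def cmh_test(strata: Sequence[np.ndarray | Sequence[Sequence[int]]]) -> AssociationResult:
    """Cochran-Mantel-Haenszel test over 2x2 strata.

    The common odds ratio is Mantel-Haenszel pooled
    ``sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``; the chi-square statistic
    is computed without continuity correction.  A single stratum reduces
    exactly to that table's MH odds ratio.  All-degenerate strata (a zero
    margin everywhere) yield a flagged, undefined result.
    """
    tables = [np.asarray(t, dtype=float) for t in strata]
    if not tables:
        raise ValueError("need at least one stratum")
    for t in tables:
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("strata must be non-negative integer 2x2 tables")
    informative = [t for t in tables if t.sum(axis=0).min() > 0 or t.sum(axis=1).min() > 0]
    nondegenerate = [t for t in tables if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all()]
    if not nondegenerate:
        return AssociationResult(
            "cmh", float("nan"), None, None, None, len(tables), flagged=True,
            note="all strata degenerate",
        )
    st = StratifiedTable(tables)
    orr = float(st.oddsratio_pooled)
    test = st.test_null_odds(correction=False)
    lo, hi = st.oddsratio_pooled_confint()
    return AssociationResult(
        "cmh",
        float(test.statistic),
        orr,
        (float(lo), float(hi)),
        float(test.pvalue),
        len(tables),
    )


def fisher_exact(table: np.ndarray | Sequence[Sequence[int]]) -> AssociationResult:
    """Two-sided Fisher's exact test with conditional-MLE odds ratio.

    The p-value sums all hypergeometric probabilities no larger than the
    observed table's.  A zero margin makes the table uninformative:
    p = 1 and the odds ratio is undefined.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return AssociationResult("fisher", float("nan"), None, None, 1.0, flagged=True,
                                 note="zero margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    res = stats.contingency.odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(0.95)
    return AssociationResult(
        "fisher", float(res.statistic), float(res.statistic),
        (float(ci.low), float(ci.high)), float(p),
    )


def logistic_conservation(
    outcome: Iterable[bool | int], covariate: Iterable[float]
) -> AssociationResult:
    """Logistic regression of a binary outcome on one covariate.

    Newton-fitted binomial GLM with logit link; the Wald p-value on the
    slope is reported, with the slope as ``statistic`` and exp(slope) as
    the odds ratio per covariate unit.  Complete separation is flagged
    with the p-value omitted; a constant covariate is rejected.
    """
    y = np.asarray(list(outcome), dtype=float)
    x = np.asarray(list(covariate), dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and covariate lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    y, x = y[keep], x[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant: no variation to regress on")
    X = sm.add_constant(x)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return AssociationResult("logistic", float("nan"), None, None, None,
                                 flagged=True, note="complete separation")
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    converged = bool(fit.mle_retvals.get("converged", True))
    if not converged or not np.isfinite(se) or se > 1e3 * max(1.0, abs(slope)):
        return AssociationResult("logistic", slope, None, None, None,
                                 flagged=True, note="separation or non-convergence")
    p = float(fit.pvalues[1])
    ci = fit.conf_int()[1]
    return AssociationResult(
        "logistic", slope, float(np.exp(slope)),
        (float(np.exp(ci[0])), float(np.exp(ci[1]))), p,
    )


def quantile_bins(values: Iterable[float], n_bins: int = 10) -> np.ndarray:
    """Quantile (default decile) bin index per value; ties go to the lower bin."""
    x = np.asarray(list(values), dtype=float)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="left")


def de_cre_strata(
    gene_calls: pd.DataFrame,
    cre_calls: pd.DataFrame,
    gene_links: pd.DataFrame,
    comparisons: Sequence[str],
) -> List[np.ndarray]:
    """Build CMH strata: differential expression x differential CRE state.

    One 2x2 table per comparison, over genes: rows = gene differentially
    expressed in that comparison or not, columns = gene linked to at
    least one differentially modified CRE in that comparison or not.
    ``gene_links`` maps cre_id -> gene (columns cre_id, gene).
    """
    strata = []
    for cid in comparisons:
        g = gene_calls[gene_calls["comparison_id"] == cid].set_index("feature_id")
        c = cre_calls[cre_calls["comparison_id"] == cid]
        dm_cres = set(c.loc[c["significant"] == True, "feature_id"])  # noqa: E712
        linked = gene_links.groupby("gene")["cre_id"].apply(
            lambda ids: any(i in dm_cres for i in ids)
        )
        genes = g.index.intersection(linked.index)
        de = g.loc[genes, "significant"].astype(bool).to_numpy()
        dm = linked.loc[genes].astype(bool).to_numpy()
        strata.append(
            np.array(
                [
                    [np.sum(de & dm), np.sum(de & ~dm)],
                    [np.sum(~de & dm), np.sum(~de & ~dm)],
                ]
            )
        )
    return strata
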