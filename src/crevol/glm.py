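"""Negative-binomial GLM core for differential histone modification and
differential expression.

This module re-implements, self-contained, the count-model machinery the
cross-species comparisons rest on:

* median-of-ratios size factors (per-sample sequencing-depth normalisation),
* per-feature maximum-likelihood NB dispersion (variance = mu + alpha*mu^2),
* IRLS fitting of the NB GLM with log link and offsets,
* Wald tests on single coefficients and Benjamini-Hochberg adjustment.

Differential histone modification uses the interaction design

    log mu = intercept + assay + condition + assay:condition  (+ log sizefactor)

where ``assay`` separates immunoprecipitated (IP) from input chromatin and
``condition`` separates the two species groups being compared.  The
``assay:condition`` coefficient is the species effect on IP enrichment over
input — the quantity tested.  Differential expression uses the plain
``~ condition`` design with gene-length offsets.

Dispersion is estimated per feature by profile maximum likelihood without
empirical-Bayes shrinkage across features; with the group sizes used here
(>= 3 individuals x 2 assays per group) this is adequate and keeps the
estimator free of cross-feature modelling assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

LN2 = math.log(2.0)

ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0


class ComparisonError(ValueError):
    """A comparison cannot be run with the samples available."""


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample metadata.

    ``metadata`` is indexed by sample id and carries at least ``species``,
    ``individual`` and ``assay`` (``IP``/``input``); ChIP tables also carry
    ``mark`` and RNA tables ``mark == 'none'``.  ``feature_lengths`` (bp) is
    used for RNA length offsets.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    feature_lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.metadata.index):
            # allow metadata in any order but require coverage
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
            self.metadata = self.metadata.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.loc[self.counts.index]
            if (self.feature_lengths <= 0).any():
                raise ValueError("feature_lengths must be positive")

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)],
            self.metadata.loc[list(sample_ids)],
            self.feature_lengths,
        )


# ---------------------------------------------------------------------------
# normalisation


def estimate_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each feature positive in every sample, the ratio of each sample's
    count to the feature's geometric mean is formed; a sample's factor is
    the median of its ratios.  If no feature is positive in all samples the
    per-sample median is taken over that sample's positive-count features
    (with a warning via ``RuntimeWarning``).
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("counts must be a 2-D features x samples array")
    all_pos = (X > 0).all(axis=1)
    if all_pos.any():
        ref = X[all_pos]
        log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
        ratios = np.log(ref) - log_geo
        log_sf = np.median(ratios, axis=0)
    else:
        import warnings

        warnings.warn(
            "no feature has positive counts in all samples; "
            "falling back to positive-count-only medians",
            RuntimeWarning,
        )
        with np.errstate(divide="ignore"):
            logX = np.where(X > 0, np.log(X), np.nan)
        log_geo = np.nanmean(logX, axis=1, keepdims=True)
        ratios = logX - log_geo
        log_sf = np.nanmedian(ratios, axis=0)
        log_sf = np.where(np.isnan(log_sf), 0.0, log_sf)
    log_sf = log_sf - np.mean(log_sf)  # geometric mean 1
    return np.exp(log_sf)


# ---------------------------------------------------------------------------
# NB likelihood and dispersion


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood with variance mu + alpha*mu^2 (Poisson as alpha->0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    # below ~1e-7 the NB expressions cancel catastrophically; the Poisson
    # limit is then accurate to far better than the remaining terms
    if alpha < 1e-7:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def estimate_dispersion(
    counts_row: np.ndarray,
    fitted_means: np.ndarray,
    bounds: tuple[float, float] = (ALPHA_MIN, ALPHA_MAX),
    design_matrix: Optional[np.ndarray] = None,
) -> float:
    """Per-feature ML dispersion alpha given fitted means.

    Maximises the NB log-likelihood over log(alpha) within ``bounds``.
    When ``design_matrix`` is given, the Cox-Reid adjustment
    ``-0.5 log det(X' W X)`` is added to the profile likelihood, removing
    the downward bias caused by estimating the mean coefficients from the
    same few samples; the differential-testing drivers use this form.
    Returns the lower bound when the data are under-dispersed relative to
    Poisson.  All-zero rows are rejected (no information about alpha).
    """
    y = np.asarray(counts_row, dtype=float)
    mu = np.asarray(fitted_means, dtype=float)
    if not np.any(y > 0):
        raise ValueError("all-zero count row: dispersion undefined")
    lo, hi = bounds

    if design_matrix is None:

        def neg_ll(log_a: float) -> float:
            return -nb_loglik(y, mu, math.exp(log_a))

    else:
        X = np.asarray(design_matrix, dtype=float)

        def neg_ll(log_a: float) -> float:
            a = math.exp(log_a)
            W = mu / (1.0 + a * mu)
            _, logdet = np.linalg.slogdet(X.T @ (X * W[:, None]))
            return -(nb_loglik(y, mu, a) - 0.5 * logdet)

    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = float(math.exp(res.x))
    # prefer the boundary if it is at least as good (bounded search cannot
    # sit exactly on the bound)
    if neg_ll(math.log(lo)) <= res.fun:
        alpha = lo
    return min(max(alpha, lo), hi)


# ---------------------------------------------------------------------------
# IRLS GLM


@dataclass
class NBFit:
    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    deviance: float
    alpha: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if alpha < 1e-7:
        dev = 2.0 * np.sum(t1 - (y - mu))
    else:
        inv = 1.0 / alpha
        t2 = (y + inv) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
        dev = 2.0 * np.sum(t1 - t2)
    return float(dev)


def fit_nb_glm(
    counts_row: np.ndarray,
    design_matrix: np.ndarray,
    offsets: np.ndarray | float = 0.0,
    alpha: float = ALPHA_MIN,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NBFit:
    """Fit an NB GLM with log link by IRLS with step halving.

    ``offsets`` are added to the linear predictor (log size factors, plus
    log feature length for RNA).  The covariance is the inverse Fisher
    information at the optimum, treating ``alpha`` as fixed.  Step halving
    guarantees the deviance is non-increasing across iterations; failure to
    reach ``tol`` within ``max_iter`` is flagged, not raised.
    """
    y = np.asarray(counts_row, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("counts_row and design_matrix disagree on n")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name a maximal independent set; the rest are collinear
        q, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [j for j in range(p) if j < len(diag) and diag[j] < 1e-10 * diag.max()]
        raise ValueError(f"design matrix not full rank (rank {rank} < {p}); suspect columns {bad}")
    offs = np.broadcast_to(np.asarray(offsets, dtype=float), (n,)).copy()

    eta = np.log(y + 0.5) - offs
    beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    mu = np.exp(np.clip(X @ beta + offs, -30.0, 30.0))
    dev = _nb_deviance(y, mu, alpha)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + offs, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)  # Fisher weights for log link, NB2
        z = (eta - offs) + (y - mu) / mu
        WX = X * W[:, None]
        XtWX = X.T @ WX
        XtWz = WX.T @ z
        try:
            beta_new = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(XtWX, XtWz, rcond=None)[0]
        step = beta_new - beta
        # step halving: never let the deviance increase
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            mu_c = np.exp(np.clip(X @ cand + offs, -30.0, 30.0))
            dev_c = _nb_deviance(y, mu_c, alpha)
            if dev_c <= dev + 1e-10 * max(1.0, abs(dev)):
                break
            lam *= 0.5
        else:
            cand, dev_c = beta, dev
        delta = np.max(np.abs(cand - beta))
        beta, dev = cand, dev_c
        if delta < tol:
            converged = True
            break

    eta = np.clip(X @ beta + offs, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    XtWX = X.T @ (X * W[:, None])
    cov = np.linalg.pinv(XtWX)
    return NBFit(coef=beta, cov=cov, converged=converged, n_iter=it, deviance=dev, alpha=alpha)


def wald_test(coefficient: float, se: float) -> tuple[float, float]:
    """Wald z and two-sided normal p for a single coefficient."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = coefficient / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential testing drivers


def _check_groups(meta: pd.DataFrame, group_a: frozenset, group_b: frozenset, with_assay: bool) -> None:
    if group_a & group_b:
        raise ComparisonError("species groups overlap")
    for name, grp in (("A", group_a), ("B", group_b)):
        sub = meta[meta["species"].isin(grp)]
        if with_assay:
            for assay in ("IP", "input"):
                n = (sub["assay"] == assay).sum()
                if n < 2:
                    raise ComparisonError(
                        f"group {name} has {n} {assay} samples (< 2); comparison refused"
                    )
        else:
            if len(sub) < 2:
                raise ComparisonError(f"group {name} has {len(sub)} samples (< 2)")


def _fit_one(y: np.ndarray, X: np.ndarray, offs: np.ndarray, test_col: int):
    """Two-step fit: Poisson-limit means, ML dispersion, NB refit, Wald."""
    fit0 = fit_nb_glm(y, X, offs, alpha=ALPHA_MIN)
    mu0 = np.exp(np.clip(X @ fit0.coef + offs, -30.0, 30.0))
    alpha = estimate_dispersion(y, mu0, design_matrix=X)
    fit = fit_nb_glm(y, X, offs, alpha=alpha) if alpha > ALPHA_MIN else fit0
    coef = float(fit.coef[test_col])
    se = float(fit.se[test_col])
    if not np.isfinite(se) or se <= 0:
        return coef / LN2, np.nan, np.nan, np.nan, False
    z, p = wald_test(coef, se)
    return coef / LN2, se / LN2, z, p, fit.converged


def diff_histone(
    counts: CountMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    comparison_id: str = "",
    mark: Optional[str] = None,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Differential histone modification between two species groups.

    Fits, per region, the interaction model ``~ assay + condition +
    assay:condition`` on IP and input counts jointly and Wald-tests the
    interaction coefficient: a species-group difference in IP signal that
    is not mirrored in the input.  Regions whose IP counts are all zero in
    the selected samples are reported ``untested`` and excluded from the
    BH adjustment.  ``log2fc > 0`` means higher IP enrichment in group A.
    """
    ga, gb = frozenset(group_a), frozenset(group_b)
    meta = counts.metadata
    keep = meta["species"].isin(ga | gb) & meta["assay"].isin(["IP", "input"])
    if mark is not None:
        keep &= meta["mark"] == mark
    sub = counts.subset_samples(list(meta.index[keep]))
    _check_groups(sub.metadata, ga, gb, with_assay=True)

    is_ip = (sub.metadata["assay"] == "IP").to_numpy(dtype=float)
    in_a = sub.metadata["species"].isin(ga).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(is_ip), is_ip, in_a, is_ip * in_a])
    sf = estimate_size_factors(sub.counts)
    offs = np.log(sf)

    Y = sub.counts.to_numpy(dtype=float)
    ip_mask = is_ip.astype(bool)
    rows = []
    for i, fid in enumerate(sub.counts.index):
        y = Y[i]
        if not np.any(y[ip_mask] > 0):
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, "untested"))
            continue
        l2fc, se, z, p, conv = _fit_one(y, X, offs, test_col=3)
        status = "tested" if conv and np.isfinite(p) else "not_converged"
        rows.append((fid, l2fc, se, z, p, status))
    res = pd.DataFrame(
        rows, columns=["feature_id", "log2fc", "se", "wald_z", "p", "status"]
    )
    res.insert(1, "comparison_id", comparison_id)
    tested = res["p"].notna()
    res["padj"] = np.nan
    if tested.any():
        res.loc[tested, "padj"] = bh_adjust(res.loc[tested, "p"])
    res["significant"] = tested & (res["padj"] < fdr)
    return res


def diff_expression(
    counts: CountMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    comparison_id: str = "",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential expression between two species groups (``~ condition``).

    Offsets combine log size factors with log gene length so that the
    condition coefficient is a length-normalised abundance contrast.
    """
    ga, gb = frozenset(group_a), frozenset(group_b)
    meta = counts.metadata
    keep = meta["species"].isin(ga | gb)
    sub = counts.subset_samples(list(meta.index[keep]))
    _check_groups(sub.metadata, ga, gb, with_assay=False)

    in_a = sub.metadata["species"].isin(ga).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(in_a), in_a])
    sf = estimate_size_factors(sub.counts)
    log_sf = np.log(sf)

    if sub.feature_lengths is not None:
        log_len = np.log(sub.feature_lengths.to_numpy(dtype=float))
    else:
        log_len = np.zeros(len(sub.counts))

    Y = sub.counts.to_numpy(dtype=float)
    rows = []
    for i, fid in enumerate(sub.counts.index):
        y = Y[i]
        if not np.any(y > 0):
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, "untested"))
            continue
        offs = log_sf + log_len[i]
        l2fc, se, z, p, conv = _fit_one(y, X, offs, test_col=1)
        status = "tested" if conv and np.isfinite(p) else "not_converged"
        rows.append((fid, l2fc, se, z, p, status))
    res = pd.DataFrame(
        rows, columns=["feature_id", "log2fc", "se", "wald_z", "p", "status"]
    )
    res.insert(1, "comparison_id", comparison_id)
    tested = res["p"].notna()
    res["padj"] = np.nan
    if tested.any():
        res.loc[tested, "padj"] = bh_adjust(res.loc[tested, "p"])
    res["significant"] = tested & (res["padj"] < fdr)
    return res
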