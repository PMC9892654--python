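"""Differential-expression pre-filter.

One-way fixed-effects ANOVA of every feature across the response groups;
features with p below a threshold (default 0.05, uncorrected, strict
inequality) are retained as differentially expressed proteins (DEPs).  The F
statistic is computed from explicit between/within sums of squares,
vectorized over features; p-values come from the F distribution.

Degenerate features are handled by a documented convention: when the
within-group variance is exactly zero, p is 0 if the group means differ
(infinite evidence) and 1 if every value is identical (no signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import CLASSES, ExpressionMatrix, ResponseLabels


@dataclass(frozen=True)
class DepResult:
    feature_id: str
    f_statistic: float
    p_value: float
    group_means: tuple[float, float, float]  # (RD, NR, PR); NaN if group absent


def anova_scan(
    m: ExpressionMatrix, labels: ResponseLabels, log2: bool = False
) -> list[DepResult]:
    """One-way ANOVA of each feature across the response groups.

    Requires a fully imputed matrix and at least two groups with at least two
    samples each.  ``log2=True`` tests log2 abundances instead of the raw
    values (all values must then be positive).
    """
    if m.missing_mask.any():
        raise ValueError("matrix contains missing values; impute first")
    aligned = labels.aligned_to(m.sample_ids)
    groups = {c: idx for c, idx in aligned.group_indices().items() if idx.size > 0}
    if len(groups) < 2:
        raise ValueError("need at least two response groups")
    for c, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"group {c} has {idx.size} sample(s); need at least 2")

    X = m.values
    if log2:
        if np.any(X <= 0):
            raise ValueError("log2 transform requires strictly positive abundances")
        X = np.log2(X)

    n = X.shape[1]
    k = len(groups)
    grand_mean = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    group_means: dict[str, np.ndarray] = {}
    for c, idx in groups.items():
        sub = X[:, idx]
        gm = sub.mean(axis=1)
        group_means[c] = gm
        ss_between += idx.size * (gm - grand_mean) ** 2
        ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)

    df_between = k - 1
    df_within = n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    p = stats.f.sf(f, df_between, df_within)

    # zero within-group variance: p = 0 when group means differ, 1 when the
    # feature is constant everywhere (then F is defined as 0)
    tol = 1e-12 * np.maximum(1.0, np.abs(X).max(axis=1)) ** 2
    degenerate = ss_within <= tol * df_within
    no_signal = degenerate & (ss_between <= tol)
    f = np.where(degenerate, np.inf, f)
    f = np.where(no_signal, 0.0, f)
    p = np.where(degenerate, 0.0, p)
    p = np.where(no_signal, 1.0, p)

    results = []
    for i, fid in enumerate(m.feature_ids):
        gm3 = tuple(
            float(group_means[c][i]) if c in group_means else float("nan")
            for c in CLASSES
        )
        results.append(
            DepResult(
                feature_id=fid,
                f_statistic=float(f[i]),
                p_value=float(p[i]),
                group_means=gm3,  # type: ignore[arg-type]
            )
        )
    return results


def filter_deps(
    results: list[DepResult], alpha: float = 0.05, method: str = "none"
) -> list[str]:
    """Feature IDs with p < alpha, input order preserved.

    ``method="fdr_bh"`` applies Benjamini-Hochberg correction before
    thresholding (off by default; the discovery protocol uses raw p-values).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if method == "none":
        return [r.feature_id for r in results if r.p_value < alpha]
    if method == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        pvals = np.array([r.p_value for r in results])
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        return [r.feature_id for r, keep in zip(results, reject) if keep]
    raise ValueError(f"unknown method {method!r}; use 'none' or 'fdr_bh'")
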