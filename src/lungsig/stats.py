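"""Association statistics for signature exposures and cohort phenotypes.

The tests here are the cohort-level workhorses: a Cochran-Armitage trend
test for a binary outcome over ordered exposure groups, Fisher's exact
test with the conditional-MLE odds ratio for 2x2 count tables, the
Wilcoxon rank-sum test, Spearman (partial) rank correlation, the
Benjamini-Hochberg step-up FDR, and the SPM cell-type specificity score.
All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import brentq
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d: rows = exposed/unexposed, cols = outcome/no outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def cochran_armitage_trend(
    successes: np.ndarray, totals: np.ndarray, scores: np.ndarray | None = None
) -> tuple[float, float]:
    """Cochran-Armitage test for a linear trend in proportions.

    ``successes[i]`` of ``totals[i]`` events in group i with monotone group
    score ``scores[i]`` (defaults to 1..G). Returns (Z, two-sided p) with Z
    referred to the standard normal; Z > 0 means the proportion increases
    with the score.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 groups of matching shape")
    if (n <= 0).any():
        raise ValueError("every group needs a positive total")
    if (x > n).any():
        raise ValueError("successes exceed totals")
    s = np.arange(1, len(x) + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if len(s) != len(x):
        raise ValueError("scores length mismatch")
    N = n.sum()
    p_bar = x.sum() / N
    num = float(s @ (x - n * p_bar))
    var = p_bar * (1 - p_bar) * float(n @ s**2 - (n @ s) ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    return float(z), float(2 * st.norm.sf(abs(z)))


def exposure_trend_groups(
    contributions: np.ndarray, outcome: np.ndarray, n_groups: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Bin samples into equal-size quantile groups of a signature's
    contribution and tally a binary outcome per group."""
    contributions = np.asarray(contributions, dtype=float)
    outcome = np.asarray(outcome)
    n_groups = min(n_groups, len(contributions))  # no empty quantile groups
    order = np.argsort(contributions, kind="stable")
    group = np.empty(len(order), dtype=int)
    # equal-size groups (sizes differ by at most 1)
    splits = np.array_split(order, n_groups)
    for g, idx in enumerate(splits):
        group[idx] = g
    successes = np.array([outcome[group == g].sum() for g in range(n_groups)], dtype=float)
    totals = np.array([(group == g).sum() for g in range(n_groups)], dtype=float)
    return successes, totals


def _log_nchg_weights(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Support and log binomial-product weights of the noncentral
    hypergeometric distribution of the a-cell given fixed margins."""
    m1 = table.a + table.b      # exposed row total
    m2 = table.c + table.d
    k = table.a + table.c       # outcome column total
    lo = max(0, k - m2)
    hi = min(k, m1)
    support = np.arange(lo, hi + 1)
    logw = (
        gammaln(m1 + 1) - gammaln(support + 1) - gammaln(m1 - support + 1)
        + gammaln(m2 + 1) - gammaln(k - support + 1) - gammaln(m2 - (k - support) + 1)
    )
    return support, logw


def _conditional_mean(log_psi: float, support: np.ndarray, logw: np.ndarray) -> float:
    logp = logw + support * log_psi
    logp -= logp.max()
    p = np.exp(logp)
    return float((support * p).sum() / p.sum())


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Fisher's exact test: conditional-MLE odds ratio and two-sided p.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one (the
    minimum-likelihood rule used by mainstream statistical software). The
    odds ratio maximizes the Fisher noncentral hypergeometric likelihood
    of the observed a-cell; with a zero cell it is 0 or inf.
    """
    a = table.a
    support, logw = _log_nchg_weights(table)
    if len(support) == 1:
        return np.nan, 1.0

    # two-sided p under the central (psi = 1) distribution
    logp = logw - logw.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[support == a][0]
    pvalue = float(probs[probs <= p_obs * (1 + 1e-7)].sum())

    # conditional MLE: E_psi[a] = a_obs has the same root as the score eqn
    if a == support[0]:
        or_cmle = 0.0 if a < support[-1] else np.nan
    elif a == support[-1]:
        or_cmle = np.inf
    else:
        f = lambda t: _conditional_mean(t, support, logw) - a
        lo, hi = -1.0, 1.0
        while f(lo) > 0:
            lo *= 2
        while f(hi) < 0:
            hi *= 2
        or_cmle = float(np.exp(brentq(f, lo, hi, xtol=1e-12)))
    return or_cmle, min(pvalue, 1.0)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact null distribution when m + n <= 20 and there are no ties;
    normal approximation with midranks and tie correction otherwise.
    Returns (rank-sum statistic W of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic + len(x) * (len(x) + 1) / 2)  # U -> rank sum
    return w, float(min(res.pvalue, 1.0))


def spearman_partial(x, y, covariates=None) -> tuple[float, float]:
    """Spearman rank correlation of x and y, optionally partial on covariates.

    All variables are midrank-transformed; with covariates, the ranked x
    and y are residualized on the ranked covariates (with intercept) by
    least squares and the Pearson correlation of the residuals is
    reported, with a t reference on n - 2 - #covariates df. Without
    covariates this is plain Spearman.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("length mismatch")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan, np.nan
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    k = 0
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate length mismatch")
        k = C.shape[1]
        RC = np.column_stack([np.ones(n)] + [st.rankdata(C[:, j]) for j in range(k)])
        rx = rx - RC @ np.linalg.lstsq(RC, rx, rcond=None)[0]
        ry = ry - RC @ np.linalg.lstsq(RC, ry, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    r = float(np.clip(((rx - rx.mean()) @ (ry - ry.mean())) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        return r, np.nan
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r * r))
    return r, float(2 * st.t.sf(abs(t), df))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def spm_score(expression, target: int) -> float:
    """Specificity measure of one gene for one cell type.

    SPM_t = x_t / ||x||_2: the cosine between the gene's expression
    profile across cell types and the ideal one-hot profile of the target
    type. 1 means exclusive expression in the target type; genes with
    SPM > 0.9 form a type's specific gene set.
    """
    x = np.asarray(expression, dtype=float)
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    norm = np.linalg.norm(x)
    if norm == 0:
        return np.nan
    return float(x[target] / norm)


def specific_genes(expr: pd.DataFrame, cutoff: float = 0.9) -> dict[str, list[str]]:
    """Per-cell-type specific gene sets (SPM strictly above the cutoff).

    ``expr``: genes x cell types matrix of non-negative expression.
    """
    X = expr.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    out: dict[str, list[str]] = {}
    for j, ct in enumerate(expr.columns):
        with np.errstate(invalid="ignore", divide="ignore"):
            spm = np.where(norms > 0, X[:, j] / norms, np.nan)
        out[ct] = list(expr.index[spm > cutoff])
    return out


def association_report(
    contributions: pd.DataFrame, cohort: pd.DataFrame, n_groups: int = 10
) -> pd.DataFrame:
    """One row per (signature, phenotype) association.

    Binary phenotypes get the quantile-group trend test; TIL abundance
    columns (prefix ``til_``) get Spearman correlations. p-values are
    BH-adjusted within the report.
    """
    rows = []
    binary_cols = [c for c in ("driver_status", "fusion_status") if c in cohort]
    til_cols = [c for c in cohort.columns if c.startswith("til_")]
    samples = [s for s in contributions.columns if s in set(cohort["sample_id"])]
    coh = cohort.set_index("sample_id").loc[samples]
    for sig in contributions.index:
        contrib = contributions.loc[sig, samples].to_numpy(dtype=float)
        for col in binary_cols:
            outcome = coh[col].to_numpy(dtype=int)
            succ, tot = exposure_trend_groups(contrib, outcome, n_groups=n_groups)
            z, p = cochran_armitage_trend(succ, tot)
            rows.append({"signature": sig, "phenotype": col,
                         "test": "cochran_armitage", "statistic": z, "p": p})
        for col in til_cols:
            r, p = spearman_partial(contrib, coh[col].to_numpy(dtype=float))
            rows.append({"signature": sig, "phenotype": col,
                         "test": "spearman", "statistic": r, "p": p})
    report = pd.DataFrame(rows)
    if len(report):
        report["q"] = bh_fdr(report["p"].to_numpy())
    return report
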