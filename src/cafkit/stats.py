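"""Cohort-level statistics: ΔΔCt quantification, coculture tests,
correlation matrices, lactate-gene clustering, exact contingency tests
and survival analysis.

The r×c Fisher exact test enumerates every table with the observed
margins and sums the hypergeometric probabilities of tables no more
probable than the observed one (the probability-mass two-sided
convention, as in R's ``fisher.test``). Kaplan–Meier / log-rank / Cox
fits go through lifelines; the bidirectional stepwise-AIC model search
around them is implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

#: Gene panel used for the two-cluster lactate-shuttle analysis.
LACTATE_PANEL = ("MCT1", "MCT4", "CD147", "CAV1", "ACTA2")

_ENUM_GUARD = 500  # largest table total for exact enumeration
_P_SLACK = 1e-7  # numerical slack on the probability-mass criterion


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# Comparative Ct (ΔΔCt)
# ---------------------------------------------------------------------------

def ddct(records: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Relative expression by the comparative Ct method.

    ``records`` needs columns ``sample``, ``condition``, ``gene``,
    ``ct_target``, ``ct_ref`` (the reference gene, PSMB2 in this
    pipeline, measured on the same sample). Per record
    ΔCt = Ct_target − Ct_ref; per gene the control ΔCt is the arithmetic
    mean over samples of ``control_condition``; ΔΔCt = ΔCt − control
    mean. Returns the input rows with ``dct``, ``ddct``, ``log2fc``
    (= −ΔΔCt) and ``fold_change`` (= 2^−ΔΔCt) columns.
    """
    required = {"sample", "condition", "gene", "ct_target", "ct_ref"}
    missing = required - set(records.columns)
    if missing:
        raise StatsError(f"qPCR table missing column(s) {sorted(missing)}")
    out = records.copy()
    out["dct"] = out["ct_target"] - out["ct_ref"]
    control = out[out["condition"] == control_condition]
    control_mean = control.groupby("gene")["dct"].mean()
    for gene in out["gene"].unique():
        if gene not in control_mean.index:
            raise StatsError(
                f"no control ({control_condition!r}) measurements for gene {gene!r}"
            )
    out["ddct"] = out["dct"] - out["gene"].map(control_mean)
    out["log2fc"] = -out["ddct"]
    out["fold_change"] = np.power(2.0, out["log2fc"])
    return out


# ---------------------------------------------------------------------------
# t-tests and correlations
# ---------------------------------------------------------------------------

def one_sample_test(values: Sequence[float]) -> tuple[float, float]:
    """Two-sided one-sample t-test of log2 fold changes against 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("one-sample test needs n >= 2")
    if np.std(x, ddof=1) == 0:
        raise StatsError("one-sample test undefined for zero-variance data")
    res = sps.ttest_1samp(x, 0.0)
    return float(res.statistic), float(res.pvalue)


def paired_test(
    before: Sequence[float], after: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired t-test."""
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired test needs equal-length samples")
    if a.size < 2:
        raise StatsError("paired test needs n >= 2")
    d = b - a
    if np.all(d == d[0]) and d[0] == 0:
        return 0.0, 1.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(
    measurements: pd.DataFrame,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p and a significance mask.

    ``measurements`` is a samples × variables table; pairs are computed
    on pairwise-complete observations. Constant columns yield NaN r/p
    (flagged, not raised). Returns ``{"r": ..., "p": ..., "significant":
    ..., "n": ...}`` DataFrames.
    """
    if variables is None:
        variables = list(measurements.columns)
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=variables, columns=variables)
    for i, vi in enumerate(variables):
        n.loc[vi, vi] = int(measurements[vi].notna().sum())
        for vj in variables[i + 1 :]:
            pair = measurements[[vi, vj]].dropna()
            n.loc[vi, vj] = n.loc[vj, vi] = len(pair)
            if len(pair) < 3:
                raise StatsError(
                    f"pair ({vi}, {vj}) has fewer than 3 complete observations"
                )
            if pair[vi].nunique() < 2 or pair[vj].nunique() < 2:
                rv, pv = np.nan, np.nan
            else:
                res = sps.pearsonr(pair[vi], pair[vj])
                rv, pv = float(res.statistic), float(res.pvalue)
            r.loc[vi, vj] = r.loc[vj, vi] = rv
            p.loc[vi, vj] = p.loc[vj, vi] = pv
    sig = (p < alpha) & p.notna()
    np.fill_diagonal(sig.values, False)
    return {"r": r, "p": p, "significant": sig, "n": n}


# ---------------------------------------------------------------------------
# Two-cluster lactate-gene clustering
# ---------------------------------------------------------------------------

def cluster_two(
    matrix: pd.DataFrame, panel: Sequence[str] = LACTATE_PANEL
) -> pd.Series:
    """Split samples into two clusters on the lactate-shuttle gene panel.

    Genes are z-scored, samples clustered by Ward linkage on Euclidean
    distance and the tree cut at k=2. Cluster 1 is the cluster with the
    lower mean standardised panel expression, making the labelling
    deterministic. Returns a Series of labels (1/2) indexed like
    ``matrix``.
    """
    missing = [g for g in panel if g not in matrix.columns]
    if missing:
        raise StatsError(f"expression matrix missing panel gene(s) {missing}")
    x = matrix[list(panel)].astype(float)
    if len(x) < 2:
        raise StatsError("clustering needs at least 2 samples")
    if not np.all(np.isfinite(x.values)):
        raise StatsError("expression matrix contains non-finite values")
    sd = x.std(ddof=1)
    z = (x - x.mean()) / sd.replace(0, np.nan)
    z = z.fillna(0.0)  # constant gene carries no clustering information
    lab = fcluster(linkage(z.values, method="ward"), t=2, criterion="maxclust")
    means = [z.values[lab == g].mean() for g in (1, 2)]
    if means[0] > means[1]:
        lab = 3 - lab
    return pd.Series(lab, index=matrix.index, name="cluster")


# ---------------------------------------------------------------------------
# Exact r×c Fisher test
# ---------------------------------------------------------------------------

def _table_logprobs(table: np.ndarray) -> tuple[float, float]:
    """(log P(observed), log-normalising constant) under fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    lf = gammaln(np.arange(n + 2) + 1.0)  # lf[k] = log k!
    const = lf[rows].sum() + lf[cols].sum() - lf[n]
    return float(const - lf[table].sum()), float(const)


def _enumeration_bound(t: np.ndarray) -> float:
    """Upper bound on the number of margin-preserving tables enumerated
    row by row: the product over non-final rows of the number of weak
    compositions of the row sum into c cells."""
    rows = t.sum(axis=1)
    c = t.shape[1]
    out = 1.0
    for r in map(int, rows[:-1]):
        out *= math.comb(r + c - 1, c - 1)
        if out > 1e18:
            break
    return out


def fisher_exact(table, *, slack: float = _P_SLACK) -> float:
    """Two-sided exact Fisher test on an r×c contingency table.

    Enumerates every non-negative integer table with the observed row
    and column margins and returns the sum of conditional
    (multivariate hypergeometric) probabilities of tables whose
    probability does not exceed the observed table's (within a relative
    slack of 1e-7 to absorb floating-point noise). The table is
    transposed internally when that makes the row-by-row enumeration
    cheaper (the p-value is transpose-invariant).

    Raises :class:`StatsError` for tables with total > 500; use
    :func:`fisher_exact_mc` for those.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.size == 0:
        raise StatsError("contingency table must be 2-dimensional")
    if (t < 0).any():
        raise StatsError("contingency table has negative counts")
    n = int(t.sum())
    if n == 0:
        raise StatsError("contingency table total must be > 0")
    if n > _ENUM_GUARD:
        raise StatsError(
            f"table total {n} exceeds exact-enumeration guard {_ENUM_GUARD}; "
            "use fisher_exact_mc for a seeded Monte-Carlo p-value"
        )
    if _enumeration_bound(t.T) < _enumeration_bound(t):
        t = t.T
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    lf = gammaln(np.arange(n + 2) + 1.0)
    const = lf[rows].sum() + lf[cols].sum() - lf[n]
    logp_obs = const - lf[t].sum()
    threshold = logp_obs + np.log1p(slack)

    r, c = t.shape
    total_mass = 0.0
    col_rem = cols.astype(np.int64).copy()

    def fill_row(i: int, neg_lf_sum: float) -> None:
        nonlocal total_mass
        if i == r - 1:
            # last row forced to the remaining column sums
            cells_lf = lf[col_rem].sum()
            logp = const + neg_lf_sum - cells_lf
            if logp <= threshold:
                total_mass += np.exp(logp)
            return

        row_total = int(rows[i])

        def fill_cell(j: int, rem: int, acc: float) -> None:
            if j == c - 1:
                if rem <= col_rem[j]:
                    col_rem[j] -= rem
                    fill_row(i + 1, acc - lf[rem])
                    col_rem[j] += rem
                return
            hi = min(rem, int(col_rem[j]))
            # remaining cells of this row must be able to absorb the rest
            tail_capacity = int(col_rem[j + 1 :].sum())
            lo = max(0, rem - tail_capacity)
            for v in range(lo, hi + 1):
                col_rem[j] -= v
                fill_cell(j + 1, rem - v, acc - lf[v])
                col_rem[j] += v

        fill_cell(0, row_total, neg_lf_sum)

    fill_row(0, 0.0)
    return float(min(total_mass, 1.0))


def fisher_exact_auto(
    table, *, max_tables: float = 2e6,
    n_permutations: int = 10**5, seed: int = 0,
) -> tuple[float, str]:
    """Exact Fisher p when enumeration is tractable, Monte Carlo otherwise.

    Returns ``(p, method)`` with method "exact" or "monte_carlo". The
    switch is on the enumeration-size bound, not the table total, so
    wide tables with large margins (where full enumeration would take
    hours) still get a defensible seeded permutation p-value.
    """
    t = np.asarray(table, dtype=np.int64)
    bound = min(_enumeration_bound(t), _enumeration_bound(t.T))
    if int(t.sum()) <= _ENUM_GUARD and bound <= max_tables:
        return fisher_exact(t), "exact"
    return fisher_exact_mc(t, n_permutations, seed), "monte_carlo"


def fisher_exact_mc(
    table, n_permutations: int = 10**6, seed: int = 0
) -> float:
    """Monte-Carlo two-sided Fisher p for tables too large to enumerate.

    Permutes the column labels of the underlying observation list and
    counts permuted tables no more probable than the observed one; the
    add-one estimator keeps the p-value away from exact zero.
    """
    t = np.asarray(table, dtype=np.int64)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    lf = gammaln(np.arange(n + 2) + 1.0)
    const = lf[rows].sum() + lf[cols].sum() - lf[n]
    logp_obs = const - lf[t].sum()
    threshold = logp_obs + np.log1p(_P_SLACK)

    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(t.shape[0]), rows)
    col_of = np.repeat(np.arange(t.shape[1]), cols)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(col_of)
        sim = np.zeros_like(t)
        np.add.at(sim, (row_of, perm), 1)
        if const - lf[sim].sum() <= threshold:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Survival analysis
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    """Kaplan–Meier curves per group and a log-rank comparison."""

    curves: dict[str, pd.DataFrame]
    logrank_p: float | None
    test_statistic: float | None


def km_logrank(
    records: pd.DataFrame,
    group_col: str,
    time_col: str = "time",
    event_col: str = "event",
) -> SurvivalResult:
    """Product-limit survival curves per group with a log-rank test.

    A single group yields curves only (no test); two groups use the
    standard two-sample log-rank, more the k-sample extension.
    """
    if records[event_col].sum() < 1:
        raise StatsError("survival analysis needs at least one event")
    if (records[time_col] <= 0).any():
        raise StatsError("survival times must be positive")
    curves: dict[str, pd.DataFrame] = {}
    groups = list(pd.unique(records[group_col]))
    for g in groups:
        sub = records[records[group_col] == g]
        km = KaplanMeierFitter(label=str(g))
        km.fit(sub[time_col], sub[event_col])
        curves[str(g)] = km.survival_function_
    if len(groups) < 2:
        return SurvivalResult(curves, None, None)
    if len(groups) == 2:
        a = records[records[group_col] == groups[0]]
        b = records[records[group_col] == groups[1]]
        res = logrank_test(a[time_col], b[time_col], a[event_col], b[event_col])
    else:
        res = multivariate_logrank_test(
            records[time_col], records[group_col], records[event_col]
        )
    return SurvivalResult(curves, float(res.p_value), float(res.test_statistic))


def _null_partial_loglik(durations: np.ndarray, events: np.ndarray) -> float:
    """Efron partial log-likelihood of the covariate-free model (β = 0)."""
    order = np.argsort(durations)
    t = durations[order]
    e = events[order].astype(bool)
    ll = 0.0
    n = len(t)
    at_risk = n
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        for ell in range(d):
            ll -= np.log(at_risk - ell)
        at_risk -= j - i
        i = j
    return ll


@dataclass
class StepwiseCoxResult:
    """Outcome of bidirectional stepwise-AIC Cox model selection."""

    selected: list[str]
    summary: pd.DataFrame  # HR, CI, p per retained covariate
    aic: float
    failed: list[str]  # covariates dropped for non-convergence/separation
    model: CoxPHFitter | None


def _fit_cox(
    df: pd.DataFrame, covs: list[str], time_col: str, event_col: str
) -> CoxPHFitter | None:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[[time_col, event_col] + covs], time_col, event_col)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return None
    if not np.all(np.isfinite(cph.params_.values)):
        return None
    return cph


def cox_stepwise(
    records: pd.DataFrame,
    candidates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
) -> StepwiseCoxResult:
    """Bidirectional stepwise Cox model selection by AIC.

    Starts from the full model over ``candidates`` and repeatedly takes
    the single covariate addition or removal that most lowers the
    partial-likelihood AIC, stopping when no move improves it. Ties are
    handled by Efron's approximation (the lifelines default). Covariates
    whose single-covariate fit fails (non-convergence, separation) are
    flagged and excluded from the search rather than raising.
    """
    if records[event_col].sum() < 10:
        raise StatsError("stepwise Cox needs at least 10 events")
    df = records.dropna(subset=[time_col, event_col] + list(candidates)).copy()

    failed = []
    usable = []
    for cov in candidates:
        if df[cov].nunique() < 2:
            failed.append(cov)
            continue
        if _fit_cox(df, [cov], time_col, event_col) is None:
            failed.append(cov)
        else:
            usable.append(cov)

    null_ll = _null_partial_loglik(
        df[time_col].to_numpy(float), df[event_col].to_numpy(float)
    )
    null_aic = -2.0 * null_ll

    def aic_of(covs: list[str]) -> tuple[float, CoxPHFitter | None]:
        if not covs:
            return null_aic, None
        fit = _fit_cox(df, covs, time_col, event_col)
        if fit is None:
            return np.inf, None
        return float(fit.AIC_partial_), fit

    current = list(usable)
    current_aic, current_fit = aic_of(current)
    if not np.isfinite(current_aic):
        current, current_aic, current_fit = [], null_aic, None

    while True:
        moves: list[tuple[float, list[str]]] = []
        for cov in current:
            covs = [c for c in current if c != cov]
            moves.append((aic_of(covs)[0], covs))
        for cov in usable:
            if cov not in current:
                covs = current + [cov]
                moves.append((aic_of(covs)[0], covs))
        if not moves:
            break
        best_aic, best_covs = min(moves, key=lambda m: m[0])
        if best_aic < current_aic - 1e-9:
            current, current_aic = best_covs, best_aic
            current_fit = aic_of(current)[1]
        else:
            break

    if current_fit is not None:
        s = current_fit.summary
        summary = pd.DataFrame(
            {
                "HR": s["exp(coef)"],
                "HR_lower95": s["exp(coef) lower 95%"],
                "HR_upper95": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )
    else:
        summary = pd.DataFrame(columns=["HR", "HR_lower95", "HR_upper95", "p"])
    return StepwiseCoxResult(
        selected=list(current),
        summary=summary,
        aic=float(current_aic),
        failed=failed,
        model=current_fit,
    )
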