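"""Cohort inference for tsRNA biomarkers.

The analyses mirror a standard small-RNA biomarker workflow:

* paired/unpaired differential expression on log2 expression with an
  empirical-Bayes moderated t-statistic (limma-style variance
  shrinkage), gated at |log2FC| > 1 and p < 0.05;
* median split of tumor samples into low/high expression groups;
* Kaplan-Meier product-limit curves and the two-group log-rank test;
* Cox proportional-hazards regression (Breslow ties, Newton-Raphson),
  univariate sweep and joint multivariate modes;
* Pearson chi-square association of expression groups with categorical
  pathology variables;
* Spearman correlation against an mRNA matrix with top-k selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Fits (d0, s0^2) such that s2 ~ s0^2 * F(df, d0), by matching the mean
    and variance of log(s2) (the log of a chi-square has known digamma/
    trigamma moments).  Returns ``d0 = inf`` when the observed spread of
    log-variances is no wider than chi-square sampling alone explains.
    Non-positive variances are excluded from the fit (they still get
    shrunk toward the prior afterwards).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # spread no wider than chi-square sampling: infinite prior df, and
        # the prior scale MLE is then the arithmetic mean of the variances
        d0 = np.inf
        s0_sq = float(np.mean(s2[ok]))
    return d0, s0_sq


def _resolve_pairing(design: pd.DataFrame, paired) -> bool:
    """Decide paired vs unpaired; degrade to unpaired on incomplete pairing."""
    if paired is False:
        return False
    has_pairs = "pair_id" in design.columns and design["pair_id"].notna().all()
    complete = False
    if has_pairs:
        counts = design.groupby("pair_id")["group"].agg(["size", "nunique"])
        complete = bool(((counts["size"] == 2) & (counts["nunique"] == 2)).all())
    if paired is True and not complete:
        logger.warning("pair_ids incomplete; degrading to unpaired analysis")
        return False
    if paired == "auto":
        return complete
    return bool(paired)


def differential_expression(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
    paired="auto",
    method: str = "ebayes",
) -> pd.DataFrame:
    """Tumor-vs-normal contrast per signature with moderated t.

    ``expr`` is signatures x samples on the log2 scale; ``design`` is
    indexed by sample id with a ``group`` column in {tumor, normal} and
    an optional ``pair_id``.  The significance gate is strict:
    |log2FC| > ``lfc_cut`` AND p < ``p_cut``.

    ``method='welch'`` swaps the shrunken statistic for a plain Welch t
    (one-sample t on pair differences when paired), used for
    cross-validation of the moderated path.
    """
    design = design.loc[design.index.intersection(expr.columns)]
    tumor = design.index[design["group"] == "tumor"]
    normal = design.index[design["group"] == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need >= 2 samples per group for differential expression")

    use_paired = _resolve_pairing(design, paired)
    if use_paired:
        pairs = design.groupby("pair_id").groups
        t_cols, n_cols = [], []
        for _, idx in sorted(pairs.items()):
            sub = design.loc[idx]
            t_cols.append(sub.index[sub["group"] == "tumor"][0])
            n_cols.append(sub.index[sub["group"] == "normal"][0])
        diffs = expr[t_cols].to_numpy() - expr[n_cols].to_numpy()
        n = diffs.shape[1]
        lfc = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        df_resid = n - 1
        scale = 1.0 / np.sqrt(n)
    else:
        xt = expr[list(tumor)].to_numpy()
        xn = expr[list(normal)].to_numpy()
        n1, n2 = xt.shape[1], xn.shape[1]
        lfc = xt.mean(axis=1) - xn.mean(axis=1)
        v1 = xt.var(axis=1, ddof=1)
        v2 = xn.var(axis=1, ddof=1)
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df_resid = n1 + n2 - 2
        scale = np.sqrt(1.0 / n1 + 1.0 / n2)

    if method == "ebayes":
        d0, s0_sq = fit_variance_prior(s2, df_resid)
        # total df capped at the pooled residual df across all signatures
        df_pooled = len(s2) * df_resid
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = df_pooled
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = min(d0 + df_resid, df_pooled)
        tstat = lfc / (np.sqrt(s2_post) * scale)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    elif method == "welch":
        if use_paired:
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = lfc / (np.sqrt(s2) * scale)
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_resid)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(v1 / n1 + v2 / n2)
                tstat = lfc / se
                df_w = se**4 / (
                    (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
                )
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_w)
        bad = ~np.isfinite(tstat)
        if bad.any():
            logger.warning("%d zero-variance signatures: p set to NA", bad.sum())
            pvals = np.where(bad, np.nan, pvals)
        d0, s0_sq = np.nan, np.nan
    else:
        raise ValueError(f"unknown method {method!r}")

    finite = np.isfinite(pvals)
    qvals = np.full_like(pvals, np.nan)
    if finite.any():
        qvals[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": tstat,
            "p": pvals,
            "q": qvals,
            "significant": (np.abs(lfc) > lfc_cut) & (pvals < p_cut),
        },
        index=expr.index,
    )
    out.attrs.update(
        paired=use_paired, d0=d0, s0_sq=s0_sq, df_resid=df_resid, method=method
    )
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def median_split(values: pd.Series) -> pd.Series:
    """Dichotomize at the median: value <= median -> 'low', else 'high'."""
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("median split needs >= 2 samples")
    med = values.median()
    labels = np.where(values <= med, "low", "high")
    if len(set(labels)) < 2:
        raise ValueError("degenerate median split: all values on one side")
    return pd.Series(labels, index=values.index, name="expression_group")


@dataclass
class KMCurve:
    """Product-limit estimate: event-time grid, S(t) and at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator with right censoring.

    The grid contains the distinct observed event times; with no events
    the curve is flat at 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    grid, surv, risk, devents = [], [], [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        grid.append(t)
        surv.append(s)
        risk.append(n_at_risk)
        devents.append(d)
    return KMCurve(
        np.asarray(grid), np.asarray(surv), np.asarray(risk, int), np.asarray(devents, int)
    )


@dataclass
class LogRankResult:
    groups: tuple[str, str]
    observed: np.ndarray   # O_g per group
    expected: np.ndarray   # E_g per group
    variance: float
    statistic: float
    p_value: float


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test (hypergeometric O-E sum, chi-square 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels}")
    if events.sum() == 0:
        raise ValueError("log-rank undefined with no events")
    g1 = groups == labels[0]

    O = np.zeros(2)
    E = np.zeros(2)
    V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        ev = (times == t) & (events == 1)
        d = ev.sum()
        d1 = (ev & g1).sum()
        O += (d1, d - d1)
        e1 = d * n1 / n
        E += (e1, d - e1)
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = (O[0] - E[0]) ** 2 / V
    return LogRankResult(
        groups=(str(labels[0]), str(labels[1])),
        observed=O,
        expected=E,
        variance=float(V),
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df=1)),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxModel:
    table: pd.DataFrame | None
    log_likelihood: float
    converged: bool
    n: int
    n_events: int


def _encode_covariates(
    cov: pd.DataFrame, reference_levels: dict[str, str] | None
) -> pd.DataFrame:
    """Dummy-encode categorical columns against a stated reference level."""
    reference_levels = reference_levels or {}
    parts = []
    for col in cov.columns:
        s = cov[col]
        if s.dtype.kind in "biufc":
            parts.append(s.astype(float).to_frame(col))
        else:
            levels = sorted(s.astype(str).unique())
            ref = str(reference_levels.get(col, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {col}")
            for lvl in levels:
                if lvl == ref:
                    continue
                parts.append(
                    (s.astype(str) == lvl).astype(float).to_frame(f"{col}[{lvl} vs {ref}]")
                )
    X = pd.concat(parts, axis=1)
    const = X.columns[X.std(axis=0) == 0]
    if len(const):
        raise ValueError(f"constant covariate(s): {list(const)}")
    return X


def _breslow_quantities(beta, X, time, event):
    """Breslow partial log-likelihood, score and information matrix."""
    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    Xo, to, eo = X[order], time[order], event[order]
    eta = Xo @ beta
    eta = eta - eta.max()  # overflow guard; cancels in all ratios below
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * Xo, axis=0)
    s2 = np.cumsum(w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(X.shape[1])
    info = np.zeros((X.shape[1], X.shape[1]))
    i = 0
    n = len(to)
    while i < n:
        j = i
        while j + 1 < n and to[j + 1] == to[i]:
            j += 1
        ev = eo[i : j + 1] == 1
        d = int(ev.sum())
        if d:
            idx = j  # risk set = everyone with time >= to[i]
            xbar = s1[idx] / s0[idx]
            ll += eta[i : j + 1][ev].sum() - d * np.log(s0[idx])
            grad += Xo[i : j + 1][ev].sum(axis=0) - d * xbar
            info += d * (s2[idx] / s0[idx] - np.outer(xbar, xbar))
        i = j + 1
    return ll, grad, info


def _fit_single(X, time, event, tol, max_iter):
    p = X.shape[1]
    beta = np.zeros(p)
    ll = -np.inf
    for _ in range(max_iter):
        ll, grad, info = _breslow_quantities(beta, X, time, event)
        if np.linalg.norm(grad) < tol:
            if np.abs(beta).max() > 10:
                # gradient vanished on a likelihood plateau at an extreme
                # coefficient: monotone likelihood / perfect separation
                return beta, None, ll, False
            cov = np.linalg.inv(info)
            return beta, cov, ll, True
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return beta, None, ll, False
        if not np.isfinite(step).all() or np.abs(beta + step).max() > 50:
            # monotone likelihood / separation: coefficients diverge
            return beta, None, ll, False
        beta = beta + step
    return beta, None, ll, False


def cox_fit(
    times,
    events,
    covariates: pd.DataFrame,
    mode: str = "multivariate",
    reference_levels: dict[str, str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> "CoxModel | dict[str, CoxModel]":
    """Cox proportional-hazards fit with Breslow tie handling.

    ``mode='multivariate'`` fits all covariates jointly; ``'univariate'``
    fits one model per original covariate (dummy groups kept together)
    and returns a dict keyed by covariate.  Wald tests and 95% CIs are
    reported per term; non-convergence or separation is flagged and no
    estimates are returned for that model.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if mode == "univariate":
        return {
            col: cox_fit(
                times, events, covariates[[col]],
                mode="multivariate", reference_levels=reference_levels,
                tol=tol, max_iter=max_iter,
            )
            for col in covariates.columns
        }

    X_df = _encode_covariates(covariates, reference_levels)
    if events.sum() < X_df.shape[1]:
        raise ValueError("fewer events than covariates")
    X = X_df.to_numpy(dtype=float)
    center = X.mean(axis=0)
    beta, cov, ll, ok = _fit_single(X - center, times, events, tol, max_iter)
    n, n_events = len(times), int(events.sum())
    if not ok or cov is None:
        logger.warning("Cox fit did not converge (possible separation)")
        return CoxModel(None, float(ll), False, n, n_events)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": se,
            "z": z,
            "p": p,
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
        },
        index=X_df.columns,
    )
    return CoxModel(table, float(ll), True, n, n_events)


# ---------------------------------------------------------------------------
# categorical association & correlation
# ---------------------------------------------------------------------------

def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table (no continuity
    correction).  Expected counts must all be positive."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected <= 0).any():
        raise ValueError("expected count of zero: merge sparse categories first")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def crosstab_expression_pathology(
    expr_group: pd.Series, pathology: pd.Series
) -> pd.DataFrame:
    """Contingency table of low/high expression vs a pathology category."""
    shared = expr_group.index.intersection(pathology.dropna().index)
    return pd.crosstab(expr_group.loc[shared], pathology.loc[shared])


def spearman_top_k(
    target: pd.Series, mrna_matrix: pd.DataFrame, k: int = 500
) -> pd.DataFrame:
    """Top-k mRNAs by |Spearman rho| against one tsRNA's expression.

    ``mrna_matrix`` is genes x samples.  rho is Pearson on average ranks;
    p uses the t approximation with n-2 df.  Sorted by |rho| (desc), then
    rho (desc), then gene id.
    """
    shared = target.index.intersection(mrna_matrix.columns)
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples for Spearman correlation")
    y = target.loc[shared].to_numpy(dtype=float)
    M = mrna_matrix[list(shared)].to_numpy(dtype=float)

    var_ok = M.std(axis=1) > 0
    if (~var_ok).any():
        logger.info("skipping %d zero-variance genes", int((~var_ok).sum()))
    genes = mrna_matrix.index[var_ok]
    M = M[var_ok]

    n = len(shared)
    ry = stats.rankdata(y)
    rM = np.apply_along_axis(stats.rankdata, 1, M)
    ry_c = ry - ry.mean()
    rM_c = rM - rM.mean(axis=1, keepdims=True)
    denom = np.sqrt((rM_c**2).sum(axis=1) * (ry_c**2).sum())
    rho = (rM_c @ ry_c) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(tstat), df=n - 2))

    out = pd.DataFrame({"gene": genes, "rho": rho, "p": p})
    out["_abs"] = out["rho"].abs()
    out = out.sort_values(
        ["_abs", "rho", "gene"], ascending=[False, False, True]
    ).drop(columns="_abs")
    if k > len(out):
        logger.warning("k=%d exceeds %d available genes; returning all", k, len(out))
    out = out.head(k).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
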