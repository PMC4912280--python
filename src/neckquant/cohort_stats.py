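"""Cohort-level statistics: agreement, correlation, stratification, survival.

Interobserver agreement between two readers of the same volumetric quantity
is summarised by Bland–Altman bias / limits of agreement and by the
intraclass correlation for absolute agreement in its two-way random,
single-measures form ICC(A,1) (McGraw & Wong), computed from the two-way
ANOVA mean squares

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))

with n subjects and k raters.  Nonparametric correlation and group
comparison use Spearman's rho, Mann–Whitney U (2 groups), and
Kruskal–Wallis (>= 3 groups).  Survival is compared between the upper
quartile of the NAT:AWV ratio and the lower three quartiles with
Kaplan–Meier curves and the log-rank test, and quantified by a Cox
proportional-hazards model whose partial likelihood (Breslow tie handling)
is maximised by Newton iteration in this module.  All tests are two-sided;
alpha = 0.05 is reported but never suppresses output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    ConvergenceError,
    DegenerateDataError,
    InputError,
    SampleError,
    SchemaError,
)

ALPHA = 0.05
MAX_FOLLOWUP_DAYS = 670.0

BMI_CUTOFFS = (25.0, 30.0)
BMI_CATEGORIES = ("normal_or_under", "overweight", "obese")


# ---------------------------------------------------------------------------
# observer agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverPairSet:
    """Paired measurements (cc) of the same subjects by two observers."""

    subject_ids: tuple
    obs1: np.ndarray
    obs2: np.ndarray

    def __post_init__(self):
        o1 = np.asarray(self.obs1, dtype=float)
        o2 = np.asarray(self.obs2, dtype=float)
        if o1.shape != o2.shape or o1.ndim != 1:
            raise InputError("observer arrays must be equal-length 1-D")
        if not (np.all(np.isfinite(o1)) and np.all(np.isfinite(o2))):
            raise InputError("observer values must be finite")
        object.__setattr__(self, "obs1", o1)
        object.__setattr__(self, "obs2", o2)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    def __len__(self):
        return len(self.obs1)

    @classmethod
    def from_csv(cls, path) -> "ObserverPairSet":
        df = pd.read_csv(path)
        missing = {"subject_id", "obs1", "obs2"} - set(df.columns)
        if missing:
            raise SchemaError(missing, f"observer-pair CSV missing columns: {sorted(missing)}")
        return cls(tuple(df["subject_id"]), df["obs1"].to_numpy(), df["obs2"].to_numpy())


@dataclass
class AgreementResult:
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    icc_p: float | None = None
    bias: float | None = None
    bias_sd: float | None = None
    loa: tuple[float, float] | None = None
    fixed_bias_p: float | None = None
    pct_discrepancy: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("icc_ci", "loa"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def _two_way_mean_squares(o1: np.ndarray, o2: np.ndarray):
    """Mean squares of the n-subjects x 2-raters two-way layout."""
    data = np.column_stack([o1, o2])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_absolute_agreement(pairs: ObserverPairSet, alpha: float = ALPHA) -> AgreementResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    The 95% CI follows McGraw & Wong's F-based construction.  When the table
    is fully degenerate (every value identical) the ICC is reported as 1 by
    convention, with a degenerate (1, 1) interval.
    """
    if len(pairs) < 3:
        raise SampleError(f"ICC needs >= 3 subjects, got {len(pairs)}")
    msr, msc, mse, n, k = _two_way_mean_squares(pairs.obs1, pairs.obs2)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        # all values identical across subjects and raters
        warnings.warn("degenerate agreement table: all values identical; ICC = 1 by convention")
        return AgreementResult(icc=1.0, icc_ci=(1.0, 1.0), icc_p=0.0, n=n)
    icc = (msr - mse) / denom

    if mse == 0.0:
        return AgreementResult(icc=float(icc), icc_ci=(1.0, 1.0), icc_p=0.0, n=n)

    r = icc
    a = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
    b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = 1.0
    fobs = msr / mse
    icc_p = float(stats.f.sf(fobs, n - 1.0, (n - 1.0) * (k - 1.0)))
    return AgreementResult(
        icc=float(icc), icc_ci=(float(lower), float(upper)), icc_p=icc_p, n=n
    )


def bland_altman(pairs: ObserverPairSet) -> AgreementResult:
    """Bias, SD of differences, 1.96-SD limits of agreement, fixed-bias t-test.

    Degenerate conventions (documented): with zero-variance differences the
    one-sample t statistic is undefined, so fixed_bias_p = 1 when the bias is
    exactly 0 and 0 otherwise.
    """
    if len(pairs) < 2:
        raise SampleError(f"Bland-Altman needs >= 2 subjects, got {len(pairs)}")
    d = pairs.obs1 - pairs.obs2
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if sd == 0.0:
        p = 1.0 if bias == 0.0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    grand_mean = float(np.mean(np.concatenate([pairs.obs1, pairs.obs2])))
    pct = 100.0 * abs(bias) / grand_mean if grand_mean != 0 else math.nan
    return AgreementResult(
        bias=bias, bias_sd=sd, loa=loa, fixed_bias_p=p, pct_discrepancy=pct, n=len(pairs)
    )


def agreement_analysis(pairs: ObserverPairSet) -> AgreementResult:
    """Full agreement block: ICC(A,1) plus Bland–Altman on one pair set."""
    icc_part = icc_absolute_agreement(pairs)
    ba_part = bland_altman(pairs)
    return AgreementResult(
        icc=icc_part.icc,
        icc_ci=icc_part.icc_ci,
        icc_p=icc_part.icc_p,
        bias=ba_part.bias,
        bias_sd=ba_part.bias_sd,
        loa=ba_part.loa,
        fixed_bias_p=ba_part.fixed_bias_p,
        pct_discrepancy=ba_part.pct_discrepancy,
        n=len(pairs),
    )


def bland_altman_plot(pairs: ObserverPairSet, path) -> None:
    """Write a Bland–Altman scatter (mean vs difference) with bias and LoA."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    means = (pairs.obs1 + pairs.obs2) / 2.0
    diffs = pairs.obs1 - pairs.obs2
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=14, alpha=0.7)
    ax.axhline(res.bias, color="k", label=f"bias = {res.bias:.2f}")
    for v in res.loa:
        ax.axhline(v, color="k", linestyle="--")
    ax.set_xlabel("mean of observers (cc)")
    ax.set_ylabel("difference (cc)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# correlation, categorisation, group comparison
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D")
    if len(x) < 3:
        raise SampleError("Spearman needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("zero rank variance: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bmi_category(bmi: float) -> str:
    """WHO class from BMI: < 25 normal/under, [25, 30) overweight, >= 30 obese."""
    if bmi <= 0:
        raise InputError(f"BMI must be positive, got {bmi}")
    if bmi < BMI_CUTOFFS[0]:
        return BMI_CATEGORIES[0]
    if bmi < BMI_CUTOFFS[1]:
        return BMI_CATEGORIES[1]
    return BMI_CATEGORIES[2]


def describe_categorical(values) -> list[dict]:
    """Frequency and percentage (1 dp) per level, in order of appearance."""
    values = list(values)
    n = len(values)
    if n == 0:
        raise SampleError("empty categorical variable")
    out = []
    seen = {}
    for v in values:
        seen[v] = seen.get(v, 0) + 1
    for level, count in seen.items():
        out.append({"level": level, "count": count, "pct": round(100.0 * count / n, 1)})
    return out


def group_compare(values, groups) -> dict:
    """Rank-based group comparison: Mann–Whitney U (2) or Kruskal–Wallis (>=3).

    Tie-corrected.  When every observation is identical the statistic is 0
    and p = 1 by convention (the rank tests are undefined at zero variance).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise InputError("group comparison needs >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise InputError("every group needs n >= 1")
    if np.all(values == values[0]):
        test = "mann_whitney_u" if len(levels) == 2 else "kruskal_wallis"
        return {"test": test, "statistic": 0.0, "p": 1.0, "groups": list(map(str, levels))}
    if len(levels) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return {
            "test": "mann_whitney_u",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "groups": list(map(str, levels)),
        }
    res = stats.kruskal(*samples)
    return {
        "test": "kruskal_wallis",
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "groups": list(map(str, levels)),
    }


def top_quartile_split(ratios) -> tuple[np.ndarray, float]:
    """Labels {upper_quartile, lower_three} against the 75th percentile.

    The threshold uses the linear-interpolation quantile; values >= threshold
    fall in the upper group.  If all values are equal the split is degenerate
    (everything "upper") and a warning is issued.
    """
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) < 4:
        raise SampleError("quartile split needs n >= 4")
    threshold = float(np.percentile(ratios, 75.0))
    labels = np.where(ratios >= threshold, "upper_quartile", "lower_three")
    if np.all(labels == "upper_quartile"):
        warnings.warn("degenerate quartile split: all values in the upper group")
    return labels, threshold


# ---------------------------------------------------------------------------
# survival: Kaplan-Meier, log-rank, Cox (Breslow / Newton)
# ---------------------------------------------------------------------------

def logrank_statistic(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the pooled risk set; the
    statistic is (sum of O-E)^2 / (sum of variances).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise InputError(f"log-rank compares exactly 2 groups, got {len(levels)}")
    if events.sum() == 0:
        raise DegenerateDataError("no events: log-rank test undefined")
    g1 = groups == levels[0]
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var_sum = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        dead = (times == t) & (events == 1)
        d = dead.sum()
        d1 = (dead & g1).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var_sum += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var_sum == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var_sum
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_logrank(times, events, groups) -> dict:
    """Kaplan–Meier curves per group plus the log-rank comparison.

    Non-events are right-censored at their follow-up time (administratively
    bounded by the cohort's maximum follow-up).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise InputError("follow-up times must be >= 0")
    levels = pd.unique(groups)
    curves = {}
    for g in levels:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[str(g)] = {
            "t": [float(v) for v in sf.index],
            "s": [float(v) for v in sf.iloc[:, 0]],
            "n": int(sel.sum()),
            "events": int(events[sel].sum()),
        }
    chi2, p = logrank_statistic(times, events, groups)
    return {"curves": curves, "logrank_chi2": chi2, "logrank_p": p}


def km_plot(times, events, groups, path) -> None:
    """Write Kaplan–Meier step curves per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = km_logrank(times, events, groups)
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, c in rep["curves"].items():
        ax.step(c["t"], c["s"], where="post", label=f"{name} (n={c['n']})")
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"log-rank p = {rep['logrank_p']:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cox_partial_loglik(times, events, X, beta) -> float:
    """Breslow partial log-likelihood at a given coefficient vector."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        at_risk = times >= t
        ll += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[at_risk]).sum())
    return float(ll)


def _cox_newton(times, events, X, max_iter=60, tol=1e-10):
    """Newton–Raphson maximiser of the Breslow partial likelihood.

    Returns (beta, covariance, loglik).  Risk-set sums are accumulated by
    cumulative sums over descending time, with tied times sharing one risk
    set.  Step halving guards against overshoot; coefficients running away
    (monotone likelihood / perfect separation) raise ConvergenceError.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    n, p = X.shape

    order = np.argsort(-times, kind="stable")
    t_s, e_s, x_s = times[order], events[order], X[order]
    # index of the last row in each tie group = full risk set for that time
    grp_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        grp_end[i : j + 1] = j
        i = j + 1
    ev_idx = np.flatnonzero(e_s == 1)
    ge = grp_end[ev_idx]

    def ll_grad_hess(beta):
        eta = x_s @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w)
        s1 = np.cumsum(x_s * w[:, None], axis=0)
        xxw = x_s[:, :, None] * x_s[:, None, :] * w[:, None, None]
        s2 = np.cumsum(xxw, axis=0)
        s0_e, s1_e, s2_e = s0[ge], s1[ge], s2[ge]
        ll = float(eta[ev_idx].sum() - np.log(s0_e).sum())
        mean = s1_e / s0_e[:, None]
        grad = (x_s[ev_idx] - mean).sum(axis=0)
        hess = (
            s2_e / s0_e[:, None, None]
            - mean[:, :, None] * mean[:, None, :]
        ).sum(axis=0)
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = ll_grad_hess(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step halving until the likelihood does not decrease
        scale = 1.0
        for _half in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_hess = ll_grad_hess(new_beta)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.any(np.abs(beta) > 50):
            raise ConvergenceError(
                "coefficients diverging: monotone partial likelihood (perfect separation?)"
            )
        if np.max(np.abs(grad)) < tol:
            break
    else:
        if np.max(np.abs(grad)) > 1e-4:
            raise ConvergenceError("Cox Newton iteration did not converge")
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular information at optimum: {exc}") from exc
    return beta, cov, ll


@dataclass(frozen=True)
class SurvivalFit:
    """Cox model summary for one covariate of interest."""

    beta: float
    se: float
    hr: float
    hr_ci: tuple[float, float]
    p: float
    adjusted_for: tuple[str, ...] = ()
    ties: str = "breslow"
    n: int = 0
    n_events: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hr_ci"] = list(d["hr_ci"])
        d["adjusted_for"] = list(d["adjusted_for"])
        return d


def cox_univariate(times, events, covariate, adjusters: dict | None = None) -> SurvivalFit:
    """Cox proportional-hazards fit for one covariate, optionally adjusted.

    The Wald 95% CI and p refer to the covariate of interest (first column);
    ``adjusters`` maps names (e.g. "age", "sex") to covariate arrays that
    enter the linear predictor but are not themselves reported.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cov = np.asarray(covariate, dtype=float)
    if events.sum() < 1:
        raise InputError("Cox regression needs >= 1 event")
    if np.all(cov == cov[0]):
        raise InputError("covariate is constant; hazard ratio undefined")
    cols = [cov]
    names = []
    for name, arr in (adjusters or {}).items():
        cols.append(np.asarray(arr, dtype=float))
        names.append(name)
    X = np.column_stack(cols)
    beta, covm, _ = _cox_newton(times, events, X)
    b = float(beta[0])
    se = float(np.sqrt(covm[0, 0]))
    z = b / se

    def _sexp(x):  # Wald bounds can overflow when a group has no events
        return math.exp(x) if x < 709.0 else math.inf

    return SurvivalFit(
        beta=b,
        se=se,
        hr=_sexp(b),
        hr_ci=(_sexp(b - 1.96 * se), _sexp(b + 1.96 * se)),
        p=float(2.0 * stats.norm.sf(abs(z))),
        adjusted_for=tuple(names),
        n=len(times),
        n_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# ICC sample-size planning
# ---------------------------------------------------------------------------

def icc_sample_size(
    target_icc: float,
    ci_width: float,
    ratings_per_subject: int = 2,
    alpha: float = ALPHA,
    max_n: int = 100_000,
) -> dict:
    """Smallest n whose expected 95% CI width for the ICC is <= ci_width.

    The expected interval uses the F-based construction: at the target ICC
    the expected rater-adjusted F is (1 + (k-1) rho) / (1 - rho) with
    (n-1, (n-1)(k-1)) degrees of freedom, and the interval endpoints are the
    F bounds mapped back through (F - 1) / (F + k - 1).
    """
    if not 0.0 < target_icc < 1.0:
        raise InputError("target ICC must be in (0, 1)")
    if ci_width <= 0:
        raise InputError("CI width must be > 0")
    k = int(ratings_per_subject)
    if k < 2:
        raise InputError("need >= 2 ratings per subject")
    f_exp = (1.0 + (k - 1) * target_icc) / (1.0 - target_icc)
    for n in range(4, max_n + 1):
        df1 = n - 1
        df2 = (n - 1) * (k - 1)
        f_lo = f_exp / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_hi = f_exp * stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (f_lo - 1.0) / (f_lo + k - 1.0)
        upper = (f_hi - 1.0) / (f_hi + k - 1.0)
        if upper - lower <= ci_width:
            return {
                "n": n,
                "method": "f-based expected CI width",
                "target_icc": target_icc,
                "ci_width": ci_width,
                "ratings_per_subject": k,
            }
    raise InputError("no feasible n found (CI width target too tight)")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _event_prob(lam0, z, log_hr, c_lo, c_hi):
    """P(event) with exponential hazards and Uniform(c_lo, c_hi) censoring."""
    lam = lam0 * np.exp(log_hr * z)
    # E_C[1 - exp(-lam C)] with C ~ U(c_lo, c_hi)
    with np.errstate(over="ignore"):
        surv = (np.exp(-lam * c_lo) - np.exp(-lam * c_hi)) / (lam * (c_hi - c_lo))
    return float(np.mean(1.0 - surv))


def simulate_survival(
    z,
    log_hr: float,
    target_event_frac: float,
    rng: np.random.Generator,
    censor_range: tuple[float, float] = (250.0, MAX_FOLLOWUP_DAYS),
):
    """Exponential survival with planted log hazard ratio on covariate z.

    The baseline hazard is solved (Brent root find) so the expected event
    fraction under Uniform censoring matches ``target_event_frac`` for the
    covariate values actually drawn; follow-up is right-censored at the
    per-subject censoring time.
    """
    z = np.asarray(z, dtype=float)
    c_lo, c_hi = censor_range
    lam0 = optimize.brentq(
        lambda l: _event_prob(l, z, log_hr, c_lo, c_hi) - target_event_frac,
        1e-10,
        10.0,
    )
    lam = lam0 * np.exp(log_hr * z)
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(c_lo, c_hi, size=len(z))
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events


COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "bmi",
    "bmi_category",
    "natv_cc",
    "awv_cc",
    "ratio",
    "followup_days",
    "died",
)


def simulate_cohort(
    n: int = 519,
    seed: int = 0,
    planted: str = "none",
    log_hr: float = 0.0,
    target_event_frac: float = 35.0 / 519.0,
) -> pd.DataFrame:
    """Synthetic cohort with covariate structure matching clinical neck CT.

    BMI and NATV share a latent factor (Spearman correlation ~0.66); AWV is
    independent of BMI; the NAT:AWV ratio is their quotient.  Survival is
    exponential with a hazard planted on nothing ("none"), on the ratio per
    unit ("ratio"), or on upper-quartile membership ("quartile").
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n)
    bmi = np.clip(27.5 + 5.5 * (0.82 * u + math.sqrt(1 - 0.82**2) * rng.normal(size=n)), 16, 55)
    natv = np.clip(660 + 266 * (0.82 * u + math.sqrt(1 - 0.82**2) * rng.normal(size=n)), 60, None)
    awv = np.clip(rng.normal(23.6, 8.1, size=n), 5.0, None)
    ratio = natv / awv
    age = np.clip(rng.normal(57.0, 18.0, size=n), 18, 95)
    sex = rng.choice(["male", "female"], size=n, p=[0.548, 0.452])

    if planted == "none":
        z = np.zeros(n)
        b = 0.0
    elif planted == "ratio":
        z = ratio
        b = log_hr
    elif planted == "quartile":
        labels, _ = top_quartile_split(ratio)
        z = (labels == "upper_quartile").astype(float)
        b = log_hr
    else:
        raise InputError(f"unknown planted effect {planted!r}")
    times, events = simulate_survival(z, b, target_event_frac, rng)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "bmi": np.round(bmi, 1),
            "bmi_category": [bmi_category(b_) for b_ in bmi],
            "natv_cc": np.round(natv, 2),
            "awv_cc": np.round(awv, 2),
            "ratio": natv / awv,
            "followup_days": np.round(times, 1),
            "died": events,
        }
    )


def attach_followup(results: pd.DataFrame, seed: int = 0, log_hr: float = 0.0,
                    target_event_frac: float = 35.0 / 519.0) -> pd.DataFrame:
    """Extend a per-scan measurement table into a full cohort table.

    Adds demographics and simulated follow-up keyed to the measured NATV
    (BMI correlates with measured fat volume), for pipelines whose scans are
    phantoms rather than patients.
    """
    df = results.copy().reset_index(drop=True)
    n = len(df)
    rng = np.random.default_rng(seed)
    natv_std = (df["natv_cc"] - df["natv_cc"].mean()) / max(df["natv_cc"].std(ddof=0), 1e-9)
    bmi = np.clip(27.5 + 5.5 * (0.8 * natv_std + 0.6 * rng.normal(size=n)), 16, 55)
    df["age"] = np.round(np.clip(rng.normal(57.0, 18.0, size=n), 18, 95), 1)
    df["sex"] = rng.choice(["male", "female"], size=n, p=[0.548, 0.452])
    df["bmi"] = np.round(bmi, 1)
    df["bmi_category"] = [bmi_category(b) for b in bmi]
    z = df["ratio"].to_numpy() if log_hr != 0.0 else np.zeros(n)
    times, events = simulate_survival(z, log_hr, target_event_frac, rng)
    df["followup_days"] = np.round(times, 1)
    df["died"] = events
    return df


# ---------------------------------------------------------------------------
# full cohort analysis
# ---------------------------------------------------------------------------

def _median_iqr(x) -> dict:
    x = np.asarray(x, dtype=float)
    return {
        "median": float(np.median(x)),
        "iqr": [float(np.percentile(x, 25)), float(np.percentile(x, 75))],
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "n": int(len(x)),
    }


def run_cohort_analysis(
    cohort: pd.DataFrame, pairs: ObserverPairSet | None = None
) -> dict:
    """The complete cohort report as one nested, JSON-serialisable dict.

    Blocks: descriptives (counts/percentages, distribution summaries),
    observer agreement (when pairs are given), Spearman correlations of NATV
    and AWV with BMI (and with the NCSAs when measured), NATV/AWV across WHO
    BMI classes, the NAT:AWV quartile split, Kaplan–Meier + log-rank for
    upper quartile vs the rest, and crude plus age/sex-adjusted Cox models
    for the ratio (per unit) and for upper-quartile membership.
    """
    required = {"patient_id", "age", "sex", "bmi", "natv_cc", "awv_cc", "ratio",
                "followup_days", "died"}
    missing = required - set(cohort.columns)
    if missing:
        raise SchemaError(missing)
    df = cohort.copy()
    if "bmi_category" not in df.columns:
        df["bmi_category"] = [bmi_category(b) for b in df["bmi"]]

    report: dict = {"alpha": ALPHA, "n": int(len(df))}
    report["descriptives"] = {
        "sex": describe_categorical(df["sex"]),
        "bmi_category": describe_categorical(df["bmi_category"]),
        "natv_cc": _median_iqr(df["natv_cc"]),
        "awv_cc": _median_iqr(df["awv_cc"]),
        "ratio": _median_iqr(df["ratio"]),
        "age": _median_iqr(df["age"]),
    }

    if pairs is not None:
        report["agreement"] = agreement_analysis(pairs).to_dict()

    corr = {}

    def _corr(name, x, y):
        try:
            rho, p = spearman_rho(x, y)
            corr[name] = {"rho": rho, "p": p}
        except DegenerateDataError:
            corr[name] = {"rho": None, "p": None, "note": "zero rank variance"}

    _corr("natv_vs_bmi", df["natv_cc"], df["bmi"])
    _corr("awv_vs_bmi", df["awv_cc"], df["bmi"])
    for col, name in (("ncsa_upper_mm2", "natv_vs_ncsa_upper"),
                      ("ncsa_lower_mm2", "natv_vs_ncsa_lower")):
        if col in df.columns:
            _corr(name, df["natv_cc"], df[col])
    report["correlations"] = corr

    by_cat = {
        cat: _median_iqr(df.loc[df["bmi_category"] == cat, "natv_cc"])
        for cat in BMI_CATEGORIES
        if (df["bmi_category"] == cat).any()
    }
    report["bmi_groups"] = {
        "natv_by_category": by_cat,
        "natv_test": group_compare(df["natv_cc"], df["bmi_category"]),
        "awv_test": group_compare(df["awv_cc"], df["bmi_category"]),
    }

    labels, threshold = top_quartile_split(df["ratio"].to_numpy())
    upper = labels == "upper_quartile"
    report["quartile"] = {
        "threshold": threshold,
        "n_upper": int(upper.sum()),
        "n_lower": int((~upper).sum()),
        "deaths_upper": int(df.loc[upper, "died"].sum()),
        "deaths_lower": int(df.loc[~upper, "died"].sum()),
    }

    times = df["followup_days"].to_numpy(dtype=float)
    events = df["died"].to_numpy(dtype=int)
    report["km_logrank"] = km_logrank(times, events, labels)

    sex_num = (df["sex"].astype(str).str.lower() == "male").astype(float).to_numpy()
    age_arr = df["age"].to_numpy(dtype=float)
    cox_block = {}
    for tag, covariate in (
        ("ratio_per_unit", df["ratio"].to_numpy(dtype=float)),
        ("upper_quartile", upper.astype(float)),
    ):
        cox_block[f"{tag}_crude"] = cox_univariate(times, events, covariate).to_dict()
        cox_block[f"{tag}_adjusted"] = cox_univariate(
            times, events, covariate, adjusters={"age": age_arr, "sex": sex_num}
        ).to_dict()
    report["cox"] = cox_block
    return report
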