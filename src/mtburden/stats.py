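"""Statistical engine: exact tests, ANOVA linear models, survival and ROC.

All routines are self-contained (numpy/scipy primitives only) so that each can
be checked against independent oracles: exhaustive enumeration for the Fisher
test, pairwise Mann-Whitney for the AUC, permutation for the log-rank test and
resampling for the DeLong variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .errors import (
    DegenerateLabelError,
    DegenerateTableError,
    GroupingError,
    InsufficientDataError,
    PairingError,
    RankDeficiencyError,
    StatsDomainError,
)

# ---------------------------------------------------------------------------
# exact contingency tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Exact integer enumeration of the hypergeometric support; the two-sided p
    sums the probabilities of all tables no more probable than the observed
    one (method of small p-values). Exact rational arithmetic, so there is no
    floating-point tie tolerance.
    """
    for x in (a, b, c, d):
        if not isinstance(x, (int, np.integer)) or x < 0:
            raise StatsDomainError(f"cell counts must be nonnegative integers, got {x!r}")
    n = a + b + c + d
    if n == 0:
        raise DegenerateTableError("all-zero 2x2 table")
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    # P(k) proportional to C(r1, k) * C(n - r1, c1 - k); integer weights
    weights = [math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    total = sum(weights)
    p_num = sum(w for w in weights if w <= w_obs)
    return min(1.0, p_num / total)


@dataclass(frozen=True)
class MonteCarloP:
    p: float
    se: float
    iterations: int


def fisher_exact_rxc(table, mc_iterations: int = 100_000, seed: int = 0):
    """Fisher exact test for an r x c table.

    2x2 tables delegate to :func:`fisher_exact_2x2` (returning a plain float);
    larger tables use seeded Monte Carlo over tables with fixed margins
    (Patefield sampling), returning a :class:`MonteCarloP` with its standard
    error. p = proportion of sampled tables whose probability is <= the
    observed table's probability (within float rounding).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise StatsDomainError("table must be a nonnegative 2-D integer array")
    if t.sum() == 0:
        raise DegenerateTableError("all-zero contingency table")
    if t.shape == (2, 2):
        return fisher_exact_2x2(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    rng = np.random.default_rng(seed)
    # log-probability of a table with fixed margins, up to a shared constant:
    # -sum(log(x_ij!))
    def neg_logfact(x):
        return -gammaln(np.asarray(x) + 1).sum(axis=(-2, -1))

    obs = neg_logfact(t)
    dist = sps.random_table(rows, cols)
    samples = dist.rvs(mc_iterations, random_state=rng)
    stat = neg_logfact(samples)
    hits = int((stat <= obs + 1e-9).sum())
    p = hits / mc_iterations
    se = math.sqrt(max(p * (1 - p), 1.0 / mc_iterations) / mc_iterations)
    return MonteCarloP(p=p, se=se, iterations=mc_iterations)


# ---------------------------------------------------------------------------
# linear model / multiple testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    r_squared: float
    n: int
    df_resid: int


def anova_linear(y, x) -> AnovaResult:
    """OLS of y on x with intercept; F-test of the slope on (1, n-2) df."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise StatsDomainError("x and y must be 1-D arrays of equal length")
    n = len(y)
    if n < 3:
        raise StatsDomainError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise RankDeficiencyError("predictor x is constant")
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    fitted = intercept + slope * x
    sse = ((y - fitted) ** 2).sum()
    sst = ((y - ybar) ** 2).sum()
    ssr = sst - sse
    df_resid = n - 2
    if sse <= 0:
        return AnovaResult(slope, intercept, math.inf, 0.0, 1.0, n, df_resid)
    f_stat = ssr / (sse / df_resid)
    p = float(sps.f.sf(f_stat, 1, df_resid))
    r2 = ssr / sst if sst > 0 else 0.0
    return AnovaResult(float(slope), float(intercept), float(f_stat), p, float(r2), n, df_resid)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m for a familywise level alpha over m tests."""
    if not 0 < alpha < 1:
        raise StatsDomainError(f"alpha must be in (0,1), got {alpha}")
    if m < 1:
        raise StatsDomainError(f"m must be >= 1, got {m}")
    return alpha / m


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KaplanMeierCurve:
    times: np.ndarray  # event times (steps)
    survival: np.ndarray  # S(t) immediately after each step
    at_risk: np.ndarray  # risk-set size just before each step


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    observed: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def km_estimate(times, events) -> KaplanMeierCurve:
    """Product-limit survival estimate.

    Censored observations shrink the risk set without producing steps.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise StatsDomainError("km_estimate requires at least one sample")
    if (times <= 0).any():
        raise StatsDomainError("survival times must be positive")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    surv, risk = [], []
    s = 1.0
    for t in uniq:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        risk.append(n_at_risk)
    return KaplanMeierCurve(
        times=uniq, survival=np.array(surv), at_risk=np.array(risk, dtype=int)
    )


def logrank_hr(times, events, groups, exposed=None) -> LogRankResult:
    """Two-group log-rank test with a Mantel-Haenszel hazard ratio.

    HR = exp((O1 - E1) / V) for the ``exposed`` group relative to the other,
    with 95% CI exp((O1 - E1)/V +/- 1.96/sqrt(V)). ``exposed`` defaults to the
    second group label in sorted order.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise GroupingError(f"need exactly two groups, got {labels}")
    if events.sum() < 1:
        raise GroupingError("need at least one event overall")
    if exposed is None:
        exposed = labels[1]
    if exposed not in labels:
        raise GroupingError(f"exposed label {exposed!r} not among groups {labels}")
    in1 = groups == exposed

    event_times = np.unique(times[events == 1])
    o1 = e1 = v = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d1 = int((dying & in1).sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        raise GroupingError("log-rank variance is zero (no informative event times)")
    chi2 = (o1 - e1) ** 2 / v
    p = float(sps.chi2.sf(chi2, 1))
    log_hr = (o1 - e1) / v
    hr = math.exp(log_hr)
    half = 1.96 / math.sqrt(v)
    observed = {lab: float(((groups == lab) & (events == 1)).sum()) for lab in labels}
    expected = {exposed: e1}
    other = labels[0] if exposed == labels[1] else labels[1]
    expected[other] = float(events.sum()) - e1
    return LogRankResult(
        chi_square=float(chi2),
        p_value=p,
        hazard_ratio=hr,
        ci_low=math.exp(log_hr - half),
        ci_high=math.exp(log_hr + half),
        observed=observed,
        expected=expected,
    )


def dichotomize_burden(n_snv: int, cutoff: int = 1) -> str:
    """'high' iff n_snv >= cutoff, else 'low'."""
    if n_snv < 0 or cutoff < 1:
        raise StatsDomainError(f"invalid n_snv={n_snv} or cutoff={cutoff}")
    return "high" if n_snv >= cutoff else "low"


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels).tolist()) - {0, 1}:
        raise StatsDomainError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise DegenerateLabelError("both label classes must be present")
    return labels


def roc_auc(scores, labels) -> RocResult:
    """Empirical ROC curve and Mann-Whitney AUC (ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if scores.shape != labels.shape:
        raise PairingError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    thresholds = np.concatenate(([math.inf], np.unique(scores)[::-1]))
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    # AUC via midranks (equivalent to the pairwise ties-at-1/2 oracle)
    ranks = sps.rankdata(scores)
    n1, n0 = len(pos), len(neg)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=float(auc),
    )


@dataclass(frozen=True)
class CombinedPredictor:
    coefficients: np.ndarray  # (intercept, beta_1, beta_2)
    scores: np.ndarray  # fitted linear predictor per patient
    converged: bool
    separation_fallback: bool


def combine_predictors(x1, x2, labels, tol: float = 1e-8, max_iter: int = 100) -> CombinedPredictor:
    """Logistic combination of two predictors by IRLS.

    The combined score is the fitted linear predictor. Constant predictors are
    dropped (they carry no information beyond the intercept). Under perfect
    separation the fit is abandoned and the score falls back to the rank sum
    of the standardized predictors.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = _check_labels(labels)
    n = len(y)
    if n < 10:
        raise StatsDomainError(f"need >= 10 patients, got {n}")
    if x1.shape != y.shape or x2.shape != y.shape:
        raise PairingError("predictors and labels must have equal length")

    cols = [np.ones(n)]
    used = []
    for j, xj in enumerate((x1, x2)):
        if np.ptp(xj) > 0:
            cols.append(xj)
            used.append(j)
    X = np.column_stack(cols)
    beta = np.zeros(X.shape[1])
    converged = False
    singular = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1 - mu)
        if w.max() < 1e-12:
            singular = True
            break
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        try:
            wx = X * w[:, None]
            beta_new = np.linalg.solve(X.T @ wx, X.T @ (w * z))
        except np.linalg.LinAlgError:
            singular = True
            break
        if not np.all(np.isfinite(beta_new)):
            singular = True
            break
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    separated = singular or np.max(np.abs(beta[1:])) > 25 if len(beta) > 1 else singular
    if separated:
        import warnings

        warnings.warn(
            "perfect separation in logistic combination; "
            "falling back to rank sum of standardized predictors",
            stacklevel=2,
        )
        score = np.zeros(n)
        for j, xj in enumerate((x1, x2)):
            if np.ptp(xj) > 0:
                score += (xj - xj.mean()) / xj.std()
        score = sps.rankdata(score)
        full = np.zeros(3)
        return CombinedPredictor(full, score, False, True)

    full = np.zeros(3)
    full[0] = beta[0]
    for k, j in enumerate(used):
        full[j + 1] = beta[k + 1]
    return CombinedPredictor(full, X @ beta, converged, False)


def delong_variance(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """(auc_a, auc_b, variance of the AUC difference) by DeLong's method."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _check_labels(labels)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise PairingError("paired scores must align with labels")

    def placements(s):
        pos, neg = s[y == 1], s[y == 0]
        # V10[i] = Pr(score_pos_i > score_neg) with ties at 1/2
        v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / len(neg) for p in pos])
        v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / len(pos) for q in neg])
        return v10, v01

    v10a, v01a = placements(sa)
    v10b, v01b = placements(sb)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    return float(v10a.mean()), float(v10b.mean()), float(var)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong comparison of two paired AUCs: returns (auc_a, auc_b, p).

    Placement values per positive/negative case give the empirical covariance
    of the paired AUC estimates; the AUC difference is tested against a
    two-sided normal reference.
    """
    auc_a, auc_b, var = delong_variance(scores_a, scores_b, labels)
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return auc_a, auc_b, p


# ---------------------------------------------------------------------------
# relapse classification
# ---------------------------------------------------------------------------

PSA_RELAPSE_THRESHOLD = 0.2  # ng/mL, two consecutive measurements above


def classify_relapse(record: dict) -> tuple[int, float]:
    """(event flag, event/censoring time in months) from a clinical record.

    Precedence: an explicit relapse flag wins; otherwise non-curative surgery
    (event at month 1), then two consecutive PSA measurements > 0.2 ng/mL
    (event at the month of the confirming measurement), then recorded
    metastasis or disease death; otherwise censored at the end of follow-up.
    """
    if record.get("relapse") is not None:
        flag = int(record["relapse"])
        if flag:
            t = record.get("relapse_month", record.get("follow_up_months"))
        else:
            t = record.get("follow_up_months")
        if t is None:
            raise InsufficientDataError("relapse flag present but no usable time")
        return flag, float(t)

    follow_up = record.get("follow_up_months")
    if record.get("non_curative"):
        return 1, 1.0
    psa = record.get("psa_series")
    if psa is not None:
        months = [m for m, _ in psa]
        values = [v for _, v in psa]
        for i in range(1, len(values)):
            if values[i] > PSA_RELAPSE_THRESHOLD and values[i - 1] > PSA_RELAPSE_THRESHOLD:
                return 1, float(months[i])
        if record.get("metastasis") or record.get("disease_death"):
            t = record.get("event_month", follow_up)
            if t is None:
                raise InsufficientDataError("metastasis/death flagged but no time")
            return 1, float(t)
        if follow_up is None:
            raise InsufficientDataError("PSA series without follow-up end")
        return 0, float(follow_up)
    if record.get("metastasis") or record.get("disease_death"):
        t = record.get("event_month", follow_up)
        if t is None:
            raise InsufficientDataError("metastasis/death flagged but no time")
        return 1, float(t)
    raise InsufficientDataError(
        "record carries neither a relapse flag nor a PSA series"
    )
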