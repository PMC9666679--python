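"""Survival and categorical statistics authored in-package.

Kaplan-Meier product-limit estimation, the two-group log-rank test,
univariate Cox proportional-hazards regression (Newton-Raphson on the Efron
partial likelihood, with the score test at beta = 0 used for feature
screening), inverse-probability-of-censoring-weighted time-dependent ROC/AUC
(cumulative cases / dynamic controls), a two-sided 2x2 Fisher's exact test by
full hypergeometric enumeration, and the clinical-covariate comparison table.

The Cox score test for a binary covariate coincides with the log-rank test in
the absence of ties, which is the identity the latent-feature screening rule
("univariate Cox-PH ... log-rank p-value") relies on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class SurvivalData:
    """Right-censored survival outcomes: positive times, 0/1 event flags."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if len(self.time) == 0:
            raise ValueError("empty survival data")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be > 0")
        if not np.all(np.isin(self.event, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        return SurvivalData(self.time[mask], self.event[mask])


@dataclass
class KMCurve:
    """Product-limit survival estimate: S(t) right-continuous step function."""

    times: np.ndarray        # distinct event times, sorted
    survival: np.ndarray     # S just after each event time
    at_risk: np.ndarray      # number at risk just before each event time
    n_events: np.ndarray     # deaths at each event time

    def survival_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """S(t); S = 1 before the first event time."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def survival_before(self, t: float | np.ndarray) -> np.ndarray | float:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[np.argmax(below)]) if below.any() else math.inf


@dataclass
class CoxFit:
    """Univariate Cox-PH fit: coefficient, SE, score/Wald tests."""

    beta: float
    se: float
    score_stat: float
    p_score: float
    p_wald: float
    n_iter: int


@dataclass
class TimeDepAUC:
    horizon: float
    auc: float
    n_cases: int
    n_controls: int
    estimator: str = "IPCW cumulative/dynamic"


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("all-zero contingency table")


def km_estimate(s: SurvivalData) -> KMCurve:
    """Kaplan-Meier estimator; censored times shrink risk sets without steps."""
    order = np.argsort(s.time, kind="stable")
    t, e = s.time[order], s.event[order]
    n = len(t)
    times, survival, at_risk, n_events = [], [], [], []
    surv = 1.0
    i = 0
    while i < n:
        tt = t[i]
        j = i
        deaths = 0
        while j < n and t[j] == tt:
            deaths += int(e[j])
            j += 1
        risk = n - i
        if deaths > 0:
            surv *= 1.0 - deaths / risk
            times.append(tt)
            survival.append(surv)
            at_risk.append(risk)
            n_events.append(deaths)
        i = j
    return KMCurve(
        np.asarray(times), np.asarray(survival), np.asarray(at_risk, dtype=int), np.asarray(n_events, dtype=int)
    )


def restricted_mean_survival(km: KMCurve, tau: float) -> float:
    """Area under the KM curve up to ``tau`` (restricted mean survival time)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s_val in zip(km.times, km.survival):
        if t >= tau:
            break
        area += (t - prev_t) * prev_s
        prev_t, prev_s = float(t), float(s_val)
    return area + (tau - prev_t) * prev_s


def logrank_test(s: SurvivalData, groups: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test with hypergeometric variance.

    Returns (chi-square statistic on 1 df, p-value). ``groups`` is a binary
    label vector aligned with ``s``.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two non-empty groups, got {len(labels)}")
    g1 = groups == labels[1]
    order = np.argsort(s.time, kind="stable")
    t, e, in1 = s.time[order], s.event[order], g1[order]
    n = len(t)
    O = E = V = 0.0
    i = 0
    while i < n:
        tt = t[i]
        j = i
        d = d1 = 0
        while j < n and t[j] == tt:
            d += int(e[j])
            d1 += int(e[j] and in1[j])
            j += 1
        if d > 0:
            n_risk = n - i
            n1 = int(in1[i:].sum())
            O += d1
            E += d * n1 / n_risk
            if n_risk > 1:
                V += d * (n1 / n_risk) * (1 - n1 / n_risk) * (n_risk - d) / (n_risk - 1)
        i = j
    if V == 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _efron_score_info(time: np.ndarray, event: np.ndarray, X: np.ndarray, eta: np.ndarray | None = None):
    """Score vector and information for each column of X under the Efron
    partial likelihood, evaluated at linear predictor ``eta`` per column
    (``None`` means beta = 0 for all columns). Vectorized over columns.

    Returns (U, I) arrays of shape (n_features,).
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t, e, Xs = time[order], event[order], X[order]
    if eta is None:
        w = np.ones((n, p))
    else:
        w = np.exp(Xs * eta[None, :])
    wx = w * Xs
    wxx = wx * Xs
    # suffix sums over the risk set (times >= t_i)
    S = np.cumsum(w[::-1], axis=0)[::-1]
    U1 = np.cumsum(wx[::-1], axis=0)[::-1]
    Q = np.cumsum(wxx[::-1], axis=0)[::-1]
    score = np.zeros(p)
    info = np.zeros(p)
    i = 0
    while i < n:
        tt = t[i]
        j = i
        while j < n and t[j] == tt:
            j += 1
        dead = np.arange(i, j)[e[i:j] == 1]
        d = len(dead)
        if d > 0:
            Sd = w[dead].sum(axis=0)
            Ud = wx[dead].sum(axis=0)
            Qd = wxx[dead].sum(axis=0)
            score += Xs[dead].sum(axis=0)
            for ell in range(d):
                f = ell / d
                Sl = S[i] - f * Sd
                Ul = U1[i] - f * Ud
                Ql = Q[i] - f * Qd
                score -= Ul / Sl
                info += Ql / Sl - (Ul / Sl) ** 2
        i = j
    return score, info


def cox_score_test(s: SurvivalData, X: np.ndarray) -> np.ndarray:
    """Score-test p-value per column of X at beta = 0 (Efron tie handling)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(s):
        X = X.T
    U, I = _efron_score_info(s.time, s.event, X)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(I > 0, U**2 / np.maximum(I, 1e-300), 0.0)
    return stats.chi2.sf(chi2, 1)


def cox_univariate(s: SurvivalData, x: np.ndarray, tol: float = 1e-9, max_iter: int = 50) -> CoxFit:
    """Univariate Cox-PH by Newton-Raphson on the Efron partial likelihood.

    The score test is evaluated at beta = 0; Wald uses the observed
    information at the maximiser.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: Cox coefficient is not identifiable")
    X = x[:, None]
    U0, I0 = _efron_score_info(s.time, s.event, X)
    score_stat = float(U0[0] ** 2 / I0[0]) if I0[0] > 0 else 0.0
    p_score = float(stats.chi2.sf(score_stat, 1))

    beta = 0.0
    for it in range(1, max_iter + 1):
        U, I = _efron_score_info(s.time, s.event, X, eta=np.array([beta]))
        if I[0] <= 0 or not np.isfinite(U[0]):
            raise RuntimeError("Cox information matrix not positive; fit diverged")
        step = U[0] / I[0]
        beta += step
        if abs(step) < tol:
            break
    else:
        raise RuntimeError(f"Cox Newton-Raphson did not converge in {max_iter} iterations")
    _, I_hat = _efron_score_info(s.time, s.event, X, eta=np.array([beta]))
    se = float(1.0 / np.sqrt(I_hat[0]))
    wald = (beta / se) ** 2
    return CoxFit(
        beta=float(beta),
        se=se,
        score_stat=score_stat,
        p_score=p_score,
        p_wald=float(stats.chi2.sf(wald, 1)),
        n_iter=it,
    )


def screen_features(values: np.ndarray, s: SurvivalData, alpha: float = 0.05) -> np.ndarray:
    """Indices of features whose univariate Cox score-test p < alpha.

    Constant features are skipped with a warning (their coefficient is not
    identifiable). ``values`` is samples x features.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(s):
        raise ValueError("feature matrix and survival data have different sample counts")
    const = np.ptp(values, axis=0) == 0
    if const.any():
        warnings.warn(f"skipping {int(const.sum())} constant feature(s) during Cox screening")
    p = np.ones(values.shape[1])
    if (~const).any():
        p[~const] = cox_score_test(s, values[:, ~const])
    return np.flatnonzero((p < alpha) & ~const)


def time_dependent_auc(score: np.ndarray, s: SurvivalData, horizon: float) -> TimeDepAUC:
    """Cumulative-case / dynamic-control AUC at ``horizon`` with IPCW.

    Cases: event observed at or before the horizon. Controls: observed time
    beyond the horizon. Weights come from the Kaplan-Meier estimate of the
    censoring distribution G: cases get 1/G(T-), controls 1/G(horizon).
    """
    score = np.asarray(score, dtype=float)
    if len(score) != len(s):
        raise ValueError("score and survival data have different lengths")
    if not (s.time.min() <= horizon <= s.time.max()):
        raise ValueError(f"horizon {horizon} outside the observed time range")
    cases = (s.time <= horizon) & (s.event == 1)
    controls = s.time > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError(
            f"time-dependent AUC undefined at horizon {horizon}: "
            f"{int(cases.sum())} cases, {int(controls.sum())} controls"
        )
    cens_km = km_estimate(SurvivalData(s.time, 1.0 - s.event))
    w_case = 1.0 / np.asarray(cens_km.survival_before(s.time[cases]))
    w_ctrl = np.full(int(controls.sum()), 1.0 / float(cens_km.survival_at(horizon)))
    sc_case = score[cases]
    sc_ctrl = score[controls]
    gt = (sc_case[:, None] > sc_ctrl[None, :]).astype(float)
    gt += 0.5 * (sc_case[:, None] == sc_ctrl[None, :])
    num = float((w_case[:, None] * w_ctrl[None, :] * gt).sum())
    den = float(w_case.sum() * w_ctrl.sum())
    return TimeDepAUC(
        horizon=float(horizon),
        auc=num / den,
        n_cases=int(cases.sum()),
        n_controls=int(controls.sum()),
    )


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by full hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table (exact integer
    arithmetic, so the <= comparison is exact).
    """
    a, b, c, d = int(t.a), int(t.b), int(t.c), int(t.d)
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    # numerator of P(k) at fixed denominator C(n, r1)
    num = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1)}
    obs = num[a]
    total = sum(num.values())  # == C(n, r1)
    assert total == math.comb(n, r1)
    p = sum(v for v in num.values() if v <= obs) / total
    return float(min(p, 1.0))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p (tie-corrected normal approximation)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass
class CovariateComparison:
    covariate: str
    kind: str                      # "categorical" | "continuous"
    p_value: float | None          # None when untestable
    n_used: int
    detail: dict = field(default_factory=dict)


def compare_clinical_covariates(clinical, labels) -> list[CovariateComparison]:
    """Table-1 style comparison of covariates between the K0 and K1 subgroups.

    Categorical covariates (two levels) use the exact Fisher test on the 2x2
    counts; continuous covariates use the Wilcoxon rank-sum test and report
    median (IQR) per group. Missing values are excluded per covariate; a
    covariate entirely missing in one group is flagged untestable.
    """
    from tallsurv.io_preprocess import CATEGORICAL_COVARIATES, CONTINUOUS_COVARIATES

    df = clinical.frame.loc[labels.sample_ids]
    lab = np.asarray(labels.labels)
    for g in (0, 1):
        if (lab == g).sum() < 2:
            raise ValueError("need at least two samples per subgroup")
    results: list[CovariateComparison] = []
    for col in df.columns:
        if col in ("time_days", "event"):
            continue
        vals = df[col]
        ok = vals.notna().to_numpy()
        kind = "categorical" if col.lower() in CATEGORICAL_COVARIATES or vals.dtype == object else "continuous"
        if (ok & (lab == 0)).sum() == 0 or (ok & (lab == 1)).sum() == 0:
            results.append(CovariateComparison(col, kind, None, int(ok.sum()), {"untestable": "covariate missing for an entire subgroup"}))
            continue
        v = vals[ok]
        g = lab[ok]
        if kind == "categorical":
            levels = sorted(v.unique().tolist())
            if len(levels) != 2:
                results.append(CovariateComparison(col, kind, None, int(ok.sum()), {"untestable": f"{len(levels)} levels, need 2"}))
                continue
            a = int(((v == levels[0]) & (g == 0)).sum())
            b = int(((v == levels[1]) & (g == 0)).sum())
            c = int(((v == levels[0]) & (g == 1)).sum())
            d = int(((v == levels[1]) & (g == 1)).sum())
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            results.append(CovariateComparison(col, kind, p, int(ok.sum()), {"counts": [[a, b], [c, d]], "levels": levels}))
        else:
            x0 = v[g == 0].to_numpy(dtype=float)
            x1 = v[g == 1].to_numpy(dtype=float)
            p = 1.0 if (np.ptp(np.concatenate([x0, x1])) == 0) else rank_sum_test(x0, x1)
            q = lambda a_: (float(np.median(a_)), float(np.percentile(a_, 25)), float(np.percentile(a_, 75)))
            results.append(
                CovariateComparison(col, kind, p, int(ok.sum()), {"median_iqr_k0": q(x0), "median_iqr_k1": q(x1)})
            )
    return results
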