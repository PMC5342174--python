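"""Prognostic-performance statistics on scores and censored outcomes.

Covers the full evaluation battery of a prognostic biomarker study:
ROC/AUC, Youden-index threshold selection with exact (Clopper-Pearson)
binomial confidence intervals and likelihood ratios, Harrell's
concordance on censored time-to-event data with a Somers'-D-based
confidence interval, Kaplan-Meier curves, Cox proportional-hazards
regression (Breslow ties) with a backwards step-down covariate
selection, nested logistic risk models, and the integrated
discrimination improvement (IDI) / net reclassification improvement
(NRI) statistics over the conventional <10% / 10-19% / >=20% ten-year
risk categories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from acspredict.errors import EvaluationError

__all__ = [
    "DiagnosticSummary",
    "ReclassReport",
    "YoudenResult",
    "cox_fit",
    "diagnostic_summary",
    "exact_binomial_ci",
    "harrell_c",
    "idi_nri",
    "km_estimate",
    "nested_logistic_models",
    "positive_likelihood_ratio",
    "roc_auc",
    "stepwise_cox",
    "youden_threshold",
]


# ---------------------------------------------------------------------------
# binary diagnostics


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Area under the ROC curve plus the trapezoidal curve table.

    Tied scores receive midpoint credit, so the AUC equals the
    Mann-Whitney U statistic divided by n1*n0.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise EvaluationError("ROC needs both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass(frozen=True)
class YoudenResult:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def youden_threshold(scores, labels) -> YoudenResult:
    """Threshold maximizing sensitivity + specificity - 1.

    A sample is test-positive when its score is strictly above the
    threshold.  Candidates are the midpoints between consecutive
    distinct scores; among maximizers the one with higher specificity
    wins, then the lower threshold.  If all scores are equal the result
    is degenerate with J = 0.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise EvaluationError("Youden threshold needs both classes")
    distinct = np.unique(s)
    if distinct.size == 1:
        return YoudenResult(float(distinct[0]), 0.0,
                            sensitivity=0.0, specificity=1.0,
                            degenerate=True)
    cand = (distinct[:-1] + distinct[1:]) / 2.0
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    best = None
    for t in cand:
        sens = float(((s > t) & (y == 1)).sum() / n1)
        spec = float(((s <= t) & (y == 0)).sum() / n0)
        j = sens + spec - 1.0
        key = (-j, -spec, t)
        if best is None or key < best[0]:
            best = (key, t, j, sens, spec)
    _, t, j, sens, spec = best
    return YoudenResult(float(t), float(j), float(sens), float(spec))


def exact_binomial_ci(successes: int, n: int,
                      conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval.

    ``lo = BetaInv(alpha/2; x, n-x+1)`` (0 when x = 0) and
    ``hi = BetaInv(1-alpha/2; x+1, n-x)`` (1 when x = n).
    """
    x, n = int(successes), int(n)
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid counts x={x}, n={n}")
    a = (1.0 - conf) / 2.0
    lo = 0.0 if x == 0 else float(stats.beta.ppf(a, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - a, x + 1, n - x))
    return lo, hi


def positive_likelihood_ratio(sensitivity: float,
                              specificity: float) -> float:
    """sensitivity / (1 - specificity); infinite at specificity 1."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if specificity == 1.0:
        return math.inf
    return sensitivity / (1.0 - specificity)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity at a threshold with exact 95% CIs."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    positive_likelihood_ratio: float

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "positive_likelihood_ratio": self.positive_likelihood_ratio,
        }


def diagnostic_summary(scores, labels, threshold: float,
                       conf: float = 0.95) -> DiagnosticSummary:
    """Confusion counts and CI-carrying diagnostics at one threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s > threshold
    tp = int((pos & (y == 1)).sum())
    fn = int((~pos & (y == 1)).sum())
    tn = int((~pos & (y == 0)).sum())
    fp = int((pos & (y == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise EvaluationError("diagnostics need both classes present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return DiagnosticSummary(
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens,
        sensitivity_ci=exact_binomial_ci(tp, tp + fn, conf),
        specificity=spec,
        specificity_ci=exact_binomial_ci(tn, tn + fp, conf),
        positive_likelihood_ratio=positive_likelihood_ratio(sens, spec),
    )


# ---------------------------------------------------------------------------
# censored-outcome statistics


def harrell_c(scores, time, event,
              conf: float = 0.95) -> tuple[float, tuple[float, float], int]:
    """Harrell's concordance index with a Somers'-D-based CI.

    Usable pairs are those whose ordering of event times is known under
    censoring: the member with the shorter observed time experienced an
    event (pairs with equal times are usable when exactly one member
    has an event, treating that member as the earlier one).  c is
    (concordant + 0.5 * score-tied) / usable.  The CI comes from the
    asymptotic variance of Somers' D (c = (D + 1) / 2) estimated by the
    per-subject cluster delta method.

    Returns ``(c, (lo, hi), n_usable_pairs)``.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    n = s.size
    # pairwise orientation: w = usable, r = +1 concordant / -1 discordant
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    ej = e[None, :]
    si, sj = s[:, None], s[None, :]
    earlier = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    w = earlier | earlier.T
    np.fill_diagonal(w, False)
    r = np.zeros((n, n))
    # concordant: earlier member has the higher score
    r[earlier & (si > sj)] = 1.0
    r[earlier & (si < sj)] = -1.0
    r = r + r.T  # symmetrize: orientation seen from each member
    usable = int(w.sum() // 2)
    if usable == 0:
        raise EvaluationError("no usable pairs (all comparisons censored)")
    conc = float(r[np.triu(w)].sum())
    d = conc / usable  # Somers' D over usable pairs
    c = (d + 1.0) / 2.0

    wi = w.sum(axis=1).astype(float)
    ri = r.sum(axis=1)
    total_w = w.sum()
    var_d = 4.0 * float(((ri - d * wi) ** 2).sum()) / total_w**2
    se_c = math.sqrt(var_d) / 2.0
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    return c, (c - z * se_c, c + z * se_c), usable


def km_estimate(time, event, group) -> dict:
    """Kaplan-Meier product-limit curves per group.

    Returns ``{group label: DataFrame(time, at_risk, events, survival,
    cum_event_pct)}`` where ``cum_event_pct`` is 100 * (1 - S(t)), the
    cumulative percentage with an event.
    """
    df = pd.DataFrame({
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=int),
        "group": np.asarray(group),
    })
    out = {}
    for g, sub in df.groupby("group", sort=True):
        if sub.empty:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        table = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[g] = pd.DataFrame({
            "time": table.index.to_numpy(),
            "at_risk": table["at_risk"].to_numpy(),
            "events": table["observed"].to_numpy(),
            "survival": surv.reindex(table.index).to_numpy(),
            "cum_event_pct": 100.0 * (1 - surv.reindex(table.index)
                                      .to_numpy()),
        }).reset_index(drop=True)
    return out


def cox_fit(data: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str], ties: str = "breslow",
            conf: float = 0.95) -> pd.DataFrame:
    """Cox proportional-hazards fit; returns the coefficient table.

    Columns: ``coef, hr, hr_lo, hr_hi, se, p``.  Raises
    :class:`EvaluationError` on degenerate input (no events, constant
    covariate) or non-convergence (monotone likelihood).
    """
    if data[event_col].sum() < 1:
        raise EvaluationError("Cox regression needs at least one event")
    for c in covariates:
        if data[c].nunique() < 2:
            raise EvaluationError(f"covariate {c!r} is constant")
    model = sm.PHReg(data[duration_col].to_numpy(dtype=float),
                     data[list(covariates)].to_numpy(dtype=float),
                     status=data[event_col].to_numpy(dtype=int),
                     ties=ties)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(method="newton", maxiter=50, gtol=1e-8)
    except Exception as exc:
        raise EvaluationError(f"Cox fit failed: {exc}") from exc
    coef = np.asarray(fit.params)
    se = np.asarray(fit.bse)
    if not np.all(np.isfinite(coef)) or not np.all(np.isfinite(se)):
        raise EvaluationError("Cox fit did not converge "
                              "(monotone likelihood?)")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    with np.errstate(over="ignore"):  # an unbounded upper CI is legitimate
        return pd.DataFrame({
            "coef": coef,
            "hr": np.exp(coef),
            "hr_lo": np.exp(coef - z * se),
            "hr_hi": np.exp(coef + z * se),
            "se": se,
            "p": np.asarray(fit.pvalues),
        }, index=pd.Index(list(covariates), name="covariate"))


def stepwise_cox(data: pd.DataFrame, duration_col: str, event_col: str,
                 candidates: list[str], removal_alpha: float = 0.05,
                 forced: list[str] | None = None
                 ) -> tuple[list[str], pd.DataFrame, list[dict]]:
    """Backwards step-down Cox covariate selection.

    Repeatedly drops the removable covariate with the largest Wald p
    while that p is at or above ``removal_alpha``; ``forced``
    covariates are always retained (e.g. the biomarker score under
    adjustment).  Returns ``(retained, final table, trace)``.
    """
    forced = list(forced or [])
    current = list(candidates)
    trace: list[dict] = []
    while True:
        fit = cox_fit(data, duration_col, event_col, forced + current)
        removable = fit.loc[[c for c in current]]
        if removable.empty:
            return forced + current, fit, trace
        worst = removable["p"].idxmax()
        if removable.loc[worst, "p"] < removal_alpha:
            return forced + current, fit, trace
        trace.append({"removed": worst, "p": float(removable.loc[worst, "p"])})
        current.remove(worst)
        if not current and not forced:
            return [], fit, trace


# ---------------------------------------------------------------------------
# added-value statistics


def _logit_probs(y: np.ndarray, X: np.ndarray,
                 ridge_alpha: float = 1e-4) -> tuple[np.ndarray, list[str]]:
    warns: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        if not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError("unstable standard errors")
        return np.asarray(fit.predict(X)), warns
    except Exception:
        warns.append(f"separation_or_nonconvergence: ridge (alpha={ridge_alpha})")
        from acspredict.classifier import _ridge_logistic
        beta, _ = _ridge_logistic(X, y, ridge_alpha)
        return 1.0 / (1.0 + np.exp(-(X @ beta))), warns


def nested_logistic_models(labels, centre, fcvrs, pattern_scores=None,
                           composite_scores=None) -> dict:
    """Fit the nested case-control risk models.

    Model 1 regresses case status on study centre (categorical
    indicators; dropped automatically when only one centre is present)
    and the Framingham 10-year risk score.  Model 2 adds the pattern
    score, model 3 the composite score.  Returns a dict with fitted
    probability vectors ``p1``/``p2``/``p3`` (the latter two None when
    the corresponding score is not given) and any separation warnings.
    """
    y = np.asarray(labels, dtype=float)
    f = np.asarray(fcvrs, dtype=float)
    centre = pd.Series(np.asarray(centre), name="centre")
    dummies = pd.get_dummies(centre, drop_first=True, dtype=float)
    base_cols = [np.ones_like(y)]
    if dummies.shape[1]:
        base_cols.append(dummies.to_numpy())
    base_cols.append(f[:, None])
    X1 = np.column_stack(base_cols)
    out: dict = {"warnings": []}
    p1, w = _logit_probs(y, X1)
    out["p1"] = p1
    out["warnings"] += [f"model1: {m}" for m in w]
    for name, score in (("p2", pattern_scores), ("p3", composite_scores)):
        if score is None:
            out[name] = None
            continue
        Xk = np.column_stack([X1, np.asarray(score, dtype=float)[:, None]])
        pk, w = _logit_probs(y, Xk)
        out[name] = pk
        out["warnings"] += [f"{name}: {m}" for m in w]
    return out


def _category_index(p: np.ndarray, edges: tuple[float, ...]) -> np.ndarray:
    """Risk category per probability; edges are left-closed boundaries."""
    return np.searchsorted(np.asarray(edges), p, side="right")


@dataclass
class ReclassReport:
    """IDI and categorical NRI of a new risk model over an old one."""

    idi: float
    idi_se: float
    idi_p: float
    nri: float
    nri_se: float
    nri_p: float
    categories: tuple[float, ...]
    movement_events: pd.DataFrame = field(repr=False, default=None)
    movement_nonevents: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "idi": self.idi, "idi_se": self.idi_se, "idi_p": self.idi_p,
            "nri": self.nri, "nri_se": self.nri_se, "nri_p": self.nri_p,
            "categories": list(self.categories),
        }


def idi_nri(p_old, p_new, labels,
            categories: tuple[float, ...] = (0.10, 0.20)) -> ReclassReport:
    """Integrated discrimination and net reclassification improvement.

    IDI is the change in discrimination slope: (mean p_new - mean p_old
    among events) - (same among non-events).  The categorical NRI uses
    risk classes [0, 0.10), [0.10, 0.20), [0.20, 1] by default:
    NRI = (P(up) - P(down) | events) - (P(up) - P(down) | non-events).
    Standard errors treat events and non-events as independent samples;
    p-values are two-sided z-tests.
    """
    po = np.asarray(p_old, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any((po < 0) | (po > 1) | (pn < 0) | (pn > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    ev = y == 1
    ne = y == 0
    if not ev.any() or not ne.any():
        raise EvaluationError("IDI/NRI need both classes present")

    d = pn - po
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    idi = float(d[ev].mean() - d[ne].mean())
    var_e = float(d[ev].var(ddof=1)) / n_e if n_e > 1 else 0.0
    var_ne = float(d[ne].var(ddof=1)) / n_ne if n_ne > 1 else 0.0
    idi_se = math.sqrt(var_e + var_ne)
    idi_p = 2 * stats.norm.sf(abs(idi) / idi_se) if idi_se > 0 else math.nan

    co = _category_index(po, categories)
    cn = _category_index(pn, categories)
    k = len(categories) + 1
    move_e = pd.crosstab(pd.Categorical(co[ev], categories=range(k)),
                         pd.Categorical(cn[ev], categories=range(k)),
                         dropna=False)
    move_ne = pd.crosstab(pd.Categorical(co[ne], categories=range(k)),
                          pd.Categorical(cn[ne], categories=range(k)),
                          dropna=False)
    up_e = float((cn[ev] > co[ev]).mean())
    dn_e = float((cn[ev] < co[ev]).mean())
    up_ne = float((cn[ne] > co[ne]).mean())
    dn_ne = float((cn[ne] < co[ne]).mean())
    nri = (up_e - dn_e) - (up_ne - dn_ne)
    nri_var = ((up_e + dn_e - (up_e - dn_e) ** 2) / n_e
               + (up_ne + dn_ne - (up_ne - dn_ne) ** 2) / n_ne)
    nri_se = math.sqrt(max(nri_var, 0.0))
    nri_p = 2 * stats.norm.sf(abs(nri) / nri_se) if nri_se > 0 else math.nan

    return ReclassReport(
        idi=idi, idi_se=idi_se, idi_p=float(idi_p),
        nri=float(nri), nri_se=nri_se, nri_p=float(nri_p),
        categories=tuple(categories),
        movement_events=move_e, movement_nonevents=move_ne,
    )
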