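"""Delta-age outcome associations: Cox proportional hazards for all-cause
mortality, Kaplan-Meier curves by delta-age tertile, and kinship-aware
linear mixed-model associations with cardiometabolic traits.

The Cox partial likelihood is maximized by Newton-Raphson with the Efron
tie correction by default (Breslow optional); standard errors come from
the inverse observed information.  Trait associations fit the mixed model
with delta-age as the response and the trait as the tested covariate,
adjusting for age, sex and BMI (except when BMI is the trait), restricted
to the treatment-free subset the trait calls for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from mirclock.exceptions import ConfigurationError, ConvergenceError
from mirclock.lmm import KinshipEigen, reml_fit
from mirclock.preprocess import design_matrix

Z975 = stats.norm.ppf(0.975)

# mortality model adjustment sets
ADJUST_MINIMAL = ["age", "sex"]
ADJUST_FULL = ADJUST_MINIMAL + [
    "sbp",
    "dbp",
    "bmi",
    "hdl",
    "total_cholesterol",
    "triglycerides",
    "glucose",
    "smoker",
    "rx_lipid",
    "rx_dm",
    "rx_htn",
    "chd",
    "diabetes",
]

# trait -> treatment flags whose carriers are excluded before testing
TRAIT_EXCLUSIONS: dict[str, list[str]] = {
    "sbp": ["rx_htn", "rx_lipid", "rx_dm"],
    "dbp": ["rx_htn", "rx_lipid", "rx_dm"],
    "total_cholesterol": ["rx_htn", "rx_lipid", "rx_dm"],
    "hdl": ["rx_htn", "rx_lipid", "rx_dm"],
    "triglycerides": ["rx_htn", "rx_lipid", "rx_dm"],
    "glucose": ["rx_htn", "rx_lipid", "rx_dm"],
    "bmi": ["rx_htn", "rx_lipid", "rx_dm"],
    "chd": [],
    "diabetes": ["rx_dm"],
    "hypertension": ["rx_htn"],
}


@dataclass
class CoxFit:
    names: list[str]
    log_hr: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    ties_method: str
    loglik: float
    score_norm: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.log_hr)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.log_hr - Z975 * self.se)
        hi = np.exp(self.log_hr + Z975 * self.se)
        return np.column_stack([lo, hi])

    @property
    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "log_hr": self.log_hr,
                "se": self.se,
                "hr": self.hr,
                "ci95_low": ci[:, 0],
                "ci95_high": ci[:, 1],
                "p": self.p,
            },
            index=self.names,
        )


def _cox_loglik(beta, times, events, X, ties):
    """Partial log-likelihood, score and information in one pass.

    Data must be sorted by descending time so the risk set at each event
    time is a prefix.
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    if np.unique(times).size == n:
        # no ties: risk sets are prefixes of the descending sort; Efron and
        # Breslow coincide and everything vectorizes
        ev = np.flatnonzero(events)
        r0 = np.cumsum(w)[ev]
        r1 = np.cumsum(wx, axis=0)[ev]
        mu = r1 / r0[:, None]
        ll = float(eta[ev].sum() - np.log(r0).sum())
        score = X[ev].sum(axis=0) - mu.sum(axis=0)
        s2 = np.cumsum(wxx, axis=0)[ev]
        info = (s2 / r0[:, None, None]).sum(axis=0) - mu.T @ mu
        return ll, score, info

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[i]
        j = i
        while j < n and times[j] == t:
            s0 += w[j]
            s1 += wx[j]
            s2 += wxx[j]
            j += 1
        dead = [k for k in range(i, j) if events[k]]
        m = len(dead)
        if m:
            d0 = sum(w[k] for k in dead)
            d1 = np.sum(wx[dead], axis=0)
            d2 = np.sum(wxx[dead], axis=0)
            xsum = X[dead].sum(axis=0)
            ll += eta[dead].sum()
            score += xsum
            for l in range(m):
                if ties == "efron":
                    f = l / m
                    r0, r1, r2 = s0 - f * d0, s1 - f * d1, s2 - f * d2
                else:  # breslow
                    r0, r1, r2 = s0, s1, s2
                ll -= np.log(r0)
                mu = r1 / r0
                score -= mu
                info += r2 / r0 - np.outer(mu, mu)
        i = j
    return ll, score, info


def cox_fit(
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    Raises :class:`ConvergenceError` on monotone likelihood (perfect
    separation drives a coefficient to infinity) rather than returning a
    huge estimate.
    """
    if ties not in ("efron", "breslow"):
        raise ConfigurationError(f"unknown ties method {ties!r}")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    if (t < 0).any():
        raise ConfigurationError("negative survival times")
    if e.sum() == 0:
        raise ConfigurationError("no events observed")
    if not np.isfinite(X).all():
        raise ConfigurationError("non-finite covariate values")
    order = np.argsort(-t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    center = X.mean(axis=0)
    Xc = X - center

    beta = np.zeros(X.shape[1])
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, score, info = _cox_loglik(beta, t, e, Xc, ties)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # step-halving keeps the likelihood monotone
        new = beta + step
        for _h in range(30):
            ll_new = _cox_loglik(new, t, e, Xc, ties)[0]
            if ll_new >= ll - 1e-12:
                break
            new = (beta + new) / 2.0
        beta = new
        if np.abs(beta).max() > 50:
            raise ConvergenceError(
                "diverging coefficients (monotone likelihood / perfect separation?)"
            )
        if abs(ll_new - ll_prev) < tol * (abs(ll_prev) + 1.0):
            break
        ll_prev = ll_new
    else:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")

    ll, score, info = _cox_loglik(beta, t, e, Xc, ties)
    scale = Xc.std(axis=0)
    if np.any(np.abs(beta) * np.where(scale > 0, scale, 1.0) > 15.0):
        raise ConvergenceError(
            "monotone partial likelihood (perfect separation): a per-SD log-HR "
            "exceeds 15; the estimate is unbounded"
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return CoxFit(
        names=names,
        log_hr=beta,
        se=se,
        p=np.clip(p, np.finfo(float).tiny, 1.0),
        n=len(t),
        n_events=int(e.sum()),
        ties_method=ties,
        loglik=float(ll),
        score_norm=float(np.abs(score).max()),
    )


def delta_age_tertiles(delta: pd.Series) -> pd.Series:
    """Cut delta-age at its 1/3 and 2/3 sample quantiles; boundary ties go
    to the lower tertile."""
    q1, q2 = np.quantile(delta, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(delta <= q1, "T1", np.where(delta <= q2, "T2", "T3"))
    return pd.Series(labels, index=delta.index, name="tertile")


def km_by_groups(
    time: pd.Series, event: pd.Series, groups: pd.Series
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group: columns ``time``,
    ``survival``, ``at_risk``.  An all-censored group yields a curve
    constant at 1."""
    out = {}
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            raise ConfigurationError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[g] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": tab["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


def trait_assoc(
    delta: pd.DataFrame,
    phen: pd.DataFrame,
    K: pd.DataFrame | KinshipEigen,
    trait: str,
    adjust: list[str] | None = None,
    exclusions: dict[str, list[str]] | None = None,
    n_traits_tested: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Mixed-model association of delta-age (response) with one trait.

    Adjusts for age, sex and BMI -- BMI is dropped from the adjustment set
    automatically when it is the trait -- and excludes individuals on the
    treatments configured for that trait before fitting.
    """
    if trait not in phen.columns:
        raise ConfigurationError(f"trait {trait!r} not in phenotype table")
    exclusions = TRAIT_EXCLUSIONS if exclusions is None else exclusions
    if adjust is None:
        adjust = ["age", "sex"] + ([] if trait == "bmi" else ["bmi"])
    adjust = [c for c in adjust if c != trait]

    ids = delta.index.intersection(phen.index)
    keep = pd.Series(True, index=ids)
    for flag in exclusions.get(trait, []):
        keep &= phen.loc[ids, flag] == 0
    ids = ids[keep]
    if len(ids) == 0:
        raise ConfigurationError(
            f"no samples left for {trait!r} after treatment exclusions"
        )
    y = delta.loc[ids, "delta_age"]
    X = design_matrix(phen.loc[ids], [trait] + adjust)
    if isinstance(K, KinshipEigen):
        raise ConfigurationError(
            "trait_assoc subsets samples per trait; pass the kinship matrix itself"
        )
    fit = reml_fit(y, X, K.loc[ids, ids])
    tested = X.columns[1]  # first covariate after intercept is the trait term
    c = fit.coef(tested)
    return {
        "trait": trait,
        "n": int(len(ids)),
        "beta": c["beta"],
        "se": c["se"],
        "t": c["t"],
        "p": c["wald_p"],
        "significant": c["wald_p"] < alpha / n_traits_tested,
        "adjusted_for": adjust,
        "h2": fit.h2,
    }
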