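"""Kinship construction and single-random-effect linear mixed models.

The model is y = X b + g + e with g ~ N(0, sigma_A^2 K) for K the expected
additive relationship (twice the kinship coefficient) and e ~ N(0,
sigma_E^2 I).  Fitting is restricted maximum likelihood: one symmetric
eigendecomposition K = U D U', rotation of y and X by U', then a 1-D
profile of the REML log-likelihood over h2 = sigma_A^2 / (sigma_A^2 +
sigma_E^2) in [0, 1), with generalized least squares for b and the
closed-form total variance at each candidate h2.  Ties at the boundary are
broken toward h2 = 0.  Wald p-values use the normal approximation; the
residual degrees of freedom are reported so t-based intervals can be formed
if preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from mirclock.exceptions import ConfigurationError, ConvergenceError
from mirclock import io as mio

_H2_UPPER = 1.0 - 1e-6


def kinship_from_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Expected additive relationship matrix (2 * kinship) from a pedigree.

    Recursive kinship: phi(i,i) = 0.5 * (1 + phi(father_i, mother_i)) and
    phi(i,j) = 0.5 * (phi(father_i, j) + phi(mother_i, j)), founders
    unrelated and non-inbred.  Raises on cyclic parent links.
    """
    mio.validate_pedigree(ped)
    ids = ped["individual_id"].tolist()
    idx = {iid: i for i, iid in enumerate(ids)}
    parents = {
        row.individual_id: (
            idx.get(row.father_id) if row.father_id != mio.FOUNDER else None,
            idx.get(row.mother_id) if row.mother_id != mio.FOUNDER else None,
        )
        for row in ped.itertuples(index=False)
    }
    # topological order (validate_pedigree guarantees acyclicity)
    order: list[str] = []
    placed: set[str] = set()
    pending = ids
    while pending:
        rest = []
        for iid in pending:
            fa, mo = parents[iid]
            fa_ok = fa is None or ids[fa] in placed
            mo_ok = mo is None or ids[mo] in placed
            if fa_ok and mo_ok:
                order.append(iid)
                placed.add(iid)
            else:
                rest.append(iid)
        pending = rest

    n = len(ids)
    phi = np.zeros((n, n))
    for iid in order:
        i = idx[iid]
        fa, mo = parents[iid]
        if fa is None and mo is None:
            phi[i, i] = 0.5
            continue
        row_fa = phi[fa] if fa is not None else 0.0
        row_mo = phi[mo] if mo is not None else 0.0
        row = 0.5 * (row_fa + row_mo)
        phi[i, :] = row
        phi[:, i] = row
        phi_fm = phi[fa, mo] if fa is not None and mo is not None else 0.0
        phi[i, i] = 0.5 * (1.0 + phi_fm)
    return pd.DataFrame(2.0 * phi, index=ids, columns=ids)


class KinshipEigen:
    """Cached eigendecomposition of a relationship matrix, reused across
    many responses tested against the same samples."""

    def __init__(self, K: pd.DataFrame | np.ndarray, clip_tol: float = 1e-8):
        if isinstance(K, pd.DataFrame):
            self.ids = list(K.index)
            mat = K.values
        else:
            self.ids = list(range(K.shape[0]))
            mat = np.asarray(K, dtype=float)
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise ConfigurationError("kinship matrix is not symmetric")
        vals, vecs = np.linalg.eigh(mat)
        if vals.min() < -clip_tol:
            warnings.warn(
                f"kinship not PSD (min eigenvalue {vals.min():.3g}); clipping to 0",
                stacklevel=2,
            )
        self.d = np.clip(vals, 0.0, None)
        self.U = vecs

    @property
    def n(self) -> int:
        return len(self.d)

    def rotate(self, A: np.ndarray) -> np.ndarray:
        return self.U.T @ A


@dataclass
class LMMFit:
    """REML fit: fixed effects, variance components, heritability."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    sigma2_a: float
    sigma2_e: float
    h2: float
    reml_loglik: float
    df_resid: int
    identifiable: bool = True
    converged: bool = True
    _tstats: np.ndarray = field(default=None, repr=False)

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "t": self._tstats, "wald_p": self.wald_p},
            index=self.names,
        )

    def coef(self, name: str) -> dict:
        if name not in self.names:
            raise KeyError(f"covariate {name!r} not in fit ({self.names})")
        i = self.names.index(name)
        return {
            "beta": self.beta[i],
            "se": self.se[i],
            "t": self._tstats[i],
            "wald_p": self.wald_p[i],
        }


def _profile_reml(h2, yt, Xt, d, n, p):
    """Profiled REML log-likelihood at a candidate h2 plus GLS byproducts."""
    w = h2 * d + (1.0 - h2)
    wi = 1.0 / w
    Xw = Xt * wi[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ beta
    rss = float(r @ (wi * r))
    s2 = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, beta, s2, XtWX
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * s2) + 1.0) + np.log(w).sum() + logdet_xwx
    )
    return ll, beta, s2, XtWX


def reml_fit(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    K: pd.DataFrame | np.ndarray | KinshipEigen,
    names: list[str] | None = None,
    rotated: bool = False,
) -> LMMFit:
    """Fit the single-random-effect LMM by 1-D REML profiling over h2.

    Pass ``rotated=True`` when y and X are already in the eigenbasis of K
    (then K must be a :class:`KinshipEigen`).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else names
        X = X.values
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen(K)
    n, p = X.shape
    if len(y) != n or eig.n != n:
        raise ConfigurationError(
            f"dimension mismatch: y={len(y)}, X rows={n}, K={eig.n}"
        )
    if n <= p:
        raise ConfigurationError("more covariates than observations")
    if rotated:
        yt, Xt = y, X
    else:
        yt, Xt = eig.rotate(y), eig.rotate(X)
    d = eig.d

    def neg(h2):
        return -_profile_reml(h2, yt, Xt, d, n, p)[0]

    res = optimize.minimize_scalar(
        neg, bounds=(0.0, _H2_UPPER), method="bounded", options={"xatol": 1e-9}
    )
    if not res.success:
        raise ConvergenceError(f"REML profile optimization failed: {res.message}")
    ll0 = _profile_reml(0.0, yt, Xt, d, n, p)[0]
    h2 = 0.0 if ll0 >= -res.fun - 1e-10 else float(res.x)  # ties toward 0
    ll, beta, s2, XtWX = _profile_reml(h2, yt, Xt, d, n, p)

    # identifiability: likelihood flat in h2 (e.g. K = I) within tolerance
    probe = np.array([_profile_reml(q, yt, Xt, d, n, p)[0] for q in (0.0, 0.5, 0.95)])
    identifiable = bool(probe.max() - probe.min() > 1e-8)

    cov = s2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(t))
    wald_p = np.clip(wald_p, np.finfo(float).tiny, 1.0)
    return LMMFit(
        names=list(names),
        beta=beta,
        se=se,
        wald_p=wald_p,
        sigma2_a=h2 * s2,
        sigma2_e=(1.0 - h2) * s2,
        h2=h2,
        reml_loglik=float(ll),
        df_resid=n - p,
        identifiable=identifiable,
        _tstats=t,
    )


def partial_r2(fit: LMMFit, covariate: str) -> float:
    """Squared partial correlation of one covariate: t^2 / (t^2 + df)."""
    c = fit.coef(covariate)
    t2 = c["t"] ** 2
    return float(t2 / (t2 + fit.df_resid))


def heritability(
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray,
    ped: pd.DataFrame | None = None,
    K: pd.DataFrame | KinshipEigen | None = None,
) -> LMMFit:
    """h2 of a trait with covariates as fixed effects.

    Provide either a pedigree (kinship is derived) or a relationship
    matrix.  The returned fit's ``identifiable`` flag is False when the
    likelihood is flat in h2 (e.g. unrelated individuals).
    """
    if K is None:
        if ped is None:
            raise ConfigurationError("provide a pedigree or a kinship matrix")
        K = kinship_from_pedigree(ped)
    if isinstance(y, pd.Series) and isinstance(K, pd.DataFrame):
        K = K.loc[y.index, y.index]  # kinship from the full pedigree, then subset
    return reml_fit(y, covariates, K)


def _family_rotated_parts(y: pd.Series, X: pd.DataFrame, ped: pd.DataFrame):
    """Rotate (y, X) family block by family block; returns per-family
    (rotated response, rotated design, eigenvalues) triples."""
    parts = []
    avail = set(y.index)
    for _, sub in ped.groupby("pedigree_id", sort=False):
        ids = [i for i in sub["individual_id"] if i in avail]
        if not ids:
            continue
        # kinship from the whole family, then subset to measured members
        K = kinship_from_pedigree(sub).loc[ids, ids].values
        w, U = np.linalg.eigh(K)
        yi = y.loc[ids].values.astype(float)
        Xi = X.loc[ids].values.astype(float)
        parts.append((U.T @ yi, U.T @ Xi, np.clip(w, 0.0, None)))
    return parts


def heritability_bootstrap(
    y: pd.Series,
    covariates: pd.DataFrame,
    ped: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[LMMFit, np.ndarray]:
    """Family-level bootstrap of the h2 estimate.

    Families are the resampling unit (they are independent under the
    model), and each family's eigendecomposition is computed once, so
    hundreds of replicates cost little more than one fit.  Returns the
    point-estimate fit and the bootstrap h2 draws.
    """
    parts = _family_rotated_parts(y, covariates, ped)
    n_fam = len(parts)
    p = parts[0][1].shape[1]
    names = list(covariates.columns)

    def fit_from(part_idx):
        yt = np.concatenate([parts[i][0] for i in part_idx])
        Xt = np.vstack([parts[i][1] for i in part_idx])
        d = np.concatenate([parts[i][2] for i in part_idx])
        n = len(yt)

        def neg(h2):
            return -_profile_reml(h2, yt, Xt, d, n, p)[0]

        res = optimize.minimize_scalar(
            neg, bounds=(0.0, _H2_UPPER), method="bounded", options={"xatol": 1e-8}
        )
        ll0 = _profile_reml(0.0, yt, Xt, d, n, p)[0]
        return 0.0 if ll0 >= -res.fun - 1e-10 else float(res.x)

    full = list(range(n_fam))
    yt = np.concatenate([parts[i][0] for i in full])
    Xt = np.vstack([parts[i][1] for i in full])
    d = np.concatenate([parts[i][2] for i in full])
    point = reml_fit(yt, Xt, _RotatedEigen(d), names=names, rotated=True)

    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = fit_from(rng.integers(0, n_fam, n_fam))
    return point, draws


class _RotatedEigen(KinshipEigen):
    """Eigenvalue-only stand-in used when data are pre-rotated."""

    def __init__(self, d: np.ndarray):
        self.d = np.asarray(d, float)
        self.U = None
        self.ids = []

    def rotate(self, A):  # pragma: no cover - rotated inputs bypass this
        raise RuntimeError("pre-rotated eigen cannot rotate")
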