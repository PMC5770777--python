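"""Elastic-net "miRNA age" predictor and the delta-age biomarker.

The clock regresses chronological age on standardized miRNA residuals with
the elastic-net penalty

    (2n)^-1 ||y - b0 - X b||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2)

solved by cyclical coordinate descent with covariance updates and an
active-set strategy along a decreasing lambda path with warm starts.  The
intercept is unpenalized; predictors must already be standardized (mean 0,
SD 1 with 1/n variance), so the coordinate update is a plain
soft-threshold.  Lambda is chosen by pedigree-blocked 10-fold
cross-validation (minimum mean squared error) unless fixed.  Train/test
splitting assigns whole pedigrees to one side so no family spans the
split.  Delta-age is predicted age minus chronological age, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from mirclock.exceptions import AlignmentError, ConfigurationError
from mirclock.preprocess import ResidualMatrix


def split_by_pedigree(
    ped: pd.DataFrame, ratio: float = 0.5, seed: int = 0
) -> pd.Series:
    """Assign every pedigree wholly to set 'A' or 'B'.

    Greedy largest-pedigree-first balancing toward the target ratio of
    individuals; ties among equal-sized pedigrees are broken by a seeded
    shuffle.  Returns a Series mapping individual_id -> 'A'/'B'.
    """
    sizes = ped.groupby("pedigree_id")["individual_id"].count()
    if len(sizes) < 2:
        raise ConfigurationError("cannot split: need at least two pedigrees")
    rng = np.random.default_rng(seed)
    order = sizes.sample(frac=1.0, random_state=rng).sort_values(
        ascending=False, kind="stable"
    )
    total = sizes.sum()
    target_a = ratio * total
    target_b = (1.0 - ratio) * total
    count_a = count_b = 0
    assign: dict[str, str] = {}
    for fam, size in order.items():
        # assign to the side with the larger remaining deficit
        if target_a - count_a >= target_b - count_b:
            assign[fam] = "A"
            count_a += size
        else:
            assign[fam] = "B"
            count_b += size
    out = ped.set_index("individual_id")["pedigree_id"].map(assign)
    out.name = "split"
    return out


def _soft(z: float, g: float) -> float:
    return np.sign(z) * max(abs(z) - g, 0.0)


@njit(cache=False)
def _cd_solve_impl(XtX_n, Xty_n, lam, alpha, beta, tol, max_iter):  # pragma: no cover
    p = Xty_n.shape[0]
    grad_cache = Xty_n - XtX_n @ beta  # = X'r/n
    active = np.arange(p)
    it = 0
    while it < max_iter:
        it += 1
        max_delta = 0.0
        for idx in range(active.shape[0]):
            j = active[idx]
            bj = beta[j]
            rho = grad_cache[j] + XtX_n[j, j] * bj
            z = abs(rho) - lam * alpha
            bnew = 0.0 if z <= 0.0 else np.sign(rho) * z / (XtX_n[j, j] + lam * (1.0 - alpha))
            if bnew != bj:
                delta = bnew - bj
                for k in range(p):
                    grad_cache[k] -= XtX_n[k, j] * delta
                beta[j] = bnew
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            if active.shape[0] == p:
                break
            active = np.arange(p)  # active set converged: verify on the full set
        else:
            nz = np.flatnonzero(beta)
            active = nz if nz.shape[0] > 0 else np.arange(p)
    return it


def _cd_solve(XtX_n, Xty_n, lam, alpha, beta, tol=1e-7, max_iter=100_000):
    """Coordinate descent with covariance updates on standardized data.

    XtX_n = X'X/n, Xty_n = X'y/n with y centered.  Updates beta in place;
    returns the number of full sweeps used.
    """
    return _cd_solve_impl(
        np.ascontiguousarray(XtX_n),
        np.ascontiguousarray(Xty_n),
        float(lam),
        float(alpha),
        beta,
        float(tol),
        int(max_iter),
    )


def enet_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Warm-started solutions along a decreasing lambda path.

    Returns (lambdas, coefficient matrix path x p, intercept = mean(y)).
    """
    if alpha <= 0 or alpha > 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    n, p = X.shape
    ybar = float(y.mean())
    yc = y - ybar
    XtX_n = (X.T @ X) / n
    Xty_n = (X.T @ yc) / n
    if lambdas is None:
        lam_max = np.abs(Xty_n).max() / alpha
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
        if lambdas.size == 0:
            raise ConfigurationError("empty lambda grid")
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        _cd_solve(XtX_n, Xty_n, lam, alpha, beta, tol=tol)
        betas[i] = beta
    return lambdas, betas, ybar


@dataclass
class ClockModel:
    """Sparse linear age predictor; prediction is reproducible from the
    stored fields alone."""

    mirna_ids: list[str]
    coefficients: np.ndarray  # years per SD of standardized residual
    intercept: float  # years
    alpha_mix: float
    lambda_penalty: float
    n_train: int
    cv_folds: int = 0
    cv_curve: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def selected(self) -> pd.Series:
        nz = self.coefficients != 0
        return pd.Series(self.coefficients[nz], index=np.array(self.mirna_ids)[nz])

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#intercept\t{self.intercept!r}\n")
            fh.write(f"#alpha\t{self.alpha_mix!r}\n")
            fh.write(f"#lambda\t{self.lambda_penalty!r}\n")
            fh.write(f"#n_train\t{self.n_train}\n")
            for mir, coef in self.selected.items():
                fh.write(f"{mir}\t{coef!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ClockModel":
        meta: dict[str, float] = {}
        mirs: list[str] = []
        coefs: list[float] = []
        with open(path) as fh:
            for line in fh:
                key, val = line.rstrip("\n").split("\t")
                if key.startswith("#"):
                    meta[key[1:]] = float(val)
                else:
                    mirs.append(key)
                    coefs.append(float(val))
        return cls(
            mirna_ids=mirs,
            coefficients=np.array(coefs),
            intercept=meta["intercept"],
            alpha_mix=meta["alpha"],
            lambda_penalty=meta["lambda"],
            n_train=int(meta["n_train"]),
        )


def _check_standardized(X: np.ndarray) -> None:
    mu = np.abs(X.mean(axis=0)).max() if X.size else 0.0
    sd = X.std(axis=0, ddof=0)
    if mu > 1e-6 or np.abs(sd - 1.0).max() > 1e-6:
        raise ConfigurationError(
            "clock training requires standardized residuals (per-column mean 0, SD 1)"
        )


def _pedigree_folds(sample_ids, ped: pd.DataFrame | None, folds: int, seed: int):
    """Fold labels respecting pedigrees when one is supplied."""
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    if ped is None:
        return rng.permutation(n) % folds
    fam = ped.set_index("individual_id")["pedigree_id"].reindex(sample_ids)
    fam = fam.fillna(pd.Series([f"_solo{i}" for i in range(n)], index=sample_ids))
    labels = {}
    counts = np.zeros(folds)
    sizes = fam.value_counts().sample(frac=1.0, random_state=rng).sort_values(
        ascending=False, kind="stable"
    )
    for f, size in sizes.items():
        k = int(np.argmin(counts))
        labels[f] = k
        counts[k] += size
    return fam.map(labels).to_numpy()


def train_clock(
    resid: ResidualMatrix | pd.DataFrame,
    ages: pd.Series,
    alpha_mix: float = 0.5,
    lam: float | None = None,
    lambda_grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    pedigree: pd.DataFrame | None = None,
) -> ClockModel:
    """Fit the elastic-net clock on training-set standardized residuals.

    With ``lam`` fixed the model is fit straight down the path to that
    value; otherwise lambda minimizing the cross-validated MSE is chosen,
    with folds blocked by pedigree when one is given.
    """
    df = resid.values if isinstance(resid, ResidualMatrix) else resid
    X = df.to_numpy(dtype=float)
    y = ages.loc[df.index].to_numpy(dtype=float)
    n, p = X.shape
    _check_standardized(X)
    if lam is None and n <= folds:
        raise ConfigurationError(f"need more than {folds} samples for {folds}-fold CV")

    cv_curve = None
    used_folds = 0
    if lam is None:
        lams, _, _ = enet_path(X, y, alpha=alpha_mix, lambdas=lambda_grid)
        fold_id = _pedigree_folds(df.index, pedigree, folds, seed)
        mse = np.zeros((folds, len(lams)))
        for k in range(folds):
            tr = fold_id != k
            te = ~tr
            # re-standardize within the fold so training is leakage-free
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr = (X[tr] - mu) / sd
            Xte = (X[te] - mu) / sd
            _, betas, icpt = enet_path(Xtr, y[tr], alpha=alpha_mix, lambdas=lams)
            pred = icpt + Xte @ betas.T
            mse[k] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
        mean_mse = mse.mean(axis=0)
        lam = float(lams[int(np.argmin(mean_mse))])
        cv_curve = pd.DataFrame({"lambda": lams, "mean_mse": mean_mse})
        used_folds = folds

    lams, betas, icpt = enet_path(
        X, y, alpha=alpha_mix,
        lambdas=_path_to(lam, X, y, alpha_mix) if lambda_grid is None else lambda_grid,
    )
    i = int(np.argmin(np.abs(lams - lam)))
    return ClockModel(
        mirna_ids=list(df.columns),
        coefficients=betas[i],
        intercept=icpt,
        alpha_mix=alpha_mix,
        lambda_penalty=float(lams[i]),
        n_train=n,
        cv_folds=used_folds,
        cv_curve=cv_curve,
    )


def _path_to(lam: float, X, y, alpha: float, n_steps: int = 30) -> np.ndarray:
    """Decreasing warm-start path from lambda_max down to the target."""
    n = X.shape[0]
    lam_max = np.abs(X.T @ (y - y.mean()) / n).max() / alpha
    if lam >= lam_max:
        return np.array([lam])
    return np.unique(np.r_[np.geomspace(lam_max, max(lam, 1e-12), n_steps), lam])


def predict_age(
    model: ClockModel,
    resid: ResidualMatrix | pd.DataFrame,
    ages: pd.Series | None = None,
) -> tuple[pd.Series, float | None]:
    """Apply the clock; returns (predicted age, Pearson r vs chronological
    age when ages are supplied)."""
    df = resid.values if isinstance(resid, ResidualMatrix) else resid
    missing = [m for m in model.mirna_ids if m not in df.columns]
    if missing:
        raise ConfigurationError(f"matrix lacks model miRNA(s): {missing[:5]}")
    X = df[model.mirna_ids].to_numpy(dtype=float)
    pred = pd.Series(
        model.intercept + X @ model.coefficients, index=df.index, name="mirna_age"
    )
    r = None
    if ages is not None:
        r = float(stats.pearsonr(pred, ages.loc[df.index])[0])
    return pred, r


def delta_age(predicted: pd.Series, chronological: pd.Series) -> pd.DataFrame:
    """Delta-age table: predicted minus chronological age, exactly; the
    attrs carry the delta-age vs predicted-age correlation diagnostic."""
    missing = predicted.index.difference(chronological.index)
    if len(missing):
        raise AlignmentError(
            f"chronological ages missing for samples, e.g. {list(missing[:5])}"
        )
    chron = chronological.loc[predicted.index]
    out = pd.DataFrame(
        {
            "chronological_age": chron,
            "mirna_age": predicted,
            "delta_age": predicted - chron,
        }
    )
    if out["delta_age"].std() > 0 and out["mirna_age"].std() > 0:
        out.attrs["delta_vs_mirna_age_r"] = float(
            stats.pearsonr(out["delta_age"], out["mirna_age"])[0]
        )
    return out
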