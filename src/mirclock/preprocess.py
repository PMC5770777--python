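"""Ct-matrix QC, missing-value handling, technical normalization and
cell-count imputation.

QC rules run in a fixed order: (1) values at or above the detection limit
are marked missing (not expressed); (2) per-miRNA outliers at >= 5 SD from
the post-masking mean are marked missing; (3) miRNAs expressed in too small
a fraction of samples are dropped; (4) samples missing too large a fraction
of the kept panel are dropped; (5) remaining missing cells are filled with
the limit value.  Outlier statistics are computed after limit masking so
censored values cannot inflate the SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from mirclock.exceptions import ConfigurationError

DEFAULT_TECH_COVARIATES = ["batch", "rna_concentration", "rin", "ratio_260_280"]
CLOCK_COVARIATES = ["rna_concentration", "rin", "ratio_260_280", "sex"]


@dataclass
class QCReport:
    n_input_samples: int
    n_input_mirnas: int
    excluded_mirnas: dict[str, str] = field(default_factory=dict)  # id -> reason
    excluded_samples: dict[str, str] = field(default_factory=dict)
    n_marked_limit: int = 0
    n_marked_outlier: int = 0
    n_input_missing: int = 0
    n_values_filled: int = 0
    fill_value: float = 27.0

    @property
    def n_kept_mirnas(self) -> int:
        return self.n_input_mirnas - len(self.excluded_mirnas)

    @property
    def n_kept_samples(self) -> int:
        return self.n_input_samples - len(self.excluded_samples)

    def to_frame(self) -> pd.DataFrame:
        rows = [("mirna", m, r) for m, r in self.excluded_mirnas.items()]
        rows += [("sample", s, r) for s, r in self.excluded_samples.items()]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])

    def log_lines(self) -> list[str]:
        return [
            f"input: {self.n_input_samples} samples x {self.n_input_mirnas} miRNAs",
            f"marked missing at detection limit: {self.n_marked_limit}",
            f"marked missing as outliers: {self.n_marked_outlier}",
            f"missing on input: {self.n_input_missing}",
            f"miRNAs excluded: {len(self.excluded_mirnas)}",
            f"samples excluded: {len(self.excluded_samples)}",
            f"missing values filled with Ct={self.fill_value}: {self.n_values_filled}",
            f"kept: {self.n_kept_samples} samples x {self.n_kept_mirnas} miRNAs",
        ]


def qc_filter(
    ct: pd.DataFrame,
    limit: float = 27.0,
    outlier_sd: float = 5.0,
    min_expressed_frac: float = 0.95,
    max_sample_missing_frac: float = 0.10,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the QC rules (see module docstring) and report every action."""
    if ct.size == 0:
        raise ConfigurationError("empty Ct matrix")
    report = QCReport(
        n_input_samples=ct.shape[0],
        n_input_mirnas=ct.shape[1],
        fill_value=limit,
        n_input_missing=int(ct.isna().sum().sum()),
    )
    vals = ct.to_numpy(dtype=float, copy=True)

    at_limit = vals >= limit
    report.n_marked_limit = int(np.nansum(at_limit & ~np.isnan(vals)))
    vals[at_limit] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
    dev = np.abs(vals - mean)
    outlier = (dev >= outlier_sd * sd) & ~np.isnan(vals) & (sd > 0)
    report.n_marked_outlier = int(outlier.sum())
    vals[outlier] = np.nan

    expressed_frac = 1.0 - np.isnan(vals).mean(axis=0)
    keep_mir = expressed_frac >= min_expressed_frac
    for j, keep in enumerate(keep_mir):
        if not keep:
            report.excluded_mirnas[ct.columns[j]] = (
                f"expressed in {expressed_frac[j]:.3f} < {min_expressed_frac} of samples"
            )
    if not keep_mir.any():
        raise ConfigurationError("empty panel: all miRNAs failed the expression filter")
    vals = vals[:, keep_mir]
    cols = ct.columns[keep_mir]

    sample_missing = np.isnan(vals).mean(axis=1)
    keep_smp = sample_missing <= max_sample_missing_frac
    for i, keep in enumerate(keep_smp):
        if not keep:
            report.excluded_samples[ct.index[i]] = (
                f"missing {sample_missing[i]:.3f} > {max_sample_missing_frac} of kept miRNAs"
            )
    vals = vals[keep_smp, :]

    report.n_values_filled = int(np.isnan(vals).sum())
    vals = np.where(np.isnan(vals), limit, vals)
    out = pd.DataFrame(vals, index=ct.index[keep_smp], columns=cols)
    return out, report


@dataclass
class ResidualMatrix:
    """Per-miRNA least-squares residuals from a technical-covariate model."""

    values: pd.DataFrame
    covariates_removed: list[str]
    variance_explained: pd.Series
    standardized: bool = False

    @property
    def sample_ids(self):
        return self.values.index

    @property
    def mirna_ids(self):
        return self.values.columns


def design_matrix(
    phen: pd.DataFrame, covariates: list[str], add_intercept: bool = True
) -> pd.DataFrame:
    """Expand covariates into a numeric design; 'batch', 'sex' and other
    object/categorical columns become treatment-coded dummies."""
    missing = [c for c in covariates if c not in phen.columns]
    if missing:
        raise ConfigurationError(f"covariates not in phenotype table: {missing}")
    blocks = []
    if add_intercept:
        blocks.append(pd.DataFrame({"intercept": np.ones(len(phen))}, index=phen.index))
    for c in covariates:
        col = phen[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(col.astype(float).to_frame(c))
    return pd.concat(blocks, axis=1)


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop linearly dependent columns (QR pivot check) with a warning."""
    mat = X.to_numpy(dtype=float)
    q, r = np.linalg.qr(mat)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(mat.shape) * np.finfo(float).eps if diag.size else 0.0
    keep = diag > tol
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=3)
        X = X.loc[:, keep]
    return X


def technical_normalize(
    ct: pd.DataFrame, phen: pd.DataFrame, covariates: list[str] | None = None
) -> ResidualMatrix:
    """Residualize each miRNA on the technical covariates by least squares;
    reports per-miRNA variance explained by the removed covariates."""
    covariates = DEFAULT_TECH_COVARIATES if covariates is None else covariates
    phen = phen.loc[ct.index]
    X = _drop_aliased(design_matrix(phen, covariates))
    Y = ct.to_numpy(dtype=float)
    coefs, *_ = np.linalg.lstsq(X.to_numpy(dtype=float), Y, rcond=None)
    resid = Y - X.to_numpy(dtype=float) @ coefs
    total = Y.var(axis=0)
    total[total == 0] = np.nan
    ve = pd.Series(1.0 - resid.var(axis=0) / total, index=ct.columns, name="variance_explained")
    return ResidualMatrix(
        values=pd.DataFrame(resid, index=ct.index, columns=ct.columns),
        covariates_removed=covariates,
        variance_explained=ve,
    )


def standardized_residuals(
    ct: pd.DataFrame, phen: pd.DataFrame, covariates: list[str] | None = None
) -> ResidualMatrix:
    """Technical residuals z-scored per miRNA (mean 0, SD 1).

    Defaults to concentration, RIN, 260/280 ratio and sex -- batch is
    deliberately excluded (cohorts were profiled in independent batches, so
    removing batch would remove cohort-level age signal); pass covariates
    explicitly to change this.
    """
    covariates = CLOCK_COVARIATES if covariates is None else covariates
    rm = technical_normalize(ct, phen, covariates)
    vals = rm.values.to_numpy()
    sd = vals.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd < 1e-12)  # constant columns leave ~eps-scale residuals
    if zero.size:
        raise ConfigurationError(
            f"zero-variance residual column(s): {list(rm.values.columns[zero])}"
        )
    z = (vals - vals.mean(axis=0)) / sd
    return ResidualMatrix(
        values=pd.DataFrame(z, index=rm.values.index, columns=rm.values.columns),
        covariates_removed=covariates,
        variance_explained=rm.variance_explained,
        standardized=True,
    )


def impute_cell_counts(
    mrna: pd.DataFrame,
    training_cells: pd.DataFrame,
    n_components: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Impute blood-cell proportions from mRNA expression by partial
    least squares fitted on a measured-subset; returns predictions for all
    samples plus k-fold cross-validated r2 per cell type."""
    train_ids = training_cells.index
    missing = train_ids.difference(mrna.index)
    if len(train_ids) == 0 or len(missing):
        raise ConfigurationError(
            "training samples empty or absent from mRNA matrix"
            + (f": {list(missing[:5])}" if len(missing) else "")
        )
    Xtr = mrna.loc[train_ids].to_numpy()
    Ytr = training_cells.to_numpy()
    max_comp = min(Xtr.shape[0] - 1, Xtr.shape[1])
    if n_components > max_comp:
        raise ConfigurationError(
            f"n_components={n_components} exceeds max usable {max_comp}"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xtr, Ytr)
    pred_all = pd.DataFrame(
        pls.predict(mrna.to_numpy()), index=mrna.index, columns=training_cells.columns
    )

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_pred = np.empty_like(Ytr)
    for tr, te in kf.split(Xtr):
        m = PLSRegression(n_components=min(n_components, len(tr) - 1), scale=False)
        m.fit(Xtr[tr], Ytr[tr])
        cv_pred[te] = m.predict(Xtr[te])
    ss_res = ((Ytr - cv_pred) ** 2).sum(axis=0)
    ss_tot = ((Ytr - Ytr.mean(axis=0)) ** 2).sum(axis=0)
    r2 = pd.Series(1.0 - ss_res / ss_tot, index=training_cells.columns, name="cv_r2")
    return pred_all, r2
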