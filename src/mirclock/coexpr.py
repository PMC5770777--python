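"""Surrogate-variable-adjusted miRNA-mRNA coexpression scanning.

Surrogate variables are the top left-singular vectors of the mRNA matrix
after removal of the modeled covariates, filtered to those associated with
at least one miRNA at the Bonferroni level (latent structure irrelevant to
the miRNA panel is not worth adjusting for).  The coexpression scan fits,
per (miRNA, mRNA) pair, the kinship mixed model with the mRNA as response
and the miRNA as tested covariate, then applies Benjamini-Hochberg FDR
across all pairs.  Because the miRNA input is Ct-scale, the expression-
scale sign of each association is the Ct-scale sign flipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mirclock.exceptions import AlignmentError, ConfigurationError
from mirclock.enrich import bh_fdr
from mirclock.lmm import KinshipEigen, reml_fit


@dataclass
class SVMatrix:
    """Per-sample surrogate-variable scores (orthonormal columns)."""

    values: pd.DataFrame
    singular_values: np.ndarray
    retained: list[str]
    selection: pd.DataFrame  # per SV: min association p across miRNAs, kept flag

    @property
    def n_sv(self) -> int:
        return self.values.shape[1]


def estimate_svs(
    mrna: pd.DataFrame,
    covariates: pd.DataFrame,
    n_sv: int = 10,
    mirna: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> SVMatrix:
    """Residual-SVD surrogate variables with the miRNA-association
    retention filter.

    When a Ct/residual miRNA matrix is given, an SV is retained only if it
    correlates with at least one miRNA at p < alpha / n_mirna; with no
    miRNA matrix all n_sv components are retained.
    """
    if n_sv >= min(mrna.shape):
        raise ConfigurationError(f"n_sv={n_sv} must be < min(mrna dims) {min(mrna.shape)}")
    X = covariates.to_numpy(dtype=float)
    Y = mrna.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    U, S, _ = np.linalg.svd(resid, full_matrices=False)
    sv = U[:, :n_sv]
    names = [f"SV{i + 1}" for i in range(n_sv)]

    if mirna is None:
        keep = [True] * n_sv
        minp = [np.nan] * n_sv
    else:
        if not mrna.index.equals(mirna.index):
            raise AlignmentError("mRNA and miRNA matrices have different samples")
        thr = alpha / mirna.shape[1]
        keep, minp = [], []
        M = mirna.to_numpy(dtype=float)
        n = M.shape[0]
        Mz = (M - M.mean(axis=0)) / np.where(M.std(axis=0) == 0, 1.0, M.std(axis=0))
        for k in range(n_sv):
            s = sv[:, k] - sv[:, k].mean()
            s = s / (s.std() if s.std() > 0 else 1.0)
            r = np.clip(Mz.T @ s / n, -1.0, 1.0)
            t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
            p = 2.0 * stats.t.sf(np.abs(t), n - 2)
            minp.append(float(p.min()))
            keep.append(bool((p < thr).any()))

    selection = pd.DataFrame({"sv": names, "min_p": minp, "kept": keep}).set_index("sv")
    kept_names = [nm for nm, k in zip(names, keep) if k]
    values = pd.DataFrame(sv, index=mrna.index, columns=names).loc[:, kept_names]
    return SVMatrix(
        values=values,
        singular_values=S[:n_sv],
        retained=kept_names,
        selection=selection,
    )


def coexpression_scan(
    mirna: pd.DataFrame,
    mrna: pd.DataFrame,
    covariates: pd.DataFrame,
    K: pd.DataFrame | KinshipEigen,
    svs: SVMatrix | pd.DataFrame | None = None,
    mirna_ids: list[str] | None = None,
    mrna_ids: list[str] | None = None,
    mirna_on_ct_scale: bool = True,
) -> pd.DataFrame:
    """Pairwise mixed-model coexpression scan with BH FDR over all pairs.

    ``covariates`` is an already-expanded design (intercept included);
    surrogate variables are appended to it.  The kinship eigendecomposition
    is computed once and shared by every pair.
    """
    if not mirna.index.equals(mrna.index):
        raise AlignmentError("miRNA and mRNA matrices have different samples")
    sv_df = svs.values if isinstance(svs, SVMatrix) else svs
    X0 = covariates if sv_df is None else pd.concat([covariates, sv_df], axis=1)
    if not X0.index.equals(mirna.index):
        raise AlignmentError("covariate design misaligned with expression matrices")
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen(
        K.loc[mirna.index, mirna.index]
    )
    mirna_ids = list(mirna.columns) if mirna_ids is None else mirna_ids
    mrna_ids = list(mrna.columns) if mrna_ids is None else mrna_ids

    X0t = eig.rotate(X0.to_numpy(dtype=float))
    names = list(X0.columns) + ["mirna"]
    rows = []
    for mir in mirna_ids:
        xt = eig.rotate(mirna[mir].to_numpy(dtype=float))
        Xt = np.column_stack([X0t, xt])
        for gene in mrna_ids:
            yt = eig.rotate(mrna[gene].to_numpy(dtype=float))
            fit = reml_fit(yt, Xt, eig, names=names, rotated=True)
            c = fit.coef("mirna")
            rows.append((mir, gene, c["beta"], c["se"], c["wald_p"]))
    out = pd.DataFrame(rows, columns=["mirna_id", "mrna_id", "beta", "se", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    sign = -np.sign(out["beta"]) if mirna_on_ct_scale else np.sign(out["beta"])
    out["expression_scale_sign"] = sign.astype(int)
    return out
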