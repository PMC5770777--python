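"""Per-miRNA differential expression versus chronological age.

Each miRNA's Ct value (or residual) is modeled in a kinship-aware linear
mixed model with age as the tested covariate.  On the Ct scale a positive
age slope means expression falls with age, so the reported direction is
``expression-down-with-age`` iff beta > 0.  Significance uses the
Bonferroni threshold alpha / m where m is the number of miRNAs actually
tested in the run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from mirclock.exceptions import AlignmentError, ConfigurationError
from mirclock.lmm import KinshipEigen, partial_r2, reml_fit
from mirclock.preprocess import design_matrix

DOWN = "expression-down-with-age"
UP = "expression-up-with-age"


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ConfigurationError(f"number of tests m={m} must be >= 1")
    return alpha / m


def diffexpr_scan(
    ct: pd.DataFrame,
    phen: pd.DataFrame,
    K: pd.DataFrame | KinshipEigen,
    covariates: list[str],
    alpha: float = 0.05,
    cell_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Scan every miRNA column for association with age.

    ``covariates`` are adjustment covariates (sex, technical variables);
    ``cell_counts`` switches on the sensitivity mode with imputed cell
    proportions as extra fixed effects.  The kinship eigendecomposition is
    computed once and reused across miRNAs.
    """
    _check_alignment("phenotypes", ct.index, phen.index)
    if isinstance(K, KinshipEigen):
        eig = K
        if list(ct.index) != list(eig.ids):
            raise AlignmentError("Ct sample order does not match kinship eigenbasis")
    else:
        _check_alignment("kinship", ct.index, K.index)
        eig = KinshipEigen(K.loc[ct.index, ct.index])

    X = design_matrix(phen.loc[ct.index], ["age"] + list(covariates))
    if cell_counts is not None:
        _check_alignment("cell counts", ct.index, cell_counts.index)
        cells = cell_counts.loc[ct.index]
        # proportions sum to 1: drop one column to keep the design full rank
        X = pd.concat([X, cells.iloc[:, 1:]], axis=1)

    Xt = eig.rotate(X.to_numpy(dtype=float))
    m = ct.shape[1]
    thr = bonferroni_threshold(alpha, m)
    rows = []
    for mirna in ct.columns:
        yt = eig.rotate(ct[mirna].to_numpy(dtype=float))
        fit = reml_fit(yt, Xt, eig, names=list(X.columns), rotated=True)
        c = fit.coef("age")
        rows.append(
            {
                "mirna_id": mirna,
                "beta": c["beta"],
                "se": c["se"],
                "r_squared": partial_r2(fit, "age"),
                "p": c["wald_p"],
                "h2": fit.h2,
                "significant": c["wald_p"] < thr,
                "direction": DOWN if c["beta"] > 0 else UP,
            }
        )
    out = pd.DataFrame(rows).set_index("mirna_id").sort_values("p")
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["n_tests"] = m
    return out


def replication_compare(
    table_a: pd.DataFrame, table_b: pd.DataFrame, threshold: float
) -> dict:
    """Discovery/replication concordance: correlation of effect sizes and
    of log10 p-values, replication fraction of set-A hits, and direction
    concordance."""
    common = table_a.index.intersection(table_b.index)
    if len(common) == 0:
        raise AlignmentError("no shared miRNAs between the two tables")
    a = table_a.loc[common]
    b = table_b.loc[common]
    beta_r = float(stats.pearsonr(a["beta"], b["beta"])[0])
    logp_r = float(stats.pearsonr(np.log10(a["p"]), np.log10(b["p"]))[0])
    hits_a = a.index[a["p"] < threshold]
    frac = float((b.loc[hits_a, "p"] < threshold).mean()) if len(hits_a) else np.nan
    direction = float((np.sign(a["beta"]) == np.sign(b["beta"])).mean())
    return {
        "n_common": int(len(common)),
        "beta_correlation": beta_r,
        "log10p_correlation": logp_r,
        "n_significant_a": int(len(hits_a)),
        "replication_fraction": frac,
        "direction_concordance": direction,
    }


def _check_alignment(what: str, expected: pd.Index, got: pd.Index) -> None:
    missing = expected.difference(got)
    if len(missing):
        raise AlignmentError(f"{what} missing samples, e.g. {list(missing[:5])}")
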