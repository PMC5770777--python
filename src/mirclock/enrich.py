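"""Enrichment statistics: BH FDR, hypergeometric upper tail, Fisher
exact gene-set enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirclock.exceptions import ConfigurationError


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for drawing n from N with K successes.

    Computed in log space so enrichment p-values far below float-underflow
    of the naive sum remain meaningful; use :func:`hypergeom_tail_log10`
    for the exponent itself.
    """
    _check_counts(N, K, n, k)
    if k == 0:
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def hypergeom_tail_log10(N: int, K: int, n: int, k: int) -> float:
    """log10 of the upper-tail probability (finite even when the p-value
    underflows a float)."""
    _check_counts(N, K, n, k)
    if k == 0:
        return 0.0
    return float(stats.hypergeom.logsf(k - 1, N, K, n) / np.log(10.0))


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ConfigurationError(
            f"inconsistent counts: N={N}, K={K}, n={n}, k={k} "
            "(need K,n <= N and k <= min(K, n))"
        )


def fisher_enrichment(
    hit_set: set[str], background: set[str], categories: dict[str, list[str]]
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``hit_set`` in each category.

    The 2x2 table per category is (hit / non-hit) x (in / out of the
    category), restricted to the background universe; BH FDR is applied
    across categories.
    """
    hits = set(hit_set)
    bg = set(background)
    stray = hits - bg
    if stray:
        raise ConfigurationError(f"hits outside background, e.g. {sorted(stray)[:5]}")
    if not categories:
        raise ConfigurationError("no categories supplied")
    N, n = len(bg), len(hits)
    rows = []
    for name, genes in categories.items():
        cat = set(genes) & bg
        K = len(cat)
        k = len(cat & hits)
        table = [[k, n - k], [K - k, (N - K) - (n - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "category": name,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "odds_ratio": odds,
                "p": max(p, np.finfo(float).tiny),
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p")
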