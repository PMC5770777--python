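"""Independent reference implementations used as test oracles.

These are deliberately written from the definitions (dense matrix algebra,
explicit loops) rather than sharing any code path with the package.
"""

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def reml_ll_dense(h2, y, X, K):
    """Dense-REML objective at a candidate h2: direct V inversion, no
    eigen-rotation."""
    n, p = X.shape
    V = h2 * K + (1.0 - h2) * np.eye(n)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = float(r @ Vi @ r) / (n - p)
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVX)
    return -0.5 * ((n - p) * (np.log(2 * np.pi * s2) + 1.0) + ld_v + ld_x)


def naive_efron_loglik(beta, times, events, x):
    """Direct-from-definition Efron partial log-likelihood for one
    covariate; quadratic time."""
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        dead = np.where((times == t) & (events == 1))[0]
        risk = np.where(times >= t)[0]
        m = len(dead)
        s_risk = np.exp(beta * x[risk]).sum()
        s_dead = np.exp(beta * x[dead]).sum()
        ll += beta * x[dead].sum()
        for l in range(m):
            ll -= np.log(s_risk - (l / m) * s_dead)
    return ll


def seed_site_oracle_counts(mirna, target):
    """Sliding-window seed-site classification applying the site
    definitions literally at every position."""
    mir = mirna.upper().replace("U", "T")
    tgt = target.upper().replace("U", "T")
    rc7 = mir[1:8].translate(_COMP)[::-1]
    rc6 = rc7[1:]
    counts = {"8mer": 0, "7mer-m8": 0, "7mer-A1": 0, "6mer": 0}
    for i in range(len(tgt)):
        if i + 6 > len(tgt) or tgt[i : i + 6] != rc6:
            continue
        m8 = i >= 1 and tgt[i - 1 : i + 6] == rc7
        a1 = i + 7 <= len(tgt) and tgt[i + 6] == "A"
        if m8 and a1:
            counts["8mer"] += 1
        elif m8:
            counts["7mer-m8"] += 1
        elif a1:
            counts["7mer-A1"] += 1
        else:
            counts["6mer"] += 1
    return counts
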