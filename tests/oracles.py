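"""Independent oracle implementations used by the test suite.

These deliberately avoid the package's solver paths: the REML oracle is
a 1-D profiled grid search over the variance ratio; the AUC oracle is a
brute-force concordant-pair count; the mixed-model-equations oracle
solves Henderson's equations directly.
"""

import numpy as np


def grid_reml_single_kernel(y, X, K, ratios=None, refine_rounds=3):
    """Profiled restricted likelihood over gamma = s2_k / s2_e on a grid.

    For V0 = gamma*K + I, sigma2_e is profiled out analytically; the
    grid is refined around the incumbent a few times.  Returns
    (sigma2_k, sigma2_e, restricted loglik).
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = y.size, X.shape[1]

    def profile_ll(gamma):
        V0 = gamma * K + np.eye(n)
        sign, logdetV0 = np.linalg.slogdet(V0)
        V0inv = np.linalg.inv(V0)
        XtV0X = X.T @ V0inv @ X
        b = np.linalg.solve(XtV0X, X.T @ V0inv @ y)
        r = y - X @ b
        q = float(r @ V0inv @ r)
        s2e = q / (n - p)
        _, logdetX = np.linalg.slogdet(XtV0X)
        ll = -0.5 * (
            logdetV0 + (n - p) * np.log(s2e) + logdetX + (n - p)
        )
        return ll, s2e

    grid = np.concatenate([[0.0], np.logspace(-4, 4, 161)]) \
        if ratios is None else np.asarray(ratios, float)
    for _ in range(refine_rounds):
        lls = np.array([profile_ll(g)[0] for g in grid])
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        if lo == hi:
            break
        best = grid[i]
        grid = np.unique(np.concatenate([
            [best], np.linspace(max(lo, 0.0), hi, 81)
        ]))
    ll, s2e = profile_ll(grid[np.argmax([profile_ll(g)[0] for g in grid])])
    gamma = grid[np.argmax([profile_ll(g)[0] for g in grid])]
    return gamma * s2e, s2e, ll


def auc_pairwise(scores, labels):
    """Brute-force AUC: concordant pairs + half ties over all pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (pos.size * neg.size)


def mme_predict(y_train, X_train, X_val, K_all, idx_train, idx_val,
                s2_u, s2_e, ridge=1e-8):
    """Henderson's mixed-model equations with validation records absent.

    The random effect covers all animals, u ~ N(0, K_all * s2_u), but
    only training animals contribute records: Z is the n_train x n_all
    incidence.  Returns u_hat for the validation animals.
    """
    n_all = K_all.shape[0]
    n_t = len(idx_train)
    Z = np.zeros((n_t, n_all))
    Z[np.arange(n_t), idx_train] = 1.0
    Kinv = np.linalg.inv(K_all + ridge * np.eye(n_all))
    lam = s2_e / s2_u
    top = np.hstack([X_train.T @ X_train, X_train.T @ Z])
    bot = np.hstack([Z.T @ X_train, Z.T @ Z + lam * Kinv])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([X_train.T @ y_train, Z.T @ y_train])
    sol = np.linalg.solve(lhs, rhs)
    u = sol[X_train.shape[1]:]
    return u[idx_val]
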