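"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation paths (and lifelines): the
product-limit curve is a hand-rolled running product, the log-rank test an
explicit O/E/V tabulation over distinct event times, and the Cox coefficient
a 1-D search over the log partial likelihood.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize


def km_oracle(times, events):
    """Product-limit S(t) at each distinct event time, by running product."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n
        out.append((t, n, d, s))
    return out


def logrank_oracle(times, events, groups):
    """Two-group log-rank chi2 by explicit observed/expected/variance sums."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    g1 = groups == labels[0]
    num = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(np.sum((times == t) & (events == 1)))
        d1 = int(np.sum((times == t) & (events == 1) & g1))
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num**2 / var


def cox_loglik(beta, times, events, x):
    """Log partial likelihood for one covariate, Breslow form (tie-free data)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_oracle(times, events, x):
    """Maximum-partial-likelihood coefficient by bounded 1-D minimisation."""
    res = scipy.optimize.minimize_scalar(
        lambda b: -cox_loglik(b, times, events, x),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def chi2_oracle(table):
    """Pearson chi-square from the textbook formula sum (O-E)^2 / E."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())


def kl_oracle(X, Y):
    """Generalised KL divergence by element-wise loop."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    total = 0.0
    for xij, yij in zip(X.ravel(), Y.ravel()):
        if xij > 0:
            total += xij * np.log(xij / yij) - xij + yij
        else:
            total += yij
    return total


def simplex_lsq_proportions(X, basis):
    """Simplex-constrained least squares H given the true basis (per sample)."""
    import scipy.optimize as opt

    r = basis.shape[1]
    scale = np.abs(X).mean() or 1.0
    Xs, Bs = X / scale, basis / scale
    out = np.zeros((r, X.shape[1]))
    cons = {"type": "eq", "fun": lambda h: h.sum() - 1}
    for j in range(X.shape[1]):
        res = opt.minimize(
            lambda h: np.sum((Xs[:, j] - Bs @ h) ** 2),
            np.full(r, 1.0 / r), bounds=[(0, 1)] * r, constraints=[cons],
            method="SLSQP", options={"ftol": 1e-14, "maxiter": 1000},
        )
        assert res.success, res.message
        out[:, j] = res.x
    return out
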