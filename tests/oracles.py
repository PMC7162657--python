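"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the code paths of the package implementation.
"""

import numpy as np
from scipy.linalg import expm, solve


def qp_direct_transcription_energy(
    a: np.ndarray,
    s_diag: np.ndarray,
    x0: np.ndarray,
    xt: np.ndarray,
    rho: float = 1.0,
    horizon: float = 1.0,
    steps: int = 400,
) -> float:
    """Optimal transition energy by direct transcription.

    Piecewise-constant inputs on a uniform grid, exact zero-order-hold
    discretization of the dynamics, quadratic cost, and a terminal equality
    constraint, solved as one KKT system.  Independent of the shooting
    solver: no augmented system, no costates.
    """
    n = a.shape[0]
    dt = horizon / steps
    ad = expm(a * dt)
    bd = solve(a, ad - np.eye(n))  # integral of e^{A s} ds for B = I
    powers = [np.eye(n)]
    for _ in range(steps):
        powers.append(ad @ powers[-1])
    nu = n * steps
    g = np.zeros((n * steps, nu))
    h = np.zeros(n * steps)
    for k in range(1, steps + 1):
        h[(k - 1) * n : k * n] = powers[k] @ x0
        for j in range(k):
            g[(k - 1) * n : k * n, j * n : (j + 1) * n] = powers[k - 1 - j] @ bd
    big_s = np.kron(np.eye(steps), np.diag(s_diag)) * dt
    q = g.T @ big_s @ g + rho * dt * np.eye(nu)
    xt_rep = np.tile(xt, steps)
    lin = -g.T @ big_s @ (xt_rep - h)
    a_eq = g[-n:, :]
    b_eq = xt - h[-n:]
    kkt = np.block([[q, a_eq.T], [a_eq, np.zeros((n, n))]])
    rhs = np.concatenate([-lin, b_eq])
    u = np.linalg.solve(kkt, rhs)[:nu].reshape(steps, n)
    return float((u**2).sum() * dt)


def bh_stepup_oracle(p: np.ndarray, q: float) -> np.ndarray:
    """Brute-force Benjamini-Hochberg rejection flags."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    return rejected


def partial_correlation_precision_oracle(x, y, covariates) -> float:
    """Partial correlation from the inverse of the full correlation matrix."""
    data = np.column_stack([x, y, covariates])
    corr = np.corrcoef(data, rowvar=False)
    prec = np.linalg.inv(corr)
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
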