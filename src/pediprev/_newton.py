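"""Newton solver for (optionally ridge-penalized) multinomial logit.

Shared by the binary missingness model (a two-category special case)
and the four-category imputation model.  The penalty is a Gaussian
prior of precision ``ridge`` on the columns flagged in ``penalize``
(intercepts are conventionally left unpenalized); ``ridge = 0`` gives
the plain MLE, which does not exist under (quasi-)separation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["penalized_multinomial"]


def penalized_multinomial(
    X: np.ndarray, y: np.ndarray, n_cat: int, ridge: float, penalize: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton solver for the (ridge-penalized) multinomial log-likelihood.

    Returns (beta_hat of shape (p, n_cat-1), covariance of the
    column-stacked coefficients, converged).  ``penalize`` is a 0/1
    vector over the design columns (0 for the intercept).
    """
    n, p = X.shape
    km1 = n_cat - 1
    Y = np.zeros((n, n_cat))
    Y[np.arange(n), y] = 1.0
    pen = ridge * np.tile(penalize.astype(float), km1)

    def probs(beta):
        eta = np.column_stack([np.zeros(n), X @ beta])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    def objective(beta_flat):
        beta = beta_flat.reshape((p, km1), order="F")
        eta = np.column_stack([np.zeros(n), X @ beta])
        lse = np.log(np.exp(eta - eta.max(axis=1, keepdims=True)).sum(axis=1)) + eta.max(axis=1)
        ll = float(np.sum(eta[np.arange(n), y]) - lse.sum())
        return ll - 0.5 * float(pen @ beta_flat**2)

    beta = np.zeros(p * km1)
    converged = False
    for _ in range(200):
        B = beta.reshape((p, km1), order="F")
        P = probs(B)
        grad = (X.T @ (Y[:, 1:] - P[:, 1:])).flatten(order="F") - pen * beta
        H = np.empty((km1 * p, km1 * p))
        for j in range(km1):
            for l in range(km1):
                w = P[:, j + 1] * ((1.0 if j == l else 0.0) - P[:, l + 1])
                H[j * p : (j + 1) * p, l * p : (l + 1) * p] = -(X.T * w) @ X
        H -= np.diag(pen)
        step = np.linalg.solve(H, -grad)
        # step-halving keeps the penalized log-likelihood increasing
        f0 = objective(beta)
        scale = 1.0
        for _half in range(30):
            new = beta + scale * step
            if objective(new) >= f0 - 1e-12:
                break
            scale *= 0.5
        moved = float(np.abs(new - beta).max())
        beta = new
        # gradient units are log-likelihood per unit coefficient; 1e-6 is
        # far below any statistical resolution, and a vanishing accepted
        # step means the objective is at float precision
        if np.abs(grad).max() < 1e-6 or moved < 1e-12:
            converged = True
            break
    cov = np.linalg.inv(-H)
    return beta.reshape((p, km1), order="F"), cov, converged
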