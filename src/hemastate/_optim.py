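"""Shared non-negative mixture fitting by multiplicative updates.

Both bulk deconvolution and mutational-signature refitting maximize a
(weighted) Poisson log-likelihood over a fixed non-negative basis:

    L(f) = sum_g w_g * [ b_g * log(lambda_g) - lambda_g ],   lambda = B f

with ``B`` a genes/channels x components basis and ``f >= 0`` free in
scale. The classic multiplicative KL-NMF update with the basis held
fixed,

    f_k <- f_k * (sum_g w_g B_gk b_g / lambda_g) / (sum_g w_g B_gk)

is monotone in L, so the objective is asserted non-decreasing each step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FixedBasisFit", "fit_fixed_basis_poisson"]

_EPS = 1e-12


@dataclass
class FixedBasisFit:
    coefficients: np.ndarray   # raw non-negative scale (sums approx. to total)
    fractions: np.ndarray      # coefficients normalized to sum 1
    loglik: float
    n_iter: int
    converged: bool


def _loglik(b, lam, w):
    lam = np.maximum(lam, _EPS)
    return float(np.sum(w * (b * np.log(lam) - lam)))


def fit_fixed_basis_poisson(b: np.ndarray, basis: np.ndarray,
                            weights: np.ndarray | None = None,
                            tol: float = 1e-8, max_iter: int = 10_000,
                            ) -> FixedBasisFit:
    """Maximize the weighted Poisson likelihood over non-negative mixture
    coefficients with the basis fixed.

    Deterministic: initialization spreads the observed total equally over
    the components. Convergence is a relative log-likelihood change below
    ``tol``; hitting ``max_iter`` flags ``converged=False`` but still
    returns the fit.
    """
    b = np.asarray(b, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if (b < 0).any():
        raise ValueError("observed counts must be non-negative")
    G, K = basis.shape
    if len(b) != G:
        raise ValueError("counts and basis row dimension differ")
    w = np.ones(G) if weights is None else np.asarray(weights, dtype=float)
    total = b.sum()
    if total <= 0:
        raise ValueError("counts sum to zero; nothing to fit")
    f = np.full(K, total / K)
    denom = (w[:, None] * basis).sum(axis=0)
    denom = np.maximum(denom, _EPS)
    ll = _loglik(b, basis @ f, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = np.maximum(basis @ f, _EPS)
        numer = basis.T @ (w * b / lam)
        f = f * numer / denom
        new_ll = _loglik(b, basis @ f, w)
        if new_ll < ll - 1e-6 * max(1.0, abs(ll)):
            raise RuntimeError("objective decreased; multiplicative update bug")
        if abs(new_ll - ll) <= tol * max(1.0, abs(ll)):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    fsum = f.sum()
    fractions = f / fsum if fsum > 0 else np.full(K, 1.0 / K)
    return FixedBasisFit(coefficients=f, fractions=fractions, loglik=ll,
                         n_iter=it, converged=converged)
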