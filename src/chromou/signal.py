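"""Phylogenetic signal statistics: Blomberg's K and Pagel's lambda.

Both compare the observed trait covariance with the Brownian expectation
implied by the tree's shared-time matrix C.  K is the ratio of the
observed mean-square ratio (ordinary over phylogenetically corrected) to
its Brownian expectation — K = 1 under BM, K << 1 for tree-independent
data.  lambda rescales the off-diagonal of C by a factor in [0, 1] and is
estimated by maximum likelihood: lambda = 1 is exactly the BM likelihood,
lambda = 0 the independent-observations likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, optimize

from .phylo import Phylogeny, time_matrices

__all__ = ["SignalResult", "blomberg_k", "pagel_lambda"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SignalResult:
    statistic: str
    value: float
    loglik: Optional[float] = None

    def to_dict(self) -> dict:
        d = {"statistic": self.statistic, "value": float(self.value)}
        if self.loglik is not None:
            d["loglik"] = float(self.loglik)
        return d


def _prep(tree: Phylogeny, y) -> tuple:
    y = np.asarray(y, dtype=float)
    n = tree.n_tips
    if n < 4:
        raise ValueError("signal statistics need at least 4 tips")
    if y.shape != (n,):
        raise ValueError("trait length does not match the number of tips")
    if np.ptp(y) == 0:
        raise ValueError("trait has zero variance")
    C = time_matrices(tree).shared_time
    return y, C, n


def blomberg_k(tree: Phylogeny, y) -> SignalResult:
    """Blomberg's K for a continuous trait (K = 1 expected under BM)."""
    y, C, n = _prep(tree, y)
    L = linalg.cho_factor(C, lower=True)[0]
    ones = np.ones(n)
    Ci_1 = linalg.cho_solve((L, True), ones)
    denom_1 = float(ones @ Ci_1)
    a_hat = float(Ci_1 @ y) / denom_1
    r = y - a_hat
    q0 = float(r @ r)
    q = float(r @ linalg.cho_solve((L, True), r))
    observed = q0 / q
    expected = (float(np.trace(C)) - n / denom_1) / (n - 1)
    return SignalResult(statistic="K", value=observed / expected)


def _lambda_loglik(lam: float, y, C, n) -> float:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    try:
        L = linalg.cho_factor(Cl, lower=True)[0]
    except linalg.LinAlgError:
        return -np.inf
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    a_hat = float(ones_w @ yw) / float(ones_w @ ones_w)
    q = float(np.sum((yw - a_hat * ones_w) ** 2))
    if q <= 0:
        return -np.inf
    s2 = q / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * _LOG2PI + n * np.log(s2) + logdet + n)


def pagel_lambda(tree: Phylogeny, y, tol: float = 1e-6) -> SignalResult:
    """ML estimate of Pagel's lambda on [0, 1] with its log-likelihood."""
    y, C, n = _prep(tree, y)
    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(lam, y, C, n),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = [(float(res.x), -float(res.fun))]
    for lam in (0.0, 1.0):
        candidates.append((lam, _lambda_loglik(lam, y, C, n)))
    lam_hat, ll = max(candidates, key=lambda t: t[1])
    return SignalResult(statistic="lambda", value=lam_hat, loglik=ll)
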