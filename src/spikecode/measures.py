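"""Association measures: coefficient of determination and KSG mutual information.

``ksg_mi`` is the Kraskov-Stogbauer-Grassberger estimator (variant 1): in the
joint space with the Chebyshev (max) metric, the distance to the k-th nearest
neighbor of each point sets a radius; counting how many neighbors fall
strictly inside that radius in each marginal gives

    I = psi(k) + psi(N) - < psi(n_x + 1) + psi(n_y + 1) >

in nats, converted here to bits.  ``mi_discrete_continuous`` is the companion
estimator for a discrete variable against a continuous one (Ross 2014):
neighbor distances are computed within each discrete class and neighbor
counts over the full sample,

    I = psi(N) + psi(k) - < psi(n_class) > - < psi(m_i) >.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .errors import ValidationError

__all__ = ["r_squared", "ksg_mi", "mi_discrete_continuous"]


def r_squared(s: np.ndarray, s_hat: np.ndarray) -> float:
    """Coefficient of determination, averaged over stimulus components.

    ``1 - SSE/SST`` per component; at most 1, unbounded below.
    """
    s = np.asarray(s, dtype=np.float64)
    s_hat = np.asarray(s_hat, dtype=np.float64)
    if s.ndim == 1:
        s = s[:, None]
    if s_hat.ndim == 1:
        s_hat = s_hat[:, None]
    if s.shape != s_hat.shape:
        raise ValidationError(f"shape mismatch {s.shape} vs {s_hat.shape}")
    sst = np.sum((s - s.mean(axis=0)) ** 2, axis=0)
    if np.any(sst <= 0):
        raise ValidationError("zero-variance target: R^2 undefined")
    sse = np.sum((s - s_hat) ** 2, axis=0)
    return float(np.mean(1.0 - sse / sst))


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    return x


def ksg_mi(x: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """KSG (variant 1) mutual information estimate in bits.

    Parameters
    ----------
    x, y : (N,) or (N, d) sample matrices with equal N >= k + 2.
    k : neighbor count.
    """
    x, y = _as_2d(x), _as_2d(y)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValidationError("x and y must have the same number of samples")
    if n < k + 2:
        raise ValidationError(f"need at least k+2={k + 2} samples, got {n}")
    joint = np.hstack([x, y])
    tree_joint = cKDTree(joint)
    # distance to the k-th neighbor (excluding self) in the max metric
    dist, _ = tree_joint.query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    tree_x, tree_y = cKDTree(x), cKDTree(y)
    nx = np.array(tree_x.query_ball_point(x, eps - 1e-12, p=np.inf,
                                          return_length=True)) - 1
    ny = np.array(tree_y.query_ball_point(y, eps - 1e-12, p=np.inf,
                                          return_length=True)) - 1
    val = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(val / np.log(2.0))


def mi_discrete_continuous(d: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """Mutual information (bits) between a discrete ``d`` and continuous ``y``.

    Points whose class has fewer than 2 members are excluded (no within-class
    neighbor exists); classes with 1 < size <= k use the largest feasible k.
    """
    d = np.asarray(d)
    y = _as_2d(y)
    n = d.shape[0]
    if y.shape[0] != n:
        raise ValidationError("d and y must have the same number of samples")
    if n < k + 2:
        raise ValidationError(f"need at least k+2={k + 2} samples, got {n}")
    tree_all = cKDTree(y)
    psi_terms = []
    for label in np.unique(d):
        mask = d == label
        n_c = int(mask.sum())
        if n_c < 2:
            continue
        k_c = min(k, n_c - 1)
        yc = y[mask]
        tree_c = cKDTree(yc)
        dist, _ = tree_c.query(yc, k=k_c + 1, p=np.inf)
        eps = dist[:, -1]
        m = np.array(tree_all.query_ball_point(yc, eps + 1e-12, p=np.inf,
                                               return_length=True)) - 1
        m = np.maximum(m, k_c)
        psi_terms.append(digamma(k_c) - digamma(n_c) - digamma(m))
    if not psi_terms:
        return 0.0
    avg = np.mean(np.concatenate(psi_terms))
    n_used = sum(t.size for t in psi_terms)
    val = digamma(n_used) + avg
    return float(val / np.log(2.0))
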