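"""Core model equations.

Resource flow and growth follow three rules:

1. *Resource acquisition*: niche ``j`` supplies resources at rate ``p_j``,
   split among species proportionally to affinity-weighted abundance,
   ``r_ij = a_ij c_i / (sum_k a_kj c_k) * p_j`` (zero when the niche is
   uncontested).
2. *Carrying capacity*: ``k_i = v_i * sum_j r_ij`` — acquired resources are
   scaled into a sustainable cell count by the species' utilization
   efficiency.
3. *Logistic growth with dynamic capacity*:
   ``dc_i/dt = c_i / tau * (1 - c_i / k_i)`` when ``k_i > 0``, else 0.

The affinity matrix has block structure: each species has unspecific
affinity ``u`` to every niche plus an additional specific affinity ``s`` to
its preferred niche (niche ``i`` for clone ``i``, requiring ``n == q``).
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig

__all__ = [
    "build_affinity_matrix",
    "resource_rates",
    "carrying_capacities",
    "growth_rhs",
    "model_rhs",
]


def build_affinity_matrix(config: ModelConfig) -> np.ndarray:
    """Build the ``m x n`` niche affinity matrix.

    Rows ``0..q-1`` are healthy species, rows ``q..2q-1`` preleukemic.
    Entry ``(i, j)`` is ``u + s`` if niche ``j`` is species ``i``'s preferred
    niche (``j == i mod q``) and ``u`` otherwise.  Defined only for
    ``n == q`` (one preferred niche per clone).
    """
    if config.n != config.q:
        raise ValueError(
            f"affinity matrix construction requires n == q, got n={config.n}, q={config.q}"
        )
    q = config.q
    eye = np.eye(q)
    a_h = np.full((q, q), config.u_h) + config.s_h * eye
    a_p = np.full((q, q), config.u_p) + config.s_p * eye
    return np.vstack([a_h, a_p])


def resource_rates(a: np.ndarray, c: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Resource acquisition rates ``r_ij`` (an ``m x n`` matrix).

    Each niche's supply ``p_j`` is divided among species in proportion to
    ``a_ij c_i``; a niche with no positive-affinity, positive-abundance
    competitor distributes nothing (all-zero column).
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    p = np.asarray(p, dtype=float)
    if a.shape != (c.shape[0], p.shape[0]):
        raise ValueError(
            f"dimension mismatch: a {a.shape}, c {c.shape}, p {p.shape}"
        )
    weights = a * c[:, None]
    denom = weights.sum(axis=0)
    contested = denom > 0
    r = np.zeros_like(a)
    r[:, contested] = weights[:, contested] / denom[contested] * p[contested]
    return r


def carrying_capacities(r: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Carrying capacities ``k_i = v_i * sum_j r_ij``."""
    r = np.asarray(r, dtype=float)
    v = np.asarray(v, dtype=float)
    if r.shape[0] != v.shape[0]:
        raise ValueError(f"dimension mismatch: r {r.shape}, v {v.shape}")
    return v * r.sum(axis=1)


def growth_rhs(c: np.ndarray, k: np.ndarray, tau: float) -> np.ndarray:
    """Logistic time derivative ``dc_i/dt``.

    ``(c_i / tau)(1 - c_i / k_i)`` where ``k_i > 0``; exactly 0 where
    ``k_i == 0`` (a species without resources neither grows nor decays in
    this model) and where ``c_i == 0`` (extinction is absorbing).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    c = np.asarray(c, dtype=float)
    k = np.asarray(k, dtype=float)
    dc = np.zeros_like(c)
    alive = (k > 0) & (c != 0)
    dc[alive] = c[alive] / tau * (1.0 - c[alive] / k[alive])
    return dc


def model_rhs(c: np.ndarray, a: np.ndarray, p: np.ndarray, v: np.ndarray,
              tau: float) -> np.ndarray:
    """Full right-hand side: compose resource acquisition, carrying
    capacities and logistic growth for the current state."""
    r = resource_rates(a, c, p)
    k = carrying_capacities(r, v)
    return growth_rhs(c, k, tau)
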