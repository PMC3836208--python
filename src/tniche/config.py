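"""Model configuration.

The model describes ``q`` T-cell clones competing for resources supplied by
``n`` niches (distinct self-peptide--MHC complexes).  Each clone is split into
a healthy and a preleukemic *species*, so the system tracks ``m = 2q``
species.  Healthy species share one parameter triple (specific affinity
``s_h``, unspecific affinity ``u_h``, resource utilization efficiency
``v_h``); preleukemic species share another (``s_p``, ``u_p``, ``v_p``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelConfig", "default_config"]

#: Keys accepted in flat config files, in canonical order.
_CONFIG_KEYS = ("n", "q", "p", "tau", "s_h", "u_h", "v_h", "s_p", "u_p", "v_p")


@dataclass
class ModelConfig:
    """All scalar/vector parameters of the niche-competition model.

    Parameters
    ----------
    n : int
        Number of niches.
    q : int
        Number of TCR-defined clones.  The number of species is ``m = 2q``.
    p : float or array of shape (n,)
        Niche resource supply rates (resource units per hour).  A scalar
        means a constant vector.
    tau : float
        Minimum cell cycle time in hours.
    s_h, u_h, v_h : float
        Specific affinity, unspecific affinity and resource utilization
        efficiency of the healthy species.
    s_p, u_p, v_p : float
        The same three parameters for the preleukemic species.
    """

    n: int = 100
    q: int = 100
    p: float | np.ndarray = 100.0
    tau: float = 8.0
    s_h: float = 1.0
    u_h: float = 0.01
    v_h: float = 1.0
    s_p: float = 1.0
    u_p: float = 0.01
    v_p: float = 1.0

    p_vector: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n < 1 or self.q < 1:
            raise ValueError("n and q must be positive integers")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        for name in ("s_h", "u_h", "v_h", "s_p", "u_p", "v_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if p.size == 1:
            p = np.full(self.n, float(p[0]))
        if p.shape != (self.n,):
            raise ValueError(f"p must be scalar or length-{self.n}, got shape {p.shape}")
        if np.any(p < 0):
            raise ValueError("all niche supply rates p_j must be >= 0")
        object.__setattr__(self, "p_vector", p)

    @property
    def m(self) -> int:
        """Number of species (healthy + preleukemic), always ``2q``."""
        return 2 * self.q

    @property
    def v_vector(self) -> np.ndarray:
        """Per-species efficiency vector ``(v_h, ..., v_h, v_p, ..., v_p)``."""
        return np.concatenate(
            [np.full(self.q, self.v_h), np.full(self.q, self.v_p)]
        )

    @property
    def reference_total(self) -> float:
        """Physiological total cell count ``v_h * sum_j p_j``."""
        return self.v_h * float(self.p_vector.sum())

    def with_folds(self, s_fold: float, u_fold: float, v_fold: float) -> "ModelConfig":
        """Return a copy with preleukemic parameters set as fold-changes of
        the healthy ones: ``s_p = s_fold * s_h`` etc."""
        return replace(
            self,
            s_p=s_fold * self.s_h,
            u_p=u_fold * self.u_h,
            v_p=v_fold * self.v_h,
        )

    # -- flat-file round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _CONFIG_KEYS}
        p = self.p_vector
        d["p"] = float(p[0]) if np.all(p == p[0]) else [float(x) for x in p]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        unknown = set(d) - set(_CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)


def default_config() -> ModelConfig:
    """The reference parameterization: 100 niches, 100 clones, p_j = 100,
    tau = 8 h, s_h = 1, u_h = 1/n = 0.01, v_h = 1, and preleukemic species
    identical to healthy (all fold-changes 1)."""
    return ModelConfig()
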