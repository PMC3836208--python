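"""Transplantation initial conditions and ODE integration.

The in-silico transplantation puts 500 cells into an empty system.  In the
polyclonal case the healthy cells are spread over all ``q`` healthy species
(evenly, or by a seeded multinomial draw) and any preleukemic cells are
seeded one per preleukemic species; in the monoclonal case everything sits
in clone 1 (healthy species 1 and preleukemic species q+1).

Integration runs the full 2q-species system with an adaptive solver, samples
the state on a fixed checkpoint grid, and declares steady state when the
relative change of every species abundance between successive checkpoints
falls below ``rel_change_tol``.  Abundances below ``abundance_floor`` are
clamped to exactly 0 at checkpoints so that the zero branches of the
dynamics engage and extinct species do not distort the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .config import ModelConfig
from .model import build_affinity_matrix, model_rhs

__all__ = [
    "TransplantSpec",
    "IntegrationSettings",
    "KillEvent",
    "Trajectory",
    "make_initial_state",
    "apply_cell_kill",
    "integrate",
    "run_physiological",
]

Clonality = Literal["monoclonal", "polyclonal"]

#: Number of initial preleukemic cells in each screening scenario.
SCENARIOS = {"P1": 1, "P10": 10, "P100": 100}


@dataclass(frozen=True)
class TransplantSpec:
    """Definition of one in-silico transplantation."""

    total_cells: int = 500
    n_preleukemic: int = 0
    clonality: Clonality = "polyclonal"
    allocation_mode: Literal["even", "multinomial"] = "even"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.total_cells <= 0:
            raise ValueError("total_cells must be positive")
        if not 0 <= self.n_preleukemic <= self.total_cells:
            raise ValueError("n_preleukemic must be in [0, total_cells]")
        if self.clonality not in ("monoclonal", "polyclonal"):
            raise ValueError(f"unknown clonality {self.clonality!r}")
        if self.allocation_mode not in ("even", "multinomial"):
            raise ValueError(f"unknown allocation_mode {self.allocation_mode!r}")


@dataclass(frozen=True)
class IntegrationSettings:
    """Numerical settings for integration and steady-state detection."""

    rel_change_tol: float = 1e-6
    check_interval: float = 1.0      # hours between convergence checkpoints
    t_max: float = 1e6               # hours; cap when convergence is not reached
    rtol: float = 1e-8
    atol: float = 1e-10
    abundance_floor: float = 1e-9    # cells; below this a species is extinct

    def __post_init__(self) -> None:
        if self.rel_change_tol <= 0:
            raise ValueError("rel_change_tol must be > 0")
        if self.check_interval <= 0 or self.t_max < self.check_interval:
            raise ValueError("need t_max >= check_interval > 0")
        if self.abundance_floor < 0:
            raise ValueError("abundance_floor must be >= 0")


@dataclass(frozen=True)
class KillEvent:
    """Proportional cell kill: at time ``t`` every abundance is scaled by
    ``1 - fraction``."""

    time: float
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("kill fraction must be in [0, 1]")


@dataclass
class Trajectory:
    """Checkpoint-sampled solution of one run."""

    times: np.ndarray            # (T,), hours
    states: np.ndarray           # (T, m), cells
    converged: bool
    t_converged: float | None = None

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def state_at(self, t: float) -> np.ndarray:
        """State at the checkpoint closest to ``t``."""
        return self.states[int(np.argmin(np.abs(self.times - t)))]


def clone_initial_counts(spec: TransplantSpec, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer initial cell counts per clone.

    Returns ``(h0, z0)`` of length ``q``: healthy and preleukemic cells of
    each clone.  Even mode distributes the healthy cells as equally as
    possible, assigning the remainder to the lowest clone indices;
    multinomial mode makes one uniform multinomial draw (seed required).
    """
    n_h = spec.total_cells - spec.n_preleukemic
    h0 = np.zeros(q, dtype=np.int64)
    z0 = np.zeros(q, dtype=np.int64)
    if spec.clonality == "monoclonal":
        h0[0] = n_h
        z0[0] = spec.n_preleukemic
        return h0, z0
    if spec.n_preleukemic > q:
        raise ValueError(
            f"polyclonal transplant needs n_preleukemic <= q ({spec.n_preleukemic} > {q})"
        )
    z0[: spec.n_preleukemic] = 1
    if spec.allocation_mode == "even":
        base, rem = divmod(n_h, q)
        h0[:] = base
        h0[:rem] += 1
    else:
        if spec.seed is None:
            raise ValueError("multinomial allocation requires a seed")
        rng = np.random.default_rng(spec.seed)
        h0[:] = rng.multinomial(n_h, np.full(q, 1.0 / q))
    return h0, z0


def make_initial_state(spec: TransplantSpec, config: ModelConfig) -> np.ndarray:
    """Initial abundance vector ``c0`` of length ``m = 2q``."""
    h0, z0 = clone_initial_counts(spec, config.q)
    return np.concatenate([h0, z0]).astype(float)


def apply_cell_kill(c: np.ndarray, fraction: float) -> np.ndarray:
    """Scale every species abundance by ``1 - fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("kill fraction must be in [0, 1]")
    return np.asarray(c, dtype=float) * (1.0 - fraction)


def _check_convergence(prev: np.ndarray, cur: np.ndarray,
                       settings: IntegrationSettings) -> bool:
    denom = np.maximum(prev, settings.abundance_floor)
    return bool(np.max(np.abs(cur - prev) / denom) < settings.rel_change_tol)


# Integration proceeds in multi-checkpoint chunks: one solve_ivp call per
# chunk keeps solver overhead low; the live state is floor-clamped at chunk
# boundaries, stored checkpoints are clamped everywhere.  Chunks grow
# geometrically so that runs with slow transients stay cheap.
_CHUNK_CHECKPOINTS = 32
_CHUNK_CHECKPOINTS_MAX = 4096


def integrate(
    config: ModelConfig,
    c0: np.ndarray,
    settings: IntegrationSettings | None = None,
    events: Sequence[KillEvent] = (),
    stop_on_convergence: bool = True,
    t_end: float | None = None,
    store_trajectory: bool = True,
) -> Trajectory:
    """Integrate the full system from ``c0``.

    The state is sampled at every multiple of ``check_interval``.  With
    ``stop_on_convergence`` the run ends at the first checkpoint where the
    relative change of all abundances since the previous checkpoint is below
    ``rel_change_tol``; otherwise it runs to ``t_end`` (default ``t_max``).
    ``events`` are proportional cell kills applied at the stated times.
    """
    settings = settings or IntegrationSettings()
    horizon = float(t_end if t_end is not None else settings.t_max)
    if horizon < settings.check_interval:
        raise ValueError("horizon must cover at least one check interval")
    a = build_affinity_matrix(config)
    p, v, tau = config.p_vector, config.v_vector, config.tau
    floor = settings.abundance_floor

    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        return model_rhs(np.maximum(c, 0.0), a, p, v, tau)

    events = sorted(events, key=lambda e: e.time)
    for ev in events:
        if not 0.0 <= ev.time <= horizon:
            raise ValueError(f"event time {ev.time} outside [0, {horizon}]")

    dt = settings.check_interval
    c = np.asarray(c0, dtype=float).copy()
    c[c < floor] = 0.0
    times = [0.0]
    states = [c.copy()]
    prev = c.copy()  # state at the most recent checkpoint
    converged = False
    t_converged = None
    t = 0.0
    ev_queue = list(events)
    chunk_len = _CHUNK_CHECKPOINTS

    while t < horizon - 1e-9 and not (converged and stop_on_convergence):
        # segment ends at the next event or the horizon
        seg_end = ev_queue[0].time if ev_queue else horizon
        seg_end = min(seg_end, horizon)
        if seg_end <= t + 1e-9:
            c = apply_cell_kill(c, ev_queue.pop(0).fraction)
            c[c < floor] = 0.0
            prev = c.copy()  # checkpoint state right after the event
            states[-1] = c.copy()
            chunk_len = _CHUNK_CHECKPOINTS
            continue
        chunk_end = min(t + chunk_len * dt, seg_end)
        # checkpoints strictly inside (t, chunk_end]
        n_steps = int(np.round((chunk_end - t) / dt))
        t_eval = t + dt * np.arange(1, n_steps + 1)
        t_eval = t_eval[t_eval <= chunk_end + 1e-9]
        if t_eval.size == 0 or abs(t_eval[-1] - chunk_end) > 1e-9:
            t_eval = np.append(t_eval, chunk_end)
        sol = solve_ivp(
            rhs, (t, chunk_end), c, method="RK45",
            t_eval=t_eval, rtol=settings.rtol, atol=settings.atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failure at t={sol.t[-1] if sol.t.size else t}: "
                f"{sol.message}; state={c}"
            )
        for ti, ci in zip(sol.t, sol.y.T):
            ci = ci.copy()
            ci[ci < floor] = 0.0
            if not converged and _check_convergence(prev, ci, settings):
                converged = True
                t_converged = float(ti)
            prev = ci
            if store_trajectory:
                times.append(float(ti))
                states.append(ci)
            if converged and stop_on_convergence:
                break
        c = prev.copy()
        t = float(sol.t[-1]) if not (converged and stop_on_convergence) else (
            t_converged if t_converged is not None else float(sol.t[-1])
        )
        chunk_len = min(chunk_len * 2, _CHUNK_CHECKPOINTS_MAX)

    if not store_trajectory:
        times.append(t)
        states.append(c.copy())
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        converged=converged,
        t_converged=t_converged,
    )


def run_physiological(
    clonality: Clonality,
    config: ModelConfig | None = None,
    settings: IntegrationSettings | None = None,
    kill_time: float = 200.0,
    kill_fraction: float = 0.99,
    t_end: float = 400.0,
) -> Trajectory:
    """Healthy-only transplantation with a perturbation.

    500 cells are transplanted into an empty system, evolve for ``t_end``
    hours, and ``kill_fraction`` of all cells is removed at ``kill_time``.
    The system re-approaches its pre-kill steady state afterwards.
    """
    config = config or ModelConfig()
    spec = TransplantSpec(n_preleukemic=0, clonality=clonality)
    c0 = make_initial_state(spec, config)
    return integrate(
        config, c0, settings,
        events=[KillEvent(kill_time, kill_fraction)],
        stop_on_convergence=False,
        t_end=t_end,
    )
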