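"""Parameter-space screen over preleukemic cell properties.

The screen varies the three preleukemic parameters (specific affinity,
unspecific affinity, resource utilization efficiency) as fold-changes of
their healthy counterparts on a 41-point geometric grid (neighbor ratio
1.2, centered on 1, spanning roughly 1/40 to 40).  For every fold triple and
every transplantation scenario (P1/P10/P100 = 1/10/100 initial preleukemic
cells) both the monoclonal and the polyclonal transplantation are run to
steady state and classified:

* monoclonal run *premalignant*: total cell count at least 300% of the
  physiological count and preleukemic cells at least 80% of the total;
* polyclonal run *controlled*: total at most 120% of physiological and
  preleukemic contribution at most 50%.

A parameter set is *consistent* with the transformation-assay observation
(monoclonal grafts transform, polyclonal grafts do not) when its monoclonal
run is premalignant and its polyclonal run is controlled.

Runs use the symmetry-reduced system (see :mod:`tniche._reduced`) whenever
the initial condition is clone-class symmetric, which covers both allocation
modes; the full 2q-species path in :mod:`tniche.simulate` serves as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._reduced import integrate_reduced_batch, reduce_classes
from .config import ModelConfig
from .simulate import (
    SCENARIOS,
    IntegrationSettings,
    TransplantSpec,
    clone_initial_counts,
    integrate,
    make_initial_state,
)

__all__ = [
    "ClassificationThresholds",
    "make_fold_grid",
    "classify_outcome",
    "evaluate_parameter_set",
    "run_screen",
    "SCREEN_COLUMNS",
]

#: Cap for screen runs, in hours.  Effectively "integrate until the
#: steady-state criterion triggers"; runs that still change faster than the
#: criterion allows after this horizon are flagged as not converged.
SCREEN_T_MAX = 1e7


@dataclass(frozen=True)
class ClassificationThresholds:
    """Classification criteria for screen outcomes.

    Fractions are relative to ``reference_total``, the physiological total
    cell count ``v_h * sum_j p_j``.  All bounds are inclusive.
    """

    mono_min_total_frac: float = 3.0
    mono_min_prelk_frac: float = 0.8
    poly_max_total_frac: float = 1.2
    poly_max_prelk_frac: float = 0.5
    reference_total: float = 1e4

    def __post_init__(self) -> None:
        for name in ("mono_min_total_frac", "mono_min_prelk_frac",
                     "poly_max_total_frac", "poly_max_prelk_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.poly_max_prelk_frac >= self.mono_min_prelk_frac:
            raise ValueError(
                "poly_max_prelk_frac must be below mono_min_prelk_frac"
            )
        if self.reference_total <= 0:
            raise ValueError("reference_total must be positive")

    @classmethod
    def from_config(cls, config: ModelConfig, **kwargs) -> "ClassificationThresholds":
        return cls(reference_total=config.reference_total, **kwargs)


def make_fold_grid(n_values: int = 41, step: float = 1.2) -> np.ndarray:
    """Geometric fold-change grid ``step**k`` for
    ``k = -(n_values-1)/2 .. (n_values-1)/2``, ascending and centered on 1.
    """
    if n_values < 1 or n_values % 2 == 0:
        raise ValueError("n_values must be a positive odd integer")
    if step <= 1:
        raise ValueError("step must be > 1")
    half = (n_values - 1) // 2
    return step ** np.arange(-half, half + 1, dtype=float)


def classify_outcome(
    final_state: np.ndarray,
    config: ModelConfig,
    thresholds: ClassificationThresholds,
    clonality: str,
) -> tuple[bool, float, float]:
    """Classify a final state.

    Returns ``(flag, total, prelk_frac)`` where ``flag`` is *premalignant*
    for a monoclonal run and *controlled* for a polyclonal one.  An empty
    system has preleukemic fraction 0 by convention (trivially controlled,
    never premalignant).
    """
    c = np.asarray(final_state, dtype=float)
    total = float(c.sum())
    prelk = float(c[config.q:].sum())
    frac = prelk / total if total > 0 else 0.0
    ref = thresholds.reference_total
    if clonality == "monoclonal":
        flag = (total >= thresholds.mono_min_total_frac * ref
                and frac >= thresholds.mono_min_prelk_frac)
    elif clonality == "polyclonal":
        flag = (total <= thresholds.poly_max_total_frac * ref
                and frac <= thresholds.poly_max_prelk_frac)
    else:
        raise ValueError(f"unknown clonality {clonality!r}")
    return flag, total, frac


def _require_scalar_p(config: ModelConfig) -> float:
    p = config.p_vector
    if not np.all(p == p[0]):
        raise ValueError("the reduced fast path requires a constant niche supply vector")
    return float(p[0])


def _reduced_batch_for(
    scenario: str,
    clonality: str,
    config: ModelConfig,
    settings: IntegrationSettings,
    s_p: np.ndarray,
    u_p: np.ndarray,
    v_p: np.ndarray,
    allocation_mode: str = "even",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run one (scenario, clonality) batch through the reduced integrator.

    Returns ``(totals, prelk_fracs, converged, t_conv, Ng)``.
    """
    spec = TransplantSpec(
        n_preleukemic=SCENARIOS[scenario],
        clonality=clonality,
        allocation_mode=allocation_mode,
        seed=seed,
    )
    h0, z0 = clone_initial_counts(spec, config.q)
    Ng, h0c, z0c = reduce_classes(h0, z0)
    hf, zf, conv, tconv = integrate_reduced_batch(
        Ng, h0c, z0c, s_p, u_p, v_p,
        s_h=config.s_h, u_h=config.u_h, v_h=config.v_h,
        p=_require_scalar_p(config), tau=config.tau,
        rel_change_tol=settings.rel_change_tol,
        check_interval=settings.check_interval,
        t_max=SCREEN_T_MAX,
        abundance_floor=settings.abundance_floor,
        rtol=settings.rtol, atol=settings.atol,
    )
    healthy = hf @ Ng.astype(float)
    prelk = zf @ Ng.astype(float)
    totals = healthy + prelk
    fracs = np.where(totals > 0, prelk / np.maximum(totals, 1e-300), 0.0)
    return totals, fracs, conv, tconv, Ng


def evaluate_parameter_set(
    s_fold: float,
    u_fold: float,
    v_fold: float,
    scenario: str,
    config: ModelConfig | None = None,
    settings: IntegrationSettings | None = None,
    thresholds: ClassificationThresholds | None = None,
    allocation_mode: str = "even",
    seed: int | None = None,
    method: str = "reduced",
) -> dict:
    """Evaluate one fold-change triple for one scenario.

    Runs the monoclonal and polyclonal transplantations to steady state
    (``method="reduced"`` uses the symmetry-reduced fast path,
    ``method="full"`` the full 2q-species integrator) and classifies both.
    Returns a screen record dict.
    """
    if min(s_fold, u_fold, v_fold) <= 0:
        raise ValueError("fold-changes must be positive")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    config = config or ModelConfig()
    settings = settings or IntegrationSettings()
    thresholds = thresholds or ClassificationThresholds.from_config(config)
    pconfig = config.with_folds(s_fold, u_fold, v_fold)

    rec: dict = {
        "scenario": scenario,
        "s_fold": s_fold,
        "u_fold": u_fold,
        "v_fold": v_fold,
        "s_h_used": config.s_h,
    }
    for clonality, key in (("monoclonal", "mono"), ("polyclonal", "poly")):
        try:
            if method == "reduced":
                totals, fracs, conv, _, _ = _reduced_batch_for(
                    scenario, clonality, pconfig, settings,
                    np.array([pconfig.s_p]), np.array([pconfig.u_p]),
                    np.array([pconfig.v_p]),
                    allocation_mode=allocation_mode, seed=seed,
                )
                total, frac, converged = totals[0], fracs[0], bool(conv[0])
                flag = classify_outcome(
                    _totals_to_state(total, frac, pconfig), pconfig,
                    thresholds, clonality,
                )[0]
            elif method == "full":
                spec = TransplantSpec(
                    n_preleukemic=SCENARIOS[scenario], clonality=clonality,
                    allocation_mode=allocation_mode, seed=seed,
                )
                c0 = make_initial_state(spec, pconfig)
                traj = integrate(pconfig, c0, settings)
                flag, total, frac = classify_outcome(
                    traj.final_state, pconfig, thresholds, clonality
                )
                converged = traj.converged
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as exc:
            raise RuntimeError(
                f"run failed at scenario={scenario} folds=({s_fold}, {u_fold}, "
                f"{v_fold}) clonality={clonality}: {exc}"
            ) from exc
        rec[f"{key}_total"] = float(total)
        rec[f"{key}_prelk_frac"] = float(frac)
        rec[f"{key}_converged"] = converged
        rec[f"{key}_flag"] = flag
    rec["mono_premalignant"] = rec.pop("mono_flag")
    rec["poly_controlled"] = rec.pop("poly_flag")
    rec["consistent"] = rec["mono_premalignant"] and rec["poly_controlled"]
    return rec


def _totals_to_state(total: float, frac: float, config: ModelConfig) -> np.ndarray:
    """Minimal state vector reproducing a (total, preleukemic fraction)
    pair, for reuse of :func:`classify_outcome` on reduced-path results."""
    c = np.zeros(config.m)
    c[0] = total * (1.0 - frac)
    c[config.q] = total * frac
    return c


SCREEN_COLUMNS = [
    "scenario", "s_fold", "u_fold", "v_fold", "s_h_used",
    "mono_total", "mono_prelk_frac", "poly_total", "poly_prelk_frac",
    "mono_converged", "poly_converged",
    "mono_premalignant", "poly_controlled", "consistent",
]


def _classify_batch(
    thresholds: ClassificationThresholds,
    mono_totals: np.ndarray, mono_fracs: np.ndarray,
    poly_totals: np.ndarray, poly_fracs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    ref = thresholds.reference_total
    mono = ((mono_totals >= thresholds.mono_min_total_frac * ref)
            & (mono_fracs >= thresholds.mono_min_prelk_frac))
    poly = ((poly_totals <= thresholds.poly_max_total_frac * ref)
            & (poly_fracs <= thresholds.poly_max_prelk_frac))
    return mono, poly


def run_screen(
    scenarios: Sequence[str] = ("P1", "P10", "P100"),
    s_h_values: Sequence[float] = (1.0,),
    config: ModelConfig | None = None,
    settings: IntegrationSettings | None = None,
    thresholds: ClassificationThresholds | None = None,
    grid: np.ndarray | None = None,
    allocation_mode: str = "even",
    seed: int | None = None,
    out_dir: str | Path | None = None,
    resume: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full mono/polyclonal screen.

    One record per (s_h value, scenario, fold-change triple), in
    deterministic order: s_h, then scenario, then lexicographic
    ``(s_fold, u_fold, v_fold)`` grid index.  With ``out_dir`` each
    (s_h, scenario) block is written to a CSV part file as it completes;
    with ``resume=True`` existing part files are loaded instead of rerun.
    """
    if not scenarios:
        raise ValueError("scenario list must not be empty")
    base = config or ModelConfig()
    settings = settings or IntegrationSettings()
    if grid is None:
        grid = make_fold_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("fold grid must be positive")

    sf, uf, vf = [x.ravel() for x in np.meshgrid(grid, grid, grid, indexing="ij")]
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    iterator: Iterable = [
        (s_h, scen) for s_h in s_h_values for scen in scenarios
    ]
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="screen", unit="block")

    frames = []
    for s_h, scen in iterator:
        part_path = (
            out_dir / f"screen_sh{s_h:g}_{scen}.csv" if out_dir is not None else None
        )
        if resume and part_path is not None and part_path.exists():
            frames.append(pd.read_csv(part_path))
            continue
        from dataclasses import replace

        cfg = replace(base, s_h=s_h)
        thr = thresholds or ClassificationThresholds.from_config(cfg)
        s_p, u_p, v_p = sf * cfg.s_h, uf * cfg.u_h, vf * cfg.v_h
        mono_tot, mono_frac, mono_conv, _, _ = _reduced_batch_for(
            scen, "monoclonal", cfg, settings, s_p, u_p, v_p,
            allocation_mode=allocation_mode, seed=seed,
        )
        poly_tot, poly_frac, poly_conv, _, _ = _reduced_batch_for(
            scen, "polyclonal", cfg, settings, s_p, u_p, v_p,
            allocation_mode=allocation_mode, seed=seed,
        )
        mono_flag, poly_flag = _classify_batch(
            thr, mono_tot, mono_frac, poly_tot, poly_frac
        )
        df = pd.DataFrame({
            "scenario": scen,
            "s_fold": sf, "u_fold": uf, "v_fold": vf,
            "s_h_used": s_h,
            "mono_total": mono_tot, "mono_prelk_frac": mono_frac,
            "poly_total": poly_tot, "poly_prelk_frac": poly_frac,
            "mono_converged": mono_conv, "poly_converged": poly_conv,
            "mono_premalignant": mono_flag, "poly_controlled": poly_flag,
            "consistent": mono_flag & poly_flag,
        })[SCREEN_COLUMNS]
        if part_path is not None:
            df.to_csv(part_path, index=False)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
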