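"""Post-processing of screen results.

Summaries of the consistent parameter region: counts, per-parameter
direction of change (fold below/above 1), octant membership of
``(log s_fold, log u_fold, log v_fold)``, and the log-log band relating the
unspecific-affinity fold-change to the efficiency fold-change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConsistentSummary",
    "BandFit",
    "count_consistent",
    "summarize_consistent",
    "fit_uv_band",
    "write_summary",
    "plot_consistent_region",
]


@dataclass
class ConsistentSummary:
    """Characterization of the consistent parameter sets of one scenario."""

    scenario: str
    n_consistent: int
    min_v_fold: float | None = None
    frac_s_decrease_exceeds_u_decrease: float | None = None
    all_u_below_one: bool | None = None
    all_s_below_one: bool | None = None
    octant_counts: dict = field(default_factory=dict)


@dataclass
class BandFit:
    """Parallel bounding band of log u_fold versus log v_fold."""

    slope: float
    intercept_low: float
    intercept_high: float
    n_outside: int = 0


def count_consistent(records: pd.DataFrame, scenario: str | None = None) -> int:
    """Number of consistent records, optionally restricted to one scenario."""
    if len(records) == 0:
        return 0
    mask = records["consistent"].astype(bool)
    if scenario is not None:
        mask &= records["scenario"] == scenario
    return int(mask.sum())


def _octant_key(s: float, u: float, v: float) -> str:
    """Sign pattern of the log fold-changes, e.g. ``"--+"`` for decreased
    specific and unspecific affinity with increased efficiency.  A fold of
    exactly 1 maps to ``0``."""
    def sign(x: float) -> str:
        return "-" if x < 1 else ("+" if x > 1 else "0")

    return sign(s) + sign(u) + sign(v)


def summarize_consistent(records: pd.DataFrame) -> dict[str, ConsistentSummary]:
    """Per-scenario (plus ``"all"``) summaries of the consistent sets.

    "s decrease exceeds u decrease" counts records with ``s_fold < u_fold``:
    the specific affinity is reduced more strongly than the unspecific one.
    Direction flags use strict comparison against fold 1 (a fold of exactly
    1 is not a decrease).
    """
    if len(records) == 0:
        raise ValueError("record table is empty")
    out: dict[str, ConsistentSummary] = {}
    groups = [("all", records)] + [
        (str(s), g) for s, g in records.groupby("scenario", sort=True)
    ]
    for name, group in groups:
        cons = group[group["consistent"].astype(bool)]
        summ = ConsistentSummary(scenario=name, n_consistent=len(cons))
        if len(cons) > 0:
            s, u, v = (cons[k].to_numpy() for k in ("s_fold", "u_fold", "v_fold"))
            summ.min_v_fold = float(v.min())
            summ.frac_s_decrease_exceeds_u_decrease = float(np.mean(s < u))
            summ.all_u_below_one = bool(np.all(u < 1))
            summ.all_s_below_one = bool(np.all(s < 1))
            keys, counts = np.unique(
                [_octant_key(*t) for t in zip(s, u, v)], return_counts=True
            )
            summ.octant_counts = {str(k): int(c) for k, c in zip(keys, counts)}
        out[name] = summ
    return out


def fit_uv_band(records: pd.DataFrame) -> BandFit | None:
    """Minimal enclosing parallel band of the consistent records in
    ``(log v_fold, log u_fold)`` space.

    The common slope comes from a least-squares fit through the midpoint of
    the log-u range at each distinct v_fold; the two intercepts are then
    pushed out so that the band covers every consistent point.  Returns
    ``None`` when fewer than two distinct v_fold values are available.
    """
    cons = records[records["consistent"].astype(bool)]
    if len(cons) == 0:
        return None
    logv = np.log(cons["v_fold"].to_numpy())
    logu = np.log(cons["u_fold"].to_numpy())
    vs = np.unique(logv)
    if vs.size < 2:
        return None
    mids = np.array([(logu[logv == v].min() + logu[logv == v].max()) / 2 for v in vs])
    slope, intercept = np.polyfit(vs, mids, 1)
    resid = logu - slope * logv
    return BandFit(
        slope=float(slope),
        intercept_low=float(resid.min()),
        intercept_high=float(resid.max()),
        n_outside=0,
    )


def write_summary(
    records: pd.DataFrame,
    path: str | Path,
    text_path: str | Path | None = None,
) -> dict:
    """Write the JSON summary (and optional text report); returns the dict."""
    n_total = len(records)
    payload: dict = {
        "n_records": int(n_total),
        "n_consistent": count_consistent(records) if n_total else 0,
        "n_not_converged": int(
            (~(records["mono_converged"] & records["poly_converged"])).sum()
        ) if n_total else 0,
        "scenarios": {},
    }
    if n_total:
        for name, summ in summarize_consistent(records).items():
            payload["scenarios"][name] = asdict(summ)
        band = fit_uv_band(records)
        payload["uv_band"] = asdict(band) if band is not None else None
    Path(path).write_text(json.dumps(payload, indent=2))
    if text_path is not None:
        Path(text_path).write_text(_format_report(payload))
    return payload


def _format_report(payload: dict) -> str:
    lines = [
        "Screen summary",
        "==============",
        f"records:        {payload['n_records']}",
        f"consistent:     {payload['n_consistent']}",
        f"not converged:  {payload['n_not_converged']}",
        "",
    ]
    for name, s in payload.get("scenarios", {}).items():
        lines.append(f"[{name}] consistent={s['n_consistent']}")
        if s.get("min_v_fold") is not None:
            lines.append(
                f"  min v_fold={s['min_v_fold']:.4g}  "
                f"frac(s_fold<u_fold)={s['frac_s_decrease_exceeds_u_decrease']:.3f}  "
                f"all u<1: {s['all_u_below_one']}  all s<1: {s['all_s_below_one']}"
            )
    band = payload.get("uv_band")
    if band:
        lines.append(
            f"u-v band: slope={band['slope']:.4g}, intercepts "
            f"[{band['intercept_low']:.4g}, {band['intercept_high']:.4g}]"
        )
    return "\n".join(lines) + "\n"


def plot_consistent_region(records: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Diagnostic figures: 3D scatter of the consistent region,
    per-parameter histograms, and the u-v scatter with its band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cons = records[records["consistent"].astype(bool)]
    written: list[Path] = []

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for scen, g in cons.groupby("scenario"):
        ax.scatter(
            np.log(g["s_fold"]), np.log(g["u_fold"]), np.log(g["v_fold"]),
            s=6, alpha=0.4, label=scen,
        )
    ax.set_xlabel("log s fold"); ax.set_ylabel("log u fold"); ax.set_zlabel("log v fold")
    ax.legend()
    path = out_dir / "consistent_region_3d.png"
    fig.savefig(path, dpi=120); plt.close(fig); written.append(path)

    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
    for ax, col in zip(axes, ("s_fold", "u_fold", "v_fold")):
        for scen, g in cons.groupby("scenario"):
            ax.hist(np.log(g[col]), bins=20, alpha=0.5, label=scen)
        ax.set_xlabel(f"log {col}")
    axes[0].legend()
    fig.tight_layout()
    path = out_dir / "consistent_histograms.png"
    fig.savefig(path, dpi=120); plt.close(fig); written.append(path)

    band = fit_uv_band(records)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.log(cons["v_fold"]), np.log(cons["u_fold"]), s=8, alpha=0.5)
    if band is not None:
        xs = np.linspace(np.log(cons["v_fold"]).min(), np.log(cons["v_fold"]).max(), 2)
        ax.plot(xs, band.slope * xs + band.intercept_low, "k--")
        ax.plot(xs, band.slope * xs + band.intercept_high, "k--")
    ax.set_xlabel("log v fold"); ax.set_ylabel("log u fold")
    fig.tight_layout()
    path = out_dir / "uv_band.png"
    fig.savefig(path, dpi=120); plt.close(fig); written.append(path)
    return written
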