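"""Reproducible experiment driver: display sets x lesion conditions.

Runs the model over a display set under one or more lesion conditions,
collects a :class:`~teardrop.metrics.MetricsReport` per (display, lesion),
and writes per-run rows, aggregate statistics, and a manifest that captures
the configuration and seeds needed to regenerate every output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .dynamics import LESION_CONDITIONS, SimParams, Trajectory, run
from .metrics import MetricsReport, evaluate, normalize_across_conditions
from .stimuli import VisualDisplay, get_display_set

logger = logging.getLogger("teardrop")


@dataclass(frozen=True)
class ExperimentSpec:
    """What to run: a display set, lesion list, parameters and a seed."""

    display_set: str = "exemplars"
    lesions: tuple[str, ...] = ("intact",)
    params: SimParams = field(default_factory=SimParams)
    out_dir: str | None = None
    seed: int = 0
    subsample: int | None = None       # for the 500-display block sets
    save_activity: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(
            {"set": self.display_set, "lesions": list(self.lesions),
             "params": dataclasses.asdict(self.params), "seed": self.seed,
             "subsample": self.subsample},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _materialize(spec: ExperimentSpec) -> list[VisualDisplay]:
    if spec.display_set.upper() in ("LC", "MC", "HC"):
        n = spec.subsample or 50
        displays = get_display_set(spec.display_set, n=n, seed=spec.seed)
    else:
        displays = get_display_set(spec.display_set)
        if spec.subsample is not None and spec.subsample < len(displays):
            rng = np.random.default_rng(spec.seed)
            idx = rng.choice(len(displays), size=spec.subsample, replace=False)
            displays = [displays[i] for i in sorted(idx)]
    # metrics need a figure; drop background-only controls from sweeps
    return [d for d in displays if d.params.get("figure_present", True)]


def run_experiment(spec: ExperimentSpec,
                   keep_trajectories: bool = False,
                   ) -> tuple[pd.DataFrame, list[Trajectory]]:
    """Run all (display, lesion) combinations of a spec.

    Returns the per-run metrics table and (optionally) the trajectories.
    If ``spec.out_dir`` is set, writes ``runs.csv``, ``summary.csv``,
    ``normalized.csv`` (lesion-normalized index means) and
    ``manifest.json`` there.
    """
    displays = _materialize(spec)
    reports: list[MetricsReport] = []
    trajectories: list[Trajectory] = []
    n_fail = 0
    t0 = time.time()
    for disp in displays:
        for lname in spec.lesions:
            lesion = LESION_CONDITIONS[lname]
            try:
                traj = run(disp, lesion=lesion, params=spec.params)
            except Exception:
                logger.exception("run failed for %s / %s", disp.name, lname)
                n_fail += 1
                continue
            rep = evaluate(disp, traj.final.convex, lesion,
                           converged=traj.converged, n_steps=traj.n_steps_run)
            reports.append(rep)
            if keep_trajectories:
                trajectories.append(traj)
            logger.info("%s / %s: IOI=%.3f MAI=%.3f BI=%.3f (%d steps)",
                        disp.name, lname, rep.ioi, rep.mai, rep.bi,
                        traj.n_steps_run)
    table = pd.DataFrame([r.as_row() for r in reports])
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "runs.csv", index=False)
        summary = summarize(table)
        summary.to_csv(out / "summary.csv")
        norm = normalized_summary(table)
        if norm is not None:
            norm.to_csv(out / "normalized.csv")
        manifest = {
            "package_version": __version__,
            "config_hash": spec.config_hash(),
            "display_set": spec.display_set,
            "n_displays": len(displays),
            "lesions": list(spec.lesions),
            "seed": spec.seed,
            "params": dataclasses.asdict(spec.params),
            "n_failures": n_fail,
            "wall_time_s": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    if n_fail:
        raise RuntimeError(f"{n_fail} runs failed; partial results "
                           f"{'written' if spec.out_dir else 'returned'}")
    return table, trajectories


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each index per lesion condition."""
    return table.groupby("lesion")[["ioi", "mai", "bi", "kurtosis"]].agg(
        ["mean", "std"])


def normalized_summary(table: pd.DataFrame) -> pd.DataFrame | None:
    """Min-max normalized index means across lesion conditions (0 = worst,
    1 = best), the convention of lesion bar summaries."""
    if table["lesion"].nunique() < 2:
        return None
    means = table.groupby("lesion")[["ioi", "mai", "bi"]].mean()
    out = {}
    for col in means.columns:
        out[col] = normalize_across_conditions(means[col].to_dict())
    return pd.DataFrame(out)


def render_panels(trajectory: Trajectory, out_dir: str | Path,
                  dpi: int = 100) -> list[Path]:
    """Figure-style panels: per-scale convex maps plus the closure-feedback
    field (warm = enhancement, blue = suppression)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .ait import teardrop_feedback

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = trajectory.final.convex
    n_scales = x.shape[2]
    paths = []

    fig, axes = plt.subplots(1, n_scales, figsize=(2 * n_scales, 2.4))
    vmax = max(float(x.max()), 1e-9)
    for s, ax in enumerate(axes):
        ax.imshow(x[:, :, s], vmin=0, vmax=vmax, cmap="magma")
        ax.set_title(f"RF {s + 1}", fontsize=8)
        ax.axis("off")
    fig.suptitle(f"{trajectory.display.name} / {trajectory.lesion.name}: "
                 "convex activity per RF size", fontsize=9)
    p = out / f"{trajectory.display.name}_{trajectory.lesion.name}_convex.png"
    fig.savefig(p, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    F = teardrop_feedback(trajectory.final.teardrop,
                          g_half=trajectory.params.g_half,
                          theta_f=trajectory.params.theta_f,
                          g_pow=trajectory.params.g_pow)
    fig, ax = plt.subplots(figsize=(3, 3))
    lim = max(float(np.abs(F).max()), 1e-9)
    im = ax.imshow(F, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.contour(trajectory.display.figure_mask, levels=[0.5], colors="k",
               linewidths=0.6)
    ax.axis("off")
    fig.colorbar(im, shrink=0.8)
    ax.set_title("closure feedback F", fontsize=9)
    p = out / f"{trajectory.display.name}_{trajectory.lesion.name}_feedback.png"
    fig.savefig(p, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths


def render_lesion_bars(table: pd.DataFrame, out_path: str | Path,
                       dpi: int = 100) -> Path:
    """Bar chart of normalized IOI/MAI/BI per lesion condition (+/- 1 SD)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [l for l in ("teardrop_only", "convex_only", "none", "intact")
             if l in set(table["lesion"])]
    norm = normalized_summary(table)
    sds = table.groupby("lesion")[["ioi", "mai", "bi"]].std()
    fig, axes = plt.subplots(1, 3, figsize=(9, 3), sharey=True)
    for ax, idx in zip(axes, ("ioi", "mai", "bi")):
        vals = [norm.loc[l, idx] for l in order]
        errs = [sds.loc[l, idx] for l in order]
        ax.bar(range(len(order)), vals, yerr=errs, capsize=3,
               color=["tab:blue", "tab:olive", "tab:orange", "tab:red"][:len(order)])
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=45, fontsize=7)
        ax.set_title(idx.upper())
    axes[0].set_ylabel("normalized index")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return out_path


def render_time_course(traces: dict[str, np.ndarray], out_path: str | Path,
                       dpi: int = 100) -> Path:
    """Plot labelled single-cell activity traces over simulation steps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for label, trace in traces.items():
        ax.plot(trace, label=label)
    ax.set_xlabel("step")
    ax.set_ylabel("convex activity")
    ax.legend(fontsize=8)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return out_path
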