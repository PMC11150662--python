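"""Configuration, serialization, rendering and the command-line interface.

The config file is flat YAML whose keys mirror the model's symbol names
(w1, w2, A0, At, ...), grouped into ``params`` / ``domain`` / ``injury`` /
``run`` sections, so the notation of the model is the documentation of the
file. All quantitative outputs are CSV; images are a convenience and are
never parsed by tests.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from matplotlib.collections import LineCollection

from . import experiments
from .core_dynamics import (ModelParams, Outcome, find_critical_weight,
                            find_fibrotic_threshold, phase_diagram,
                            simulate_element)
from .experiments import InjurySpec, RunMetrics, run_simulation, replicate_study
from .mechanics_solver import stiffness_assay
from .network_geometry import (DomainSpec, SpringNetwork, load_network,
                               save_network)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "trajectory_to_csv",
    "render_histology",
    "render_phase_diagram",
    "cli",
    "main",
]

log = logging.getLogger("fibronet")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run: parameters, domain, injury, I/O."""

    params: ModelParams = field(default_factory=ModelParams)
    domain: DomainSpec = field(default_factory=DomainSpec)
    injury: InjurySpec = field(default_factory=InjurySpec)
    outdir: str = "fibronet_out"
    assay_stride: int = 50
    n_replicates: int = 9
    snapshot_iterations: tuple[int, ...] | None = None

    def to_dict(self) -> dict:
        d = {
            "params": dataclasses.asdict(self.params),
            "domain": dataclasses.asdict(self.domain),
            "injury": dataclasses.asdict(self.injury),
            "run": {
                "outdir": self.outdir,
                "assay_stride": self.assay_stride,
                "n_replicates": self.n_replicates,
                "snapshot_iterations":
                    None if self.snapshot_iterations is None
                    else list(self.snapshot_iterations),
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        run = d.get("run", {})
        snaps = run.get("snapshot_iterations")
        return cls(
            params=ModelParams(**d.get("params", {})),
            domain=DomainSpec(**d.get("domain", {})),
            injury=InjurySpec(**d.get("injury", {})),
            outdir=run.get("outdir", "fibronet_out"),
            assay_stride=run.get("assay_stride", 50),
            n_replicates=run.get("n_replicates", 9),
            snapshot_iterations=None if snaps is None else tuple(snaps),
        )


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def trajectory_to_csv(traj, path) -> None:
    """Single-element trajectory as CSV: iteration, A, eps, a, D, outcome."""
    df = pd.DataFrame({
        "iteration": np.arange(len(traj.states)),
        "A": [s.A for s in traj.states],
        "eps": [s.eps for s in traj.states],
        "a": [s.a for s in traj.states],
        "D": [s.D for s in traj.states],
    })
    df["outcome"] = traj.outcome.value
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_histology(net: SpringNetwork, output, max_width: float = 8.0,
                     width_per_area: float = 1.5) -> None:
    """Synthetic histology: springs drawn with width proportional to area.

    Ruptured springs are absent, so digested regions appear as voids
    (honeycombing); thickened strands mark fibrotic deposition. Width is
    clamped at ``max_width`` points.
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    live = np.flatnonzero(net.spring_alive)
    if len(live) == 0:
        log.warning("rendering an empty network: %s", output)
    else:
        segs = [(net.nodes[i], net.nodes[j]) for i, j in net.springs[live]]
        widths = np.minimum(width_per_area * net.A[live], max_width)
        ax.add_collection(LineCollection(segs, linewidths=widths,
                                         colors="#8c2a55", capstyle="round"))
        pts = net.nodes[net.node_alive]
        pad = 0.05 * (pts.max() - pts.min() + 1e-9)
        ax.set_xlim(pts[:, 0].min() - pad, pts[:, 0].max() + pad)
        ax.set_ylim(pts[:, 1].min() - pad, pts[:, 1].max() + pad)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(output, dpi=150, bbox_inches="tight")
    plt.close(fig)


_PHASE_COLORS = {"healing": "#7fc97f", "fibrotic": "#f4a5c0",
                 "mixed": "#ffff99", "undecided": "#cccccc",
                 "unstable": "#999999"}


def render_phase_diagram(eps_values, A_values, labels, output,
                         spring_states: np.ndarray | None = None,
                         element_trajectory=None) -> None:
    """Phase plane in (strain, area): outcome regions, spring states, trajectory.

    ``spring_states`` is an (n, 2) array of per-spring (eps, A) points;
    ``element_trajectory`` a Trajectory whose (eps, A) curve is overlaid
    (the lumped-model prediction the network scatters around).
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    order = ["healing", "fibrotic", "mixed", "undecided", "unstable"]
    codes = {lab: k for k, lab in enumerate(order)}
    grid = np.array([[codes[lab] for lab in row] for row in labels])
    cmap = matplotlib.colors.ListedColormap([_PHASE_COLORS[k] for k in order])
    ax.pcolormesh(np.asarray(A_values), np.asarray(eps_values), grid,
                  cmap=cmap, vmin=-0.5, vmax=len(order) - 0.5, shading="nearest")
    present = sorted({lab for row in labels for lab in row}, key=order.index)
    handles = [plt.Rectangle((0, 0), 1, 1, color=_PHASE_COLORS[k]) for k in present]
    if spring_states is not None and len(spring_states):
        ax.plot(spring_states[:, 1], spring_states[:, 0], "r*", ms=5,
                label="springs")
    if element_trajectory is not None:
        ax.plot([s.A for s in element_trajectory.states],
                [s.eps for s in element_trajectory.states], "k-", lw=1.5,
                label="single-element path")
    ax.legend(handles + ax.get_lines(), present
              + [ln.get_label() for ln in ax.get_lines()], loc="upper right",
              fontsize=8)
    ax.set_xlabel("cross-sectional area A")
    ax.set_ylabel("strain eps")
    fig.savefig(output, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

def _write_manifest(outdir: Path, args: argparse.Namespace, cfg: RunConfig) -> None:
    manifest = {"argv": sys.argv[1:], "config": cfg.to_dict(),
                "overrides": {k: v for k, v in vars(args).items()
                              if k not in ("func", "config") and v is not None}}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))


def _load_cfg(args) -> RunConfig:
    cfg = load_config(args.config) if args.config else RunConfig()
    p = cfg.params
    overrides = {}
    if getattr(args, "w2", None) is not None:
        overrides["w2"] = args.w2
    if getattr(args, "seed", None) is not None:
        overrides["seed"] = args.seed
    if getattr(args, "iterations", None) is not None:
        overrides["n_iterations"] = args.iterations
    if overrides:
        p = replace(p, **overrides)
    inj = cfg.injury
    if getattr(args, "injury_fraction", None) is not None:
        inj = replace(inj, fraction=args.injury_fraction)
    if getattr(args, "injury_multiplier", None) is not None:
        inj = replace(inj, multiplier=args.injury_multiplier)
    out = args.out if getattr(args, "out", None) else cfg.outdir
    reps = args.replicates if getattr(args, "replicates", None) else cfg.n_replicates
    return replace(cfg, params=p, injury=inj, outdir=out, n_replicates=reps)


def _cmd_element(args) -> int:
    cfg = _load_cfg(args)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = simulate_element(cfg.params, cfg.injury.multiplier)
    trajectory_to_csv(traj, outdir / "element_trajectory.csv")
    thr = find_fibrotic_threshold(cfg.params)
    crit = find_critical_weight(cfg.params) if cfg.params.w1 > 0 else float("nan")
    summary = {"outcome": traj.outcome.value, "fibrotic_threshold": thr,
               "critical_weight": crit}
    (outdir / "element_summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(outdir, args, cfg)
    log.info("element run: %s", summary)
    return 0


def _cmd_phase(args) -> int:
    cfg = _load_cfg(args)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eps_values = np.geomspace(0.05, 5.0, args.grid)
    A_values = np.geomspace(0.05, 5.0 * cfg.params.At, args.grid)
    labels = phase_diagram(eps_values, A_values, cfg.params,
                           n_iterations=args.iterations or 500)
    pd.DataFrame(labels, index=eps_values, columns=A_values).to_csv(
        outdir / "phase_labels.csv")
    render_phase_diagram(eps_values, A_values, labels,
                         outdir / "phase_diagram.png")
    _write_manifest(outdir, args, cfg)
    return 0


def _cmd_generate(args) -> int:
    cfg = _load_cfg(args)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    domain = cfg.domain if args.seed is None else replace(cfg.domain, seed=args.seed)
    net = experiments.generate_prestressed_network(domain, cfg.params)
    save_network(net, outdir / "network.txt")
    _write_manifest(outdir, args, cfg)
    log.info("generated network: %d nodes, %d springs",
             net.n_live_nodes, net.n_live_springs)
    return 0


def _cmd_simulate(args) -> int:
    cfg = _load_cfg(args)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if args.ablation:
        runs = [experiments.ablation(cfg.params, args.ablation, cfg.domain,
                                     cfg.injury, seed=cfg.params.seed,
                                     assay_stride=cfg.assay_stride)]
    elif cfg.n_replicates > 1:
        runs = replicate_study(cfg.params, cfg.domain, cfg.injury,
                               cfg.n_replicates, base_seed=cfg.params.seed,
                               assay_stride=cfg.assay_stride)
    else:
        runs = [run_simulation(cfg.params, cfg.domain, cfg.injury,
                               seed=cfg.params.seed,
                               assay_stride=cfg.assay_stride,
                               snapshot_iterations=cfg.snapshot_iterations)]
    frames = []
    for k, m in enumerate(runs):
        df = m.to_dataframe()
        df["replicate"] = k
        frames.append(df)
        for it, snap in m.snapshots.items():
            save_network(snap, outdir / f"snapshot_rep{k}_iter{it}.txt")
    tidy = pd.concat(frames, ignore_index=True)
    tidy.to_csv(outdir / "metrics.csv", index=False)
    outcomes = {k: m.outcome.value for k, m in enumerate(runs)}
    (outdir / "outcomes.json").write_text(json.dumps(outcomes, indent=2))
    _write_manifest(outdir, args, cfg)
    log.info("outcomes: %s", outcomes)
    return 0


def _cmd_assay(args) -> int:
    net = load_network(args.network)
    coeff, rms = stiffness_assay(net)
    print(json.dumps({"stiffness_coefficient": coeff, "fit_rms": rms}))
    return 0


def _cmd_render(args) -> int:
    net = load_network(args.network)
    out = Path(args.out or "histology.png")
    render_histology(net, out)
    log.info("wrote %s", out)
    return 0


def cli(argv=None) -> int:
    """Entry point; returns a process exit code."""
    parser = argparse.ArgumentParser(
        prog="fibronet",
        description="Agent-based spring-network model of lung fibrosis")
    parser.add_argument("-v", "--verbose", action="store_true")
    sub = parser.add_subparsers(dest="command", required=True)

    def common(sp, network=False):
        sp.add_argument("--config", default=None)
        sp.add_argument("--seed", type=int, default=None)
        sp.add_argument("--w2", type=float, default=None)
        sp.add_argument("--injury-fraction", type=float, default=None,
                        dest="injury_fraction")
        sp.add_argument("--injury-multiplier", type=float, default=None,
                        dest="injury_multiplier")
        sp.add_argument("--iterations", type=int, default=None)
        sp.add_argument("--replicates", type=int, default=None)
        sp.add_argument("--out", default=None)

    sp = sub.add_parser("element", help="single-element trajectory and thresholds")
    common(sp)
    sp.set_defaults(func=_cmd_element)

    sp = sub.add_parser("phase", help="phase diagram of the element map")
    common(sp)
    sp.add_argument("--grid", type=int, default=15)
    sp.set_defaults(func=_cmd_phase)

    sp = sub.add_parser("generate", help="generate a prestressed network")
    common(sp)
    sp.set_defaults(func=_cmd_generate)

    sp = sub.add_parser("simulate", help="full run / replicates / ablations")
    common(sp)
    sp.add_argument("--ablation", choices=["no_strain", "no_stiffness"],
                    default=None)
    sp.set_defaults(func=_cmd_simulate)

    sp = sub.add_parser("assay", help="stiffness assay of a network snapshot")
    sp.add_argument("network")
    sp.set_defaults(func=_cmd_assay)

    sp = sub.add_parser("render", help="synthetic histology of a snapshot")
    sp.add_argument("network")
    sp.add_argument("--out", default=None)
    sp.set_defaults(func=_cmd_render)

    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)
    logging.basicConfig(level=logging.DEBUG if args.verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    try:
        return args.func(args)
    except FileNotFoundError as exc:
        log.error("file not found: %s", exc)
        return 2
    except (ValueError, KeyError, TypeError) as exc:
        log.error("invalid input: %s", exc)
        return 2


def main() -> None:
    sys.exit(cli())
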