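"""End-to-end experiment orchestration from plain-text (TOML) configs.

Five canned experiments bind the modules together:

* ``ws_contrast`` — excitable dynamics on critical (k=10) vs non-critical
  (k=2) Watts–Strogatz networks: indicator curves across a threshold sweep;
* ``stroke_sweep`` — S2 threshold curves for graded artificial strokes of a
  target RSN on a synthetic modular connectome (comb family);
* ``structural`` — lesion ensembles across severities: normalized area under
  S2 against normalized modularity and conductance, with Pearson summaries;
* ``ising_divided`` — temperature sweeps of the (divided) square-lattice
  Ising model with whole-system and per-subsystem cluster curves;
* ``comb`` — families of Ising S2 curves for growing central-patch sizes.

Each run writes TSV tables, a ``summary.json`` and a log of every sub-seed
under the configured output directory; re-running a config reproduces the
tables byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters, gh_dynamics, graphmeasures, indicators, ising, lesion, networks

__all__ = ["ExperimentConfig", "run_experiment", "make_report"]

logger = logging.getLogger("criticonn")

EXPERIMENTS = ("ws_contrast", "stroke_sweep", "structural", "ising_divided", "comb")


@dataclass
class ExperimentConfig:
    """One experiment fully specified by a TOML table."""

    experiment: str
    seed: int = 0
    outdir: str | Path = "results"
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )

    @classmethod
    def from_toml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        try:
            experiment = data.pop("experiment")
        except KeyError as exc:
            raise ValueError(f"{path}: config must set 'experiment'") from exc
        seed = data.pop("seed", 0)
        outdir = data.pop("outdir", "results")
        return cls(experiment=experiment, seed=seed, outdir=outdir, options=data)

    def opt(self, key, default):
        return self.options.get(key, default)


def _grid(lo: float, hi: float, num: int) -> np.ndarray:
    if num < 2:
        raise ValueError("grids need at least 2 points")
    return np.linspace(lo, hi, num)


def _threshold_grid_for(net: networks.WeightedNetwork, r2: float, num: int) -> np.ndarray:
    """30-point default grid spanning [0.2, 3] x the mean-field critical
    threshold, so the sweep covers the critical value on any network."""
    tc = indicators.mean_field_tc(net, r2)
    return _grid(0.2 * tc, 3.0 * tc, num)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the configured experiment; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("experiment=%s seed=%s outdir=%s", config.experiment, config.seed, outdir)
    runner = {
        "ws_contrast": _run_ws_contrast,
        "stroke_sweep": _run_stroke_sweep,
        "structural": _run_structural,
        "ising_divided": _run_ising_divided,
        "comb": _run_comb,
    }[config.experiment]
    try:
        summary = runner(config, outdir)
    except Exception as exc:
        raise RuntimeError(
            f"experiment {config.experiment!r} failed; partial outputs in {outdir}"
        ) from exc
    summary["experiment"] = config.experiment
    summary["master_seed"] = config.seed
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return outdir


# ---------------------------------------------------------------------------
# experiment bodies
# ---------------------------------------------------------------------------

def _run_ws_contrast(config: ExperimentConfig, outdir: Path) -> dict:
    n = int(config.opt("n", 2000))
    pi = float(config.opt("pi", 0.5))
    lam = float(config.opt("lam", 12.5))
    r1 = float(config.opt("r1", 0.001))
    r2 = float(config.opt("r2", 0.3))
    t_max = int(config.opt("t_max", 10_000))
    t_init = int(config.opt("t_init", 200))
    n_thresholds = int(config.opt("n_thresholds", 30))
    ks = {"critical": int(config.opt("k_critical", 10)), "noncritical": int(config.opt("k_noncritical", 2))}

    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(ks, ss.spawn(len(ks)))}

    summary: dict = {}
    grid = None
    for name, k in ks.items():
        net = networks.generate_ws_network(n, k, pi, lam, seed=seeds[name])
        if grid is None:
            grid = _threshold_grid_for(net, r2, n_thresholds)
        params = gh_dynamics.GHParams(
            threshold=grid[0], r1=r1, r2=r2, t_max=t_max, t_init=t_init, seed=seeds[name]
        )
        sweep = gh_dynamics.threshold_sweep(net, grid, params)
        _write(sweep.to_frame(), outdir / f"ws_{name}_k{k}.tsv")
        peak, interior = indicators.peak_location(sweep.curve("S2"))
        summary[f"{name}_S2_peak"] = peak
        summary[f"{name}_S2_peak_interior"] = bool(interior)
        logger.info("ws_contrast %s k=%d: S2 peak at %.4g interior=%s", name, k, peak, interior)
    return summary


def _default_connectome_from_config(config: ExperimentConfig, seed: int):
    n = int(config.opt("n", 998))
    sizes = list(config.opt("module_sizes", list(networks.DEFAULT_MODULE_SIZES)))
    names = list(config.opt("module_names", list(networks.DEFAULT_RSN_NAMES)))
    return networks.generate_modular_connectome(
        n,
        sizes,
        mean_degree_in=float(config.opt("mean_degree_in", 24.0)),
        mean_degree_out=float(config.opt("mean_degree_out", 10.0)),
        lam=float(config.opt("lam", 12.5)),
        seed=seed,
        module_names=names,
    )


def _gh_sweep_setup(config: ExperimentConfig, net):
    normalized = networks.normalize_in_strength(net)
    r1, r2 = gh_dynamics.default_rates(net.n_nodes)
    grid = _threshold_grid_for(normalized, r2, int(config.opt("n_thresholds", 30)))
    base = gh_dynamics.GHParams(
        threshold=grid[0],
        r1=r1,
        r2=r2,
        t_max=int(config.opt("t_max", 10_000)),
        t_init=int(config.opt("t_init", 200)),
    )
    return normalized, grid, base


def _run_stroke_sweep(config: ExperimentConfig, outdir: Path) -> dict:
    from dataclasses import replace

    target = config.opt("target_rsn", "auditory")
    severities = list(config.opt("severities", [0.0, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0]))
    variant = config.opt("variant", "node_severity")

    ss = np.random.SeedSequence(config.seed)
    net_seed, lesion_seed, sweep_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    net, parc = _default_connectome_from_config(config, net_seed)
    normalized, grid, base = _gh_sweep_setup(config, net)

    rows = []
    summary: dict = {"severities": severities}
    lesion_rng = np.random.default_rng(lesion_seed)
    for severity in severities:
        spec = lesion.LesionSpec(target, float(severity), variant=variant)
        lesioned = lesion.apply_lesion(net, parc, spec, lesion_rng)
        lesioned_norm = networks.normalize_in_strength(lesioned)
        sweep = gh_dynamics.threshold_sweep(
            lesioned_norm, grid, replace(base, seed=sweep_seed),
            parcellation=parc, subsystem_labels=[target],
        )
        df = sweep.to_frame()
        df.insert(0, "severity", severity)
        rows.append(df)
        peak, interior = indicators.peak_location(sweep.curve("S2"))
        summary[f"S2_peak_severity_{severity:g}"] = peak
        summary[f"S2_interior_severity_{severity:g}"] = bool(interior)
        logger.info("stroke_sweep severity=%.3g peak=%.4g interior=%s", severity, peak, interior)
    _write(pd.concat(rows, ignore_index=True), outdir / "stroke_sweep.tsv")
    return summary


def _structural_downstream(config, parc, target, grid, base):
    from dataclasses import replace

    def downstream(lesioned, realization, analysis_seed):
        lesioned_norm = networks.normalize_in_strength(lesioned)
        sweep = gh_dynamics.threshold_sweep(lesioned_norm, grid, replace(base, seed=analysis_seed))
        i2 = indicators.area_under_s2(sweep.curve("S2"))
        part = graphmeasures.louvain_partition(lesioned, seed=analysis_seed)
        q = graphmeasures.modularity(lesioned, part)
        qn = graphmeasures.q_normalized(lesioned, part)
        rsn_nodes = parc.nodes_of(target)
        h = graphmeasures.conductance(lesioned, rsn_nodes)
        return {"I2": i2, "Q": q, "Q_norm": qn, "h_G": h}

    return downstream


def _run_structural(config: ExperimentConfig, outdir: Path) -> dict:
    target = config.opt("target_rsn", "auditory")
    severities = list(config.opt("severities", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]))
    n_real = int(config.opt("n_realizations", 20))

    ss = np.random.SeedSequence(config.seed)
    net_seed, ens_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    net, parc = _default_connectome_from_config(config, net_seed)
    normalized, grid, base = _gh_sweep_setup(config, net)
    downstream = _structural_downstream(config, parc, target, grid, base)

    # baseline: the unmodified network, same analysis
    baseline = downstream(net, -1, ens_seed)
    all_rows = []
    means = []
    for s_i, severity in enumerate(severities):
        spec = lesion.LesionSpec(
            target, float(severity), variant=config.opt("variant", "node_severity"),
            n_realizations=n_real, seed=ens_seed + s_i,
        )
        frame, mean = lesion.lesion_ensemble(net, parc, spec, downstream)
        frame.insert(0, "severity", severity)
        all_rows.append(frame)
        means.append({"severity": severity, **mean.to_dict()})
        logger.info("structural severity=%.3g mean I2=%.4g Q_norm=%.4g h_G=%.4g",
                    severity, mean["I2"], mean["Q_norm"], mean["h_G"])

    per_real = pd.concat(all_rows, ignore_index=True)
    mean_df = pd.DataFrame(means)
    for col in ("I2", "Q_norm", "h_G"):
        per_real[f"{col}_norm"] = (per_real[col] - baseline[col]) / baseline[col]
        mean_df[f"{col}_norm"] = (mean_df[col] - baseline[col]) / baseline[col]
    _write(per_real, outdir / "structural_realizations.tsv")
    _write(mean_df, outdir / "structural_means.tsv")

    rho_q, p_q, lo_q, hi_q = graphmeasures.pearson_ci(per_real["I2_norm"], per_real["Q_norm"])
    rho_h, p_h, lo_h, hi_h = graphmeasures.pearson_ci(per_real["I2_norm"], -per_real["h_G_norm"])
    return {
        "baseline": baseline,
        "rho_I2_Q": rho_q, "p_I2_Q": p_q, "ci_I2_Q": [lo_q, hi_q],
        "rho_I2_negh": rho_h, "p_I2_negh": p_h, "ci_I2_negh": [lo_h, hi_h],
    }


def _run_ising_divided(config: ExperimentConfig, outdir: Path) -> dict:
    rows = int(config.opt("rows", 100))
    cols = int(config.opt("cols", 100))
    division = config.opt("division", "equal_halves")
    patch_side = int(config.opt("patch_side", 50))
    spec = networks.LatticeSpec(rows, cols, division=division, patch_side=patch_side)
    net, parc = networks.build_lattice(spec)
    temps = _grid(
        float(config.opt("t_lo", 0.01)), float(config.opt("t_hi", 4.5)),
        int(config.opt("n_temperatures", 30)),
    )
    base = ising.IsingParams(
        temperature=temps[0],
        t_max=int(config.opt("t_max", 5000)),
        t_init=int(config.opt("t_init", 200)),
        seed=config.seed,
    )
    labels = [lab for lab in ("A", "B") if lab in parc.label_set] if division != "none" else []
    sweep = ising.temperature_sweep(net, temps, base, parcellation=parc, subsystem_labels=labels)
    _write(sweep.to_frame(), outdir / f"ising_{division}.tsv")
    summary: dict = {"division": division}
    for name in ["S2"] + [f"S2[{lab}]" for lab in labels]:
        peak, interior = indicators.peak_location(sweep.curve(name))
        summary[f"{name}_peak"] = peak
        summary[f"{name}_interior"] = bool(interior)
        logger.info("ising_divided %s: peak at %.4g interior=%s", name, peak, interior)
    return summary


def _run_comb(config: ExperimentConfig, outdir: Path) -> dict:
    rows = int(config.opt("rows", 100))
    cols = int(config.opt("cols", 100))
    patch_sides = list(config.opt("patch_sides", [20, 30, 40, 50, 60]))
    temps = _grid(
        float(config.opt("t_lo", 0.01)), float(config.opt("t_hi", 4.5)),
        int(config.opt("n_temperatures", 30)),
    )
    base = ising.IsingParams(
        temperature=temps[0],
        t_max=int(config.opt("t_max", 5000)),
        t_init=int(config.opt("t_init", 200)),
        seed=config.seed,
    )
    frames = []
    summary: dict = {"patch_sides": patch_sides}
    for side in patch_sides:
        spec = networks.LatticeSpec(rows, cols, division="central_patch", patch_side=int(side))
        net, parc = networks.build_lattice(spec)
        sweep = ising.temperature_sweep(net, temps, base)
        df = sweep.to_frame()
        df.insert(0, "patch_side", side)
        frames.append(df)
        peak, interior = indicators.peak_location(sweep.curve("S2"))
        summary[f"S2_peak_side_{side}"] = peak
        summary[f"S2_interior_side_{side}"] = bool(interior)
        logger.info("comb side=%d peak=%.4g interior=%s", side, peak, interior)
    _write(pd.concat(frames, ignore_index=True), outdir / "comb.tsv")
    return summary


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def make_report(outdir: str | Path) -> list[Path]:
    """Regenerate plots from the saved tables of a finished experiment run —
    simulation-free.  Returns the paths of the written figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {outdir}; run the experiment first")
    with open(summary_path) as fh:
        summary = json.load(fh)
    written: list[Path] = []
    for tsv in sorted(outdir.glob("*.tsv")):
        df = pd.read_csv(tsv, sep="\t")
        control = "temperature" if "temperature" in df.columns else "threshold"
        if control not in df.columns:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        group_col = next((c for c in ("severity", "patch_side") if c in df.columns), None)
        if group_col is None:
            for col in df.columns:
                if col.startswith(("S1", "S2")):
                    ax.plot(df[control], df[col], label=col)
        else:
            for value, sub in df.groupby(group_col):
                ax.plot(sub[control], sub["S2"], label=f"{group_col}={value:g}")
        ax.set_xlabel(control)
        ax.set_ylabel("cluster size")
        ax.set_title(tsv.stem)
        ax.legend(fontsize=7)
        fig.tight_layout()
        out = tsv.with_suffix(".png")
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)

    if "rho_I2_Q" in summary:
        df = pd.read_csv(outdir / "structural_realizations.tsv", sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].scatter(df["Q_norm"], df["I2_norm"], s=12)
        axes[0].set_xlabel("Q (norm.)")
        axes[0].set_ylabel("I2 (norm.)")
        axes[0].set_title(f"rho={summary['rho_I2_Q']:.3f} CI={summary['ci_I2_Q']}")
        axes[1].scatter(-df["h_G_norm"], df["I2_norm"], s=12)
        axes[1].set_xlabel("-h_G (norm.)")
        axes[1].set_title(f"rho={summary['rho_I2_negh']:.3f} CI={summary['ci_I2_negh']}")
        fig.tight_layout()
        out = outdir / "structural_scatter.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written
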