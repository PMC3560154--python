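"""Experiment orchestration: null calibration, power grids, multiplex designs.

Three experiment families are provided, mirroring a complete power study of
two-condition RNA-Seq DE detection:

* **Null calibration** -- simulate paired lanes with no DE and record the
  false positive rate of each dispersion strategy at a nominal significance
  level, overall and split into high-/low-count transcripts.
* **Power grid** -- induce DE in a fraction of transcripts, simulate at
  full depth, thin each library over a grid of sequencing depths, and record
  call rate, FPR and TPR for both the adjusted-p criterion and a raw
  fold-change criterion.  Within a repetition every reduced-depth dataset is
  a strict subsample of the full-depth one, so depth comparisons are paired.
* **Multiplex scenarios** -- n barcoded samples per condition packed into a
  fixed number of lanes, each sample sequenced at average depth 1/n; the
  trajectory of TPR across these designs is the "multiplex line".

All randomness flows from one root seed through key-derived child streams
``(root, stage, repetition, n, depth)``, so any cell of any grid is
independently reproducible and shared across scenarios that reuse it.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as m
from .de_tests import DispersionStrategy, STRATEGY_ALIASES, ExactNBTest, fold_change_detector
from .synthetic_data import (
    CountMatrix,
    GeneratorConfig,
    ParameterPopulation,
    build_parameter_population,
    draw_regulating_factors,
    label_effective_de,
    simulate_counts,
    subsample_depth,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "NullExperimentConfig",
    "PowerGridConfig",
    "MultiplexConfig",
    "DEFAULT_DEPTH_GRID",
    "MULTIPLEX_NS",
    "run_null_experiment",
    "run_power_grid",
    "run_multiplex_scenarios",
    "summarise_repetitions",
    "write_report",
]

#: Depth grid covering full depth down to 1% of a lane.
DEFAULT_DEPTH_GRID = (1.0, 0.75, 0.50, 0.25, 0.15, 0.10, 0.05, 0.01)

#: Replicate numbers of the multiplex designs (each at depth 1/n).
MULTIPLEX_NS = (2, 3, 4, 6, 8, 12, 32, 96)


@dataclass(frozen=True)
class ScenarioSpec:
    """A single evaluation cell of the study design space."""

    n_per_condition: int
    depth_fraction: float = 1.0
    strategy: str = "max-parametric"
    criterion: str = "adjusted-p"
    alpha_percent: float = 1.0
    fold_threshold: float = 2.0
    repetitions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if not 0 < self.depth_fraction <= 1:
            raise ValueError("depth_fraction must lie in (0, 1]")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.criterion not in ("adjusted-p", "fold-change"):
            raise ValueError("criterion must be 'adjusted-p' or 'fold-change'")


@dataclass(frozen=True)
class NullExperimentConfig:
    ns: tuple = (2, 3, 4, 6, 8, 12)
    strategies: tuple = ("tagwise-squeeze", "max-parametric", "powerlaw")
    repetitions: int = 100
    alpha_percent: float = 1.0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


@dataclass(frozen=True)
class PowerGridConfig:
    ns: tuple = (2, 3, 4, 6, 8, 12)
    depths: tuple = DEFAULT_DEPTH_GRID
    strategies: tuple = ("max-parametric",)
    repetitions: int = 10
    alpha_percent: float = 1.0
    fold_threshold: float = 2.0
    pseudocounts: tuple = (0.0, 1.0)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


@dataclass(frozen=True)
class MultiplexConfig:
    ns: tuple = MULTIPLEX_NS
    strategies: tuple = ("max-parametric",)
    repetitions: int = 10
    alpha_percent: float = 1.0
    fold_threshold: float = 2.0
    pseudocounts: tuple = (0.0, 1.0)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.ns):
            raise ValueError("multiplex scenarios require n >= 2")

    @property
    def depths(self) -> tuple:
        return tuple(1.0 / n for n in self.ns)


# ---------------------------------------------------------------------------
# keyed child seeds
# ---------------------------------------------------------------------------

_STAGE = {"population": 1, "theta": 2, "simulate": 3, "subsample": 4, "null": 5}


def _child_rng(root_seed: int, stage: str, *keys) -> np.random.Generator:
    ints = [int(root_seed), _STAGE[stage]] + [int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


def _depth_key(depth: float) -> int:
    return int(round(depth * 10**6))


def _resolve_strategy(name, population: ParameterPopulation) -> DispersionStrategy:
    if isinstance(name, DispersionStrategy):
        return name
    canonical = STRATEGY_ALIASES.get(name, name)
    if canonical == "oracle":
        return DispersionStrategy("oracle", true_dispersions=population.dispersion)
    return DispersionStrategy(canonical)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def run_null_experiment(config: NullExperimentConfig, seed: int = 0) -> pd.DataFrame:
    """Null-hypothesis calibration: FPR of each strategy at each n.

    Per repetition a fresh paired dataset with all regulating factors at 1
    is simulated for every n; each strategy's raw p-values give the FPR
    overall and within high-/low-count strata.  Returns one tidy row per
    (n, strategy, repetition, stratum).
    """
    if config.repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    population = build_parameter_population(
        config.generator, seed=_child_rng(seed, "population")
    )
    rows = []
    for rep in range(config.repetitions):
        for n in config.ns:
            cm = simulate_counts(population, n, seed=_child_rng(seed, "null", rep, n))
            strata = m.stratify_by_count(cm)
            for strat_name in config.strategies:
                strategy = _resolve_strategy(strat_name, population)
                res = ExactNBTest(cm, strategy=strategy).fit()
                p = res.p_values
                for stratum, mask in (
                    ("all", np.ones(len(p), dtype=bool)),
                    ("high", strata["high"]),
                    ("low", strata["low"]),
                ):
                    value = m.fpr_null(p[mask], config.alpha_percent) if mask.any() else np.nan
                    rows.append(
                        {
                            "experiment": "null",
                            "n": n,
                            "depth": 1.0,
                            "strategy": strategy.name,
                            "repetition": rep,
                            "stratum": stratum,
                            "fpr_null_pct": value,
                            "n_transcripts": int(mask.sum()),
                        }
                    )
        logger.info("null experiment: repetition %d/%d done", rep + 1, config.repetitions)
    return pd.DataFrame(rows)


def _evaluate_cell(
    res_frame: pd.DataFrame,
    calls_fc: dict,
    labels: np.ndarray,
    cm: CountMatrix,
    alpha_percent: float,
) -> list:
    """Metric rows (one per criterion and stratum) for one tested dataset."""
    strata = m.stratify_by_count(cm)
    p_adj = res_frame["p_adj"].to_numpy()
    out = []
    masks = (
        ("all", np.ones(len(labels), dtype=bool)),
        ("high", strata["high"]),
        ("low", strata["low"]),
    )
    for stratum, mask in masks:
        lab = labels[mask]
        out.append(
            {
                "criterion": "adjusted-p",
                "pseudocount": np.nan,
                "stratum": stratum,
                "call_rate_pct": m.call_rate(p_adj[mask], alpha_percent) if mask.any() else np.nan,
                "fpr_pct": m.fpr(p_adj[mask], lab, alpha_percent) if mask.any() else np.nan,
                "tpr_pct": m.tpr(p_adj[mask], lab, alpha_percent) if mask.any() else np.nan,
                "n_transcripts": int(mask.sum()),
                "n_effective_de": int(lab.sum()),
                "n_effective_nonde": int((~lab).sum()),
            }
        )
    for pseudo, calls in calls_fc.items():
        for stratum, mask in masks:
            lab = labels[mask]
            c = calls[mask]
            out.append(
                {
                    "criterion": "fold-change",
                    "pseudocount": pseudo,
                    "stratum": stratum,
                    "call_rate_pct": 100.0 * float(c.mean()) if mask.any() else np.nan,
                    "fpr_pct": 100.0 * float(c[~lab].mean()) if (~lab).any() else np.nan,
                    "tpr_pct": 100.0 * float(c[lab].mean()) if lab.any() else np.nan,
                    "n_transcripts": int(mask.sum()),
                    "n_effective_de": int(lab.sum()),
                    "n_effective_nonde": int((~lab).sum()),
                }
            )
    return out


def _run_de_grid(config, ns, depths_by_n, seed: int, experiment: str) -> pd.DataFrame:
    """Shared engine behind the power grid and the multiplex scenarios."""
    population = build_parameter_population(
        config.generator, seed=_child_rng(seed, "population")
    )
    rows = []
    for rep in range(config.repetitions):
        t0 = time.perf_counter()
        pop = draw_regulating_factors(
            population,
            config.generator.frac_up,
            config.generator.frac_down,
            seed=_child_rng(seed, "theta", rep),
        )
        pop = label_effective_de(pop)
        labels = pop.effective_de
        for n in ns:
            full = simulate_counts(pop, n, seed=_child_rng(seed, "simulate", rep, n))
            for depth in depths_by_n[n]:
                cm = (
                    full
                    if depth == 1.0
                    else subsample_depth(
                        full, depth, seed=_child_rng(seed, "subsample", rep, n, _depth_key(depth))
                    )
                )
                for strat_name in config.strategies:
                    strategy = _resolve_strategy(strat_name, pop)
                    res = ExactNBTest(cm, strategy=strategy).fit()
                    calls_fc = {
                        pseudo: fold_change_detector(
                            cm, threshold=config.fold_threshold, pseudocount=pseudo
                        )
                        for pseudo in config.pseudocounts
                    }
                    for row in _evaluate_cell(
                        res.frame, calls_fc, labels, cm, config.alpha_percent
                    ):
                        row.update(
                            {
                                "experiment": experiment,
                                "n": n,
                                "depth": depth,
                                "strategy": strategy.name,
                                "repetition": rep,
                            }
                        )
                        rows.append(row)
        logger.info(
            "%s: repetition %d/%d done in %.1fs",
            experiment,
            rep + 1,
            config.repetitions,
            time.perf_counter() - t0,
        )
    cols = [
        "experiment",
        "n",
        "depth",
        "strategy",
        "repetition",
        "criterion",
        "pseudocount",
        "stratum",
        "call_rate_pct",
        "fpr_pct",
        "tpr_pct",
        "n_transcripts",
        "n_effective_de",
        "n_effective_nonde",
    ]
    return pd.DataFrame(rows)[cols]


def run_power_grid(config: PowerGridConfig, seed: int = 0) -> pd.DataFrame:
    """Replication x depth power grid with induced DE.

    Per repetition one full-depth dataset is simulated for each n and thinned
    to every depth in the grid, so depth comparisons are paired.  Returns
    tidy rows of call rate / FPR / TPR per (n, depth, strategy, repetition,
    criterion, stratum).
    """
    depths = tuple(sorted(config.depths, reverse=True))
    return _run_de_grid(
        config, config.ns, {n: depths for n in config.ns}, seed, "power-grid"
    )


def run_multiplex_scenarios(config: MultiplexConfig, seed: int = 0) -> pd.DataFrame:
    """Multiplex designs: n samples per condition, each at depth 1/n.

    Cells share their seed derivation with :func:`run_power_grid`, so a
    multiplex cell (n, 1/n) reproduces the grid cell with the same root
    seed.
    """
    depths_by_n = {n: (1.0 / n,) for n in config.ns}
    df = _run_de_grid(config, config.ns, depths_by_n, seed, "multiplex")
    return df


def summarise_repetitions(df: pd.DataFrame, metric_cols=None) -> pd.DataFrame:
    """Median and 90% interval (5th-95th percentile) across repetitions.

    Groups by every scenario column except ``repetition``; each metric
    contributes ``<name>_median``, ``<name>_q05`` and ``<name>_q95``.
    """
    if metric_cols is None:
        metric_cols = [
            c for c in ("fpr_null_pct", "call_rate_pct", "fpr_pct", "tpr_pct") if c in df
        ]
    group_cols = [
        c
        for c in ("experiment", "n", "depth", "strategy", "criterion", "pseudocount", "stratum")
        if c in df
    ]
    gb = df.groupby(group_cols, dropna=False)[metric_cols]
    med = gb.median()
    q05 = gb.quantile(0.05)
    q95 = gb.quantile(0.95)
    out = pd.concat(
        {"median": med, "q05": q05, "q95": q95}, axis=1
    )
    out.columns = [f"{metric}_{stat}" for stat, metric in out.columns]
    return out.reset_index()


def write_report(tables: dict, output_dir, plots: bool = False) -> list:
    """Write tidy TSVs, a JSON summary, and optional figures.

    ``tables`` maps names to per-repetition DataFrames; each is written as
    ``<name>.tsv`` with its repetition summary as ``<name>_summary.tsv``,
    and all summaries are collected into ``summary.json``.  Returns the
    list of written paths.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    summaries = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
        summary = summarise_repetitions(df)
        spath = outdir / f"{name}_summary.tsv"
        summary.to_csv(spath, sep="\t", index=False)
        written.append(spath)
        summaries[name] = json.loads(summary.to_json(orient="records"))
    jpath = outdir / "summary.json"
    jpath.write_text(json.dumps(summaries, indent=2))
    written.append(jpath)
    if plots:
        written.extend(_write_plots(tables, outdir))
    return written


def _write_plots(tables: dict, outdir: Path) -> list:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    written = []
    for name, df in tables.items():
        if "tpr_pct" not in df or df["tpr_pct"].dropna().empty:
            continue
        summary = summarise_repetitions(df)
        sub = summary[
            (summary.get("criterion", "adjusted-p") == "adjusted-p")
            & (summary["stratum"] == "all")
        ]
        if sub.empty:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
        for n, g in sub.groupby("n"):
            g = g.sort_values("depth")
            axes[0].plot(100 * g["depth"], g["tpr_pct_median"], "o-", label=f"n={n}")
            axes[1].plot(100 * g["depth"], g["fpr_pct_median"], "o-", label=f"n={n}")
        axes[0].set_ylabel("TPR (%)")
        axes[1].set_ylabel("FPR (%)")
        for ax in axes:
            ax.set_xlabel("sequencing depth (%)")
        axes[0].legend(fontsize=8)
        fig.suptitle(name)
        fig.tight_layout()
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
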