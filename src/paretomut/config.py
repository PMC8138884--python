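"""Run configuration for optimizations, and the batch-run driver.

A run configuration (YAML or dict) names a dataset bundle, an objective
mode, an optional sample-group restriction plus candidate-gene frequency
filter, the simple optimization setup, and a seed.  ``execute_run`` turns
one configuration into a Pareto table plus a small JSON report;
``run_batch`` executes several configurations across worker processes with
deterministic per-run child seeds (seed + run index).
"""

from __future__ import annotations

import json
import time
import traceback
from concurrent.futures import ProcessPoolExecutor, as_completed
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from . import io as pio
from .metrics import COVERAGE_SIZE, MODES
from .moea import (
    SimpleSetup,
    scheduled_evaluations,
    simple_to_algorithm_params,
    evolve,
)

CONFIG_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """One optimization run over a dataset bundle."""

    dataset: str
    name: str = "run"
    mode: str = COVERAGE_SIZE
    group_attribute: str | None = None
    group_value: str | None = None
    min_frequency: float = 0.0
    max_size: int | None = None
    seed: int = 0
    setup: SimpleSetup = field(default_factory=SimpleSetup)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown objective mode {self.mode!r}")
        if (self.group_attribute is None) != (self.group_value is None):
            raise ConfigurationError(
                "group_attribute and group_value must be given together"
            )

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        raw = dict(raw)
        version = raw.pop("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigurationError(f"unsupported config version {version}")
        setup = SimpleSetup(**raw.pop("setup", {}))
        dataset = raw.pop("dataset", None)
        if dataset is None:
            raise ConfigurationError("config must name a dataset")
        if base_dir is not None and not Path(dataset).is_absolute():
            dataset = str(base_dir / dataset)
        known = {"name", "mode", "group_attribute", "group_value",
                 "min_frequency", "max_size", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(dataset=dataset, setup=setup, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        return cls.from_dict(raw, base_dir=path.parent)


def load_batch(path) -> list[RunConfig]:
    """Load a batch file: ``{seed: int, runs: [run config, ...]}``.

    Per-run child seeds are derived deterministically as seed + run index
    unless a run sets its own seed.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or "runs" not in raw or not raw["runs"]:
        raise ConfigurationError(f"{path}: batch file must list runs")
    base_seed = int(raw.get("seed", 0))
    configs = []
    names = set()
    for i, entry in enumerate(raw["runs"]):
        entry = dict(entry)
        entry.setdefault("seed", base_seed + i)
        entry.setdefault("name", f"run{i + 1}")
        cfg = RunConfig.from_dict(entry, base_dir=path.parent)
        if cfg.name in names:
            raise ConfigurationError(f"duplicate run name {cfg.name!r}")
        names.add(cfg.name)
        configs.append(cfg)
    return configs


def _candidate_genes(matrix, clinical, config: RunConfig):
    """Sample restriction + frequency filter; returns (matrix, genes)."""
    if config.group_attribute is not None:
        if clinical is None:
            raise ConfigurationError(
                "group restriction requires a clinical table"
            )
        if config.group_attribute not in clinical.attributes:
            raise ConfigurationError(
                f"unknown attribute {config.group_attribute!r}"
            )
        col = clinical.data[config.group_attribute]
        keep = [s for s in matrix.sample_ids
                if s in col.index and col.loc[s] == config.group_value]
        if not keep:
            raise ConfigurationError(
                f"no samples with {config.group_attribute} == "
                f"{config.group_value!r}"
            )
        matrix = matrix.subset(samples=keep)
    if config.min_frequency > 0:
        matrix = pio.filter_genes(matrix, min_frequency=config.min_frequency)
    return matrix, matrix.gene_ids


def execute_run(config: RunConfig, out_dir, progress_callback=None) -> dict:
    """Execute one optimization run; writes pareto.tsv + report.json.

    Returns the report dict (also written to disk).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, clinical, _manifest = pio.read_dataset(config.dataset)
    matrix, genes = _candidate_genes(matrix, clinical, config)
    params = simple_to_algorithm_params(config.setup, len(genes),
                                        seed=config.seed)
    pareto = evolve(matrix, genes, config.mode, params,
                    progress_callback=progress_callback)
    pio.write_pareto_table(pareto, out_dir / "pareto.tsv")
    report = {
        "name": config.name,
        "mode": config.mode,
        "n_samples": matrix.n_samples,
        "n_candidate_genes": len(genes),
        "seed": config.seed,
        "n_evaluations": pareto.n_evaluations,
        "n_initial_evaluations": pareto.n_initial_evaluations,
        "n_solutions": len(pareto),
    }
    if config.max_size is not None:
        entry = pareto.max_coverage_within_size(config.max_size)
        if entry is None:
            report["best_within_size"] = None
        else:
            sel, vec = entry
            report["best_within_size"] = {
                "max_size": config.max_size,
                "coverage": vec.coverage,
                "coverage_percent": round(
                    100.0 * vec.coverage / matrix.n_samples, 1
                ) if matrix.n_samples else 0.0,
                "second_objective": vec.second,
                "genes": list(sel.members),
            }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report


def _run_worker(config: RunConfig, out_dir: str) -> dict:
    return execute_run(config, out_dir)


def format_progress(done_runs, total_runs, fraction, elapsed) -> str:
    """`Runs: r/R - Progress: p% - Estimated Duration: HH:MM:SS`."""
    if fraction > 0:
        remaining = elapsed * (1 - fraction) / fraction
    else:
        remaining = 0.0
    secs = int(round(remaining))
    h, rem = divmod(secs, 3600)
    m, s = divmod(rem, 60)
    return (
        f"Runs: {done_runs}/{total_runs} - "
        f"Progress: {100.0 * fraction:.3f}% - "
        f"Estimated Duration: {h:02d}:{m:02d}:{s:02d}"
    )


def run_batch(
    configs: list[RunConfig],
    out_dir,
    threads: int = 1,
    progress=print,
) -> dict:
    """Execute runs across worker processes; one failure does not abort.

    Progress lines report completed scheduled evaluations over the total.
    Returns a summary dict with per-run reports and failures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    budgets = {
        cfg.name: cfg.setup.population_size * cfg.setup.search_steps
        for cfg in configs
    }
    total_budget = sum(budgets.values())
    start = time.monotonic()
    done_budget = 0
    results: dict[str, dict] = {}
    failures: dict[str, str] = {}
    progress(format_progress(0, len(configs), 0.0, 0.0))

    def record(name, outcome, error=None):
        nonlocal done_budget
        done_budget += budgets[name]
        if error is None:
            results[name] = outcome
        else:
            failures[name] = error
        progress(format_progress(
            len(results) + len(failures), len(configs),
            done_budget / total_budget if total_budget else 1.0,
            time.monotonic() - start,
        ))

    if threads <= 1:
        for cfg in configs:
            try:
                record(cfg.name, execute_run(cfg, out_dir / cfg.name))
            except Exception:
                record(cfg.name, None, traceback.format_exc())
    else:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            futures = {
                pool.submit(_run_worker, cfg, str(out_dir / cfg.name)): cfg.name
                for cfg in configs
            }
            for fut in as_completed(futures):
                name = futures[fut]
                try:
                    record(name, fut.result())
                except Exception:
                    record(name, None, traceback.format_exc())
    summary = {
        "runs": results,
        "failures": failures,
        "n_runs": len(configs),
        "n_failed": len(failures),
    }
    (out_dir / "batch_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
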