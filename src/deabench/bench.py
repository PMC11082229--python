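"""End-to-end benchmark orchestration.

Runs a grid of workflows over a collection of datasets, scores every
(workflow, dataset-contrast) cell on the five metrics, averages across
contrasts, and attaches the ranking table with performance levels. Cell
failures are recorded, not fatal — brute-force grids inevitably contain
degenerate combinations — and failed cells are excluded from the means.

Determinism: each cell's randomness derives solely from (master seed,
dataset index, workflow index), so parallel or reordered execution cannot
change the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import WorkflowSpec, validate_workflow
from .evaluate import METRIC_NAMES, aggregate_ranks, lodocv, metric_vector
from .mining import mine_levels, patterns_to_frame
from .simulate import SpikeInDataset
from .stats import run_workflow

__all__ = ["BenchmarkRun", "run_grid", "report"]


@dataclass
class BenchmarkRun:
    grid: list[WorkflowSpec]
    dataset_ids: list[str]
    cell_metrics: pd.DataFrame      # rows: (workflow, dataset); columns: metrics
    mean_metrics: pd.DataFrame      # rows: workflow; columns: metrics
    ranking: pd.DataFrame
    failures: list[tuple[str, str, str]] = field(default_factory=list)
    seed: int = 0

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "grid": [f"{s.setting}:{s}" for s in self.grid],
                "datasets": self.dataset_ids,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cell_seed(master_seed: int, dataset_index: int, workflow_index: int) -> int:
    ss = np.random.SeedSequence(entropy=(master_seed, dataset_index, workflow_index))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_grid(
    datasets: Sequence[SpikeInDataset],
    grid: Sequence[WorkflowSpec],
    seed: int = 0,
    dataset_ids: Sequence[str] | None = None,
) -> BenchmarkRun:
    """Score every workflow on every dataset and rank the grid."""
    grid = list(grid)
    for spec in grid:
        violations = validate_workflow(spec)
        if violations:
            raise ValueError(f"invalid grid workflow {spec}: {violations}")
    ids = list(dataset_ids) if dataset_ids else [f"ds{i}" for i in range(len(datasets))]
    rows = []
    failures: list[tuple[str, str, str]] = []
    for d_i, (ds_id, ds) in enumerate(zip(ids, datasets)):
        for w_i, spec in enumerate(grid):
            try:
                result = run_workflow(
                    ds.views, spec, ds.design, seed=_cell_seed(seed, d_i, w_i)
                )
                mv = metric_vector(result, ds.truth)
                rows.append({"workflow": str(spec), "dataset": ds_id,
                             **dict(zip(METRIC_NAMES, mv.as_array()))})
            except Exception as err:  # noqa: BLE001 - failures are data
                failures.append((str(spec), ds_id, str(err)))
    if not rows:
        raise RuntimeError("every grid cell failed")
    cells = pd.DataFrame(rows)
    mean_metrics = (
        cells.drop(columns="dataset").groupby("workflow").mean().sort_index()
    )
    ranking = aggregate_ranks(mean_metrics)
    return BenchmarkRun(
        grid=grid,
        dataset_ids=ids,
        cell_metrics=cells,
        mean_metrics=mean_metrics,
        ranking=ranking,
        failures=failures,
        seed=seed,
    )


def report(run: BenchmarkRun, out_dir) -> dict[str, Path]:
    """Write ranking, H/L pattern, and LODOCV tables; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ranking = run.ranking.copy()
    ranking.insert(0, "workflow", ranking.index)
    ranking["config_hash"] = run.config_hash
    paths["ranking"] = out / "ranking.tsv"
    ranking.to_csv(paths["ranking"], sep="\t", index=False, float_format="%.10g")

    for level in ("H", "L"):
        try:
            patterns = mine_levels(run.ranking, run.grid, level)
        except ValueError:
            patterns = []
        frame = patterns_to_frame(patterns)
        frame["config_hash"] = run.config_hash
        paths[f"patterns_{level}"] = out / f"patterns_{level}.tsv"
        frame.to_csv(paths[f"patterns_{level}"], sep="\t", index=False,
                     float_format="%.10g")

    if len(run.dataset_ids) >= 3:
        per_dataset = {
            ds: df.drop(columns="dataset").set_index("workflow").sort_index()
            for ds, df in run.cell_metrics.groupby("dataset")
        }
        complete = {
            ds: df for ds, df in per_dataset.items()
            if df.shape[0] == len(run.grid)
        }
        if len(complete) >= 3 and len(run.grid) >= 3:
            r = lodocv(complete)
            frame = r.rename_axis("dataset").reset_index()
            frame["config_hash"] = run.config_hash
            paths["lodocv"] = out / "lodocv.tsv"
            frame.to_csv(paths["lodocv"], sep="\t", index=False, float_format="%.10g")

    if run.failures:
        frame = pd.DataFrame(run.failures, columns=["workflow", "dataset", "error"])
        paths["failures"] = out / "failures.tsv"
        frame.to_csv(paths["failures"], sep="\t", index=False)
    return paths
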