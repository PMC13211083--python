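"""Ablation and loss-comparison harnesses.

``run_ablation`` trains and evaluates the detector over a grid of
component flags (aligned backbone on/off, spectral neck on/off, IPIoUv2
on/off) on the same synthetic dataset and seed, mirroring a factorial
ablation table.  ``run_loss_comparison`` keeps the architecture fixed
and swaps only the box-regression loss.

Both share one master seed that fans out to data generation, weight
initialization and batch ordering, so every row sees identical data.
"""

from __future__ import annotations

import itertools
import traceback

from .config import RunConfig, apply_ablation
from .losses import REGRESSION_LOSSES
from .model import DetectionModel

__all__ = ["run_ablation", "run_loss_comparison", "rows_to_markdown", "ABLATION_GRID"]

ABLATION_GRID = [dict(zip(("msanet", "ssaff", "ipiouv2"), bits))
                 for bits in itertools.product([False, True], repeat=3)]

_METRIC_KEYS = ("precision", "recall", "map50", "map50_95")


def _run_one(config: RunConfig, row: dict) -> dict:
    try:
        results = DetectionModel(config).fit()
        row.update({k: results.metrics[k] for k in _METRIC_KEYS})
        row["params"] = results.num_parameters
        row["final_loss"] = results.history[-1]["total"] if results.history else None
        row["error"] = None
    except Exception as e:                       # record failures, keep going
        row["error"] = f"{type(e).__name__}: {e}"
        row["traceback"] = traceback.format_exc()
    return row


def run_ablation(grid: list[dict] | None, config: RunConfig) -> list[dict]:
    """Train/evaluate every flag combination; returns one row per
    combination with the four metrics and the parameter count."""
    grid = ABLATION_GRID if grid is None else grid
    rows = []
    for flags in grid:
        cfg = apply_ablation(config, **flags)
        rows.append(_run_one(cfg, dict(flags)))
    return rows


def run_loss_comparison(losses: list[str], config: RunConfig) -> list[dict]:
    """Train the identical model/seed once per regression loss."""
    for name in losses:
        if name not in REGRESSION_LOSSES:
            raise KeyError(f"unknown regression loss {name!r}")
    rows = []
    for name in losses:
        cfg = config.model_copy(deep=True)
        cfg.train.regression_loss = name
        rows.append(_run_one(cfg, {"loss": name}))
    return rows


def rows_to_markdown(rows: list[dict]) -> str:
    if not rows:
        return ""
    keys = list(rows[0].keys())
    keys = [k for k in keys if k != "traceback"]
    lines = ["| " + " | ".join(keys) + " |",
             "|" + "|".join("---" for _ in keys) + "|"]
    for row in rows:
        cells = []
        for k in keys:
            v = row.get(k)
            cells.append(f"{v:.4f}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
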