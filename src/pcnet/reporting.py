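"""Result aggregation and table rendering.

Per-task accuracies are reported to 2 decimals with round-half-up, the
"Average" column is the unweighted mean of the per-task cells, and
algorithm deltas are annotated as ``(+x.xx)`` / ``(-x.xx)`` next to the
second algorithm's cell.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError


def round2(x: float) -> float:
    """Round half up to 2 decimals (0.005 -> 0.01)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def delta_annotation(value: float, reference: float) -> str:
    """Formatted difference ``value - reference``, e.g. ``(+4.45)``."""
    d = round2(value - reference)
    sign = "+" if d >= 0 else "-"
    return f"({sign}{abs(d):.2f})"


def final_row_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Seed-mean final evaluation row per (algorithm, method).

    Expects the tidy incremental schema (seed, algorithm, method,
    task_trained, task_evaluated, accuracy); keeps only the final row
    (task_trained == max) and averages over seeds.
    """
    required = {"seed", "algorithm", "method", "task_trained",
                "task_evaluated", "accuracy"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"results frame is missing columns {sorted(missing)}")
    last = frame[frame.task_trained == frame.task_trained.max()]
    table = (last.groupby(["algorithm", "method", "task_evaluated"])
             .accuracy.mean().unstack("task_evaluated"))
    table.columns = [f"Task{int(c)}" for c in table.columns]
    table["Average"] = table.mean(axis=1)
    return table.map(round2)


def render_incremental_table(frame: pd.DataFrame) -> str:
    """Markdown table mirroring the per-task / Average layout."""
    table = final_row_table(frame)
    cols = list(table.columns)
    lines = ["| Algorithm | Method | " + " | ".join(cols) + " |",
             "|---|---|" + "---|" * len(cols)]
    for (algo, method), row in table.iterrows():
        cells = " | ".join(f"{row[c]:.2f}" for c in cols)
        lines.append(f"| {algo.upper()} | {method.upper()} | {cells} |")
    return "\n".join(lines)


def render_comparison_table(frame: pd.DataFrame, index_cols, value_col="accuracy",
                            baseline="bp", comparison="pc") -> str:
    """Grid with the comparison algorithm annotated against the baseline.

    ``frame`` must have an ``algorithm`` column plus ``index_cols``; cells
    for the comparison algorithm get ``(+x.xx)`` deltas.
    """
    pivot = frame.pivot_table(index="algorithm", columns=index_cols,
                              values=value_col)
    if baseline not in pivot.index or comparison not in pivot.index:
        raise ConfigurationError(
            f"need both {baseline!r} and {comparison!r} rows to compare")
    cols = list(pivot.columns)
    head = " | ".join(str(c) for c in cols)
    lines = [f"| Algorithm | {head} |", "|---|" + "---|" * len(cols)]
    base = pivot.loc[baseline]
    lines.append("| " + baseline.upper() + " | "
                 + " | ".join(f"{round2(base[c]):.2f}" for c in cols) + " |")
    comp = pivot.loc[comparison]
    cells = [f"{round2(comp[c]):.2f} {delta_annotation(comp[c], base[c])}"
             for c in cols]
    lines.append("| " + comparison.upper() + " | " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_tables(results_dir) -> str:
    """Aggregate every recognised CSV in a results directory into one report."""
    results_dir = Path(results_dir)
    if not results_dir.is_dir():
        raise ConfigurationError(f"{results_dir} is not a directory")
    sections = []
    inc = results_dir / "incremental.csv"
    if inc.exists():
        sections.append("## Incremental learning (final evaluation)\n\n"
                        + render_incremental_table(pd.read_csv(inc)))
    lt = results_dir / "longtail.csv"
    if lt.exists():
        frame = pd.read_csv(lt)
        sections.append("## Long-tailed recognition\n\n"
                        + render_comparison_table(frame, ["objective", "gamma"]))
    fs = results_dir / "fewshot.csv"
    if fs.exists():
        frame = pd.read_csv(fs)
        sections.append("## Few-shot recognition\n\n"
                        + render_comparison_table(frame, ["n_way", "k_shot"]))
    if not sections:
        raise ConfigurationError(f"no result CSVs found in {results_dir}")
    return "\n\n".join(sections) + "\n"
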