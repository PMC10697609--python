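"""Human-readable markdown report for a pipeline run."""

from __future__ import annotations

import pandas as pd

from .design import TaskDesign
from .groupstats import GroupResult
from .metrics import CONDITION_LABELS, optimal_benchmarks

__all__ = ["render_report"]


def _fmt(x, nd=4):
    if x is None:
        return ""
    return f"{x:.{nd}g}"


def render_report(
    metrics: pd.DataFrame,
    results: list[GroupResult],
    design: TaskDesign,
    variance_mode: str = "centroid",
) -> str:
    """Markdown summary: condition-wise sensory weights against the normative
    benchmarks, exclusion counts, and the correlation battery."""
    bench = optimal_benchmarks(design, variance_mode)
    kept = metrics[~metrics["excluded"].astype(bool)]
    lines = ["# Coin-task pipeline report", ""]
    lines += [
        f"Participants analysed: {len(kept)} of {len(metrics)} "
        f"({int(metrics['excluded'].astype(bool).sum())} excluded).",
        "",
    ]
    for reason, count in metrics.loc[metrics["excluded"].astype(bool), "exclusion_reason"].value_counts().items():
        lines.append(f"- excluded ({reason}): {count}")
    if metrics["excluded"].astype(bool).any():
        lines.append("")

    lines += [
        "## Sensory weights by condition",
        "",
        "| condition | mean sw | sd | optimal sw |",
        "|---|---|---|---|",
    ]
    for c in CONDITION_LABELS:
        col = kept[f"sw_{c}"]
        lines.append(
            f"| {c} | {_fmt(col.mean())} | {_fmt(col.std(ddof=1))} | {_fmt(bench['sw_opt'][c])} |"
        )
    lines += ["", "## Correlation battery", ""]
    lines += ["| comparison | estimator | statistic | p | 95% CI | adjusted p | n |", "|---|---|---|---|---|---|---|"]
    for r in results:
        ci = f"[{_fmt(r.ci_low)}, {_fmt(r.ci_high)}]" if r.ci_low is not None else ""
        lines.append(
            f"| {r.name} | {r.estimator} | {_fmt(r.statistic)} | {_fmt(r.p_value, 3)} | {ci} | "
            f"{_fmt(r.p_adjusted, 3)} | {r.n_used} |"
        )
    lines.append("")
    return "\n".join(lines)
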