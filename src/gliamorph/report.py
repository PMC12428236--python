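"""Two-group statistics and run reports.

Morphological measurements across cell populations are typically
non-normal, so group comparisons use the two-sided Mann–Whitney U test
(with a rank-biserial-style effect size r = Z/√N and a Hodges–Lehmann
95% confidence interval on the median difference) corroborated by the
two-sample Kolmogorov–Smirnov test. Analyses run at the individual-cell
level, which inflates the apparent sample size; every comparison carries
an explicit caveat and the run report prints per-animal cell counts so
pseudoreplication is visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import FEATURE_COLUMNS

__all__ = ["GroupComparison", "compare_groups", "run_report", "StageError"]

CELL_LEVEL_CAVEAT = (
    "Statistics computed at the individual-cell level; this increases the "
    "apparent sample size and may overstate significance. Per-animal cell "
    "counts are reported for assessing pseudoreplication."
)


class StageError(FileNotFoundError):
    """A required upstream output is missing; the message names the stage."""


@dataclass
class GroupComparison:
    parameter: str
    groups: tuple[str, str]
    n: tuple[int, int]
    mw_U: float
    mw_p: float
    effect_size_r: float  # Z/sqrt(N), signed, in [-1, 1]
    median_difference: float  # Hodges–Lehmann estimate, group1 − group2
    ci_low: float
    ci_high: float
    ks_D: float
    ks_p: float
    caveat: str = CELL_LEVEL_CAVEAT

    def to_dict(self) -> dict:
        return asdict(self)


def _mann_whitney_z(x: np.ndarray, y: np.ndarray, U1: float) -> float:
    """Z statistic of U with tie correction (no continuity correction)."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 0.0
    return float((U1 - n1 * n2 / 2.0) / np.sqrt(sigma2))


def _hodges_lehmann_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Hodges–Lehmann estimate and distribution-free CI for the shift x − y.

    The CI takes the k-th smallest and k-th largest of all pairwise
    differences, with k from the normal approximation to the Mann–Whitney
    null distribution.
    """
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    m = len(diffs)
    estimate = float(np.median(diffs))
    n1, n2 = len(x), len(y)
    z = stats.norm.ppf(1 - alpha / 2)
    k = int(np.floor(n1 * n2 / 2.0 - z * np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)))
    k = max(k, 0)
    if k >= m / 2:
        k = 0
    return estimate, float(diffs[k]), float(diffs[m - 1 - k])


def compare_groups(
    records: pd.DataFrame,
    group_column: str = "group",
    parameters: list[str] | None = None,
) -> list[GroupComparison]:
    """Per-parameter two-group comparison (Mann–Whitney + KS).

    Exactly two groups are required (more than two clusters belong in
    :func:`gliamorph.clustering.cluster_comparisons`). Groups are taken
    in sorted label order; signs of r and the median difference refer to
    group1 − group2.
    """
    parameters = parameters or [c for c in FEATURE_COLUMNS if c in records.columns]
    group_names = sorted(records[group_column].dropna().unique())
    if len(group_names) != 2:
        raise ValueError(
            f"compare_groups requires exactly 2 groups, found {len(group_names)}; "
            "use clustering.cluster_comparisons for multi-group designs"
        )
    g1, g2 = group_names
    out = []
    for param in parameters:
        x = records.loc[records[group_column] == g1, param].to_numpy(dtype=np.float64)
        y = records.loc[records[group_column] == g2, param].to_numpy(dtype=np.float64)
        if len(x) < 3 or len(y) < 3:
            raise ValueError(f"each group needs n >= 3 (parameter {param})")
        mw = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        z = _mann_whitney_z(x, y, float(mw.statistic))
        r = z / np.sqrt(len(x) + len(y))
        est, lo, hi = _hodges_lehmann_ci(x, y)
        ks = stats.ks_2samp(x, y)
        out.append(
            GroupComparison(
                parameter=param,
                groups=(str(g1), str(g2)),
                n=(len(x), len(y)),
                mw_U=float(mw.statistic),
                mw_p=float(mw.pvalue),
                effect_size_r=float(np.clip(r, -1.0, 1.0)),
                median_difference=est,
                ci_low=lo,
                ci_high=hi,
                ks_D=float(ks.statistic),
                ks_p=float(ks.pvalue),
            )
        )
    return out


# ---------------------------------------------------------------------------
# run report


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"missing output of the {stage} stage: {path}")
    return path


def run_report(run_dir: str | Path, config_echo: dict | None = None) -> dict:
    """Assemble the end-of-run JSON report from a run directory.

    Expects ``audit.csv`` (segmentation), ``morphometrics.csv``
    (morphometry) and optionally ``cluster_labels.csv`` +
    ``frequency_table.csv`` (clustering). A missing required file raises
    :class:`StageError` naming the stage.
    """
    run_dir = Path(run_dir)
    audit = pd.read_csv(_require(run_dir / "audit.csv", "segmentation"))
    morpho = pd.read_csv(_require(run_dir / "morphometrics.csv", "morphometry"))

    report: dict = {
        "cells": {
            "total_objects": int(len(audit)),
            "included": int(audit["included"].sum()),
            "excluded_by_reason": audit.loc[~audit["included"], "exclusion_reason"]
            .value_counts()
            .to_dict(),
        },
        "per_animal_cell_counts": morpho.groupby(["group", "animal_id"])["cell_id"]
        .count()
        .to_dict()
        if "animal_id" in morpho.columns and len(morpho)
        else {},
        "caveat": CELL_LEVEL_CAVEAT,
    }
    params = [c for c in FEATURE_COLUMNS if c in morpho.columns]
    summaries: dict = {}
    for (group,), sub in morpho.groupby(["group"]) if "group" in morpho.columns else []:
        summaries[str(group)] = {
            p: {
                "median": float(sub[p].median()),
                "q1": float(sub[p].quantile(0.25)),
                "q3": float(sub[p].quantile(0.75)),
            }
            for p in params
        }
        summaries[str(group)]["n_cells"] = int(len(sub))
    report["group_summaries"] = summaries
    if "group" in morpho.columns and morpho["group"].nunique() == 2:
        report["group_comparisons"] = [c.to_dict() for c in compare_groups(morpho)]

    labels_path = run_dir / "cluster_labels.csv"
    freq_path = run_dir / "frequency_table.csv"
    if labels_path.exists() or freq_path.exists():
        _require(labels_path, "clustering")
        _require(freq_path, "clustering")
        freq = pd.read_csv(freq_path, index_col=0)
        report["cluster_frequencies"] = {
            str(g): {str(c): int(v) for c, v in row.items()} for g, row in freq.iterrows()
        }
    if config_echo is not None:
        report["config"] = config_echo

    # stable serialization: keys of nested dicts stringified
    per_animal = report.pop("per_animal_cell_counts")
    report["per_animal_cell_counts"] = {str(k): int(v) for k, v in per_animal.items()}
    return report


def write_report(report: dict, run_dir: str | Path) -> tuple[Path, Path]:
    """Write ``report.json`` and a human-readable ``report.md``."""
    run_dir = Path(run_dir)
    json_path = run_dir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    lines = ["# gliamorph run report", ""]
    cells = report.get("cells", {})
    lines.append(
        f"- objects: {cells.get('total_objects', 0)}, included cells: {cells.get('included', 0)}"
    )
    for reason, n in cells.get("excluded_by_reason", {}).items():
        lines.append(f"  - excluded ({reason}): {n}")
    for group, summary in report.get("group_summaries", {}).items():
        lines.append(f"\n## {group} (n = {summary.get('n_cells', '?')})")
        for p, q in summary.items():
            if isinstance(q, dict):
                lines.append(f"- {p}: median {q['median']:.3g} [{q['q1']:.3g}, {q['q3']:.3g}]")
    if "group_comparisons" in report:
        lines.append("\n## Group comparisons (Mann–Whitney / KS)")
        for c in report["group_comparisons"]:
            lines.append(
                f"- {c['parameter']}: U={c['mw_U']:.1f} p={c['mw_p']:.3g}, "
                f"r={c['effect_size_r']:.3f}, Δmedian={c['median_difference']:.3g} "
                f"[{c['ci_low']:.3g}, {c['ci_high']:.3g}], KS D={c['ks_D']:.3f} p={c['ks_p']:.3g}"
            )
        lines.append(f"\n> {CELL_LEVEL_CAVEAT}")
    md_path = run_dir / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    return json_path, md_path
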