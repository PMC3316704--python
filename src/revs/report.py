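"""Run configuration and report writing.

Every run can be serialised to a small set of CSV tables plus a plain-text
log: the nested model-sequence table (one row per model — entered variable,
relationship sign, adjusted R², Δ AIC, support category, P, best-model
marker, with tie alternatives appended), the method-comparison table, the
TRUE/FALSE level matrix, the inclusion ranking, and a run log carrying the
seed and configuration so any report can be regenerated byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import MethodComparison
from .dataset import DEFAULT_PREDICTOR_CAP
from .engine import REVSModelSequence, categorize_support
from .search import EXHAUSTIVE_THRESHOLD, LevelSelectionMatrix

__all__ = ["RunConfig", "sequence_table", "write_reports"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run; echoed into every report."""

    input_path: str = ""
    response: str = "y"
    cap: int = DEFAULT_PREDICTOR_CAP
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD
    allow_wide_ties: bool = False
    stepwise_direction: str = "forward"
    stepwise_criterion: str = "pvalue"
    alpha: float = 0.05
    min_drop: float = 2.0
    holdout: int | None = None
    seed: int = 0
    output_dir: str = "revs_output"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.cap < 1 or self.exhaustive_threshold < 0:
            raise ValueError("cap and exhaustive_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_drop < 0:
            raise ValueError("min_drop must be non-negative")

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return "" if np.isnan(x) else f"{x:.6g}"
    return str(x)


def sequence_table(seq: REVSModelSequence) -> pd.DataFrame:
    """The nested series as a table, tie alternatives appended at the end."""
    rows = []
    for j, (fit, var, sign, delta) in enumerate(
        zip(seq.models, seq.entered, seq.entered_signs, seq.delta_aic), 1
    ):
        name = seq.ranking.predictor_names[var]
        row = {
            "model": j,
            "kind": "primary",
            "entered_variable": name,
            "relationship": (
                "positive" if sign > 0 else "negative" if sign < 0 else ""
            ),
            "k": j,
            "fitted": fit is not None,
        }
        if fit is not None:
            row.update(
                adj_r2=fit.adj_r2,
                aic=fit.aic,
                delta_aic=delta,
                support=(
                    categorize_support(delta).label
                    if np.isfinite(delta)
                    else ""
                ),
                p_value=fit.p_value,
            )
        row["best"] = seq.best_by_aic == ("primary", j - 1)
        rows.append(row)
    for i, (alt, delta) in enumerate(
        zip(seq.alternatives, seq.alternative_delta_aic)
    ):
        names = tuple(seq.ranking.predictor_names[v] for v in alt.chosen)
        rows.append(
            {
                "model": len(seq.models) + i + 1,
                "kind": "tie-alternative",
                "entered_variable": "+".join(names),
                "relationship": "",
                "k": alt.fit.k,
                "fitted": True,
                "adj_r2": alt.fit.adj_r2,
                "aic": alt.fit.aic,
                "delta_aic": delta,
                "support": categorize_support(delta).label
                if np.isfinite(delta)
                else "",
                "p_value": alt.fit.p_value,
                "best": seq.best_by_aic == ("alternative", i),
            }
        )
    return pd.DataFrame(rows)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_reports(
    seq: REVSModelSequence,
    comparison: MethodComparison | None,
    config: RunConfig,
    outdir,
    matrix: LevelSelectionMatrix | None = None,
) -> list[Path]:
    """Write all report files into ``outdir``; returns the paths written.

    Identical inputs (sequence, comparison, config) produce byte-identical
    files, so a seed + config pair fully determines the report set.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    written: list[Path] = []

    seq_path = out / "model_sequence.csv"
    _write_csv(sequence_table(seq), seq_path)
    written.append(seq_path)

    rank = seq.ranking
    rank_path = out / "inclusion_ranking.csv"
    _write_csv(
        pd.DataFrame(
            {
                "rank": range(1, rank.p + 1),
                "variable": [rank.predictor_names[v] for v in rank.order],
                "inclusion_count": [rank.counts[v] for v in rank.order],
                "tie_group_size": [len(rank.group_of(v)) for v in rank.order],
            }
        ),
        rank_path,
    )
    written.append(rank_path)

    if matrix is not None:
        mat_path = out / "level_matrix.csv"
        frame = matrix.to_frame().map(lambda v: "TRUE" if v else "FALSE")
        frame.insert(0, "level", range(1, matrix.p + 1))
        _write_csv(frame, mat_path)
        written.append(mat_path)

    if comparison is not None:
        cmp_path = out / "method_comparison.csv"
        frame = comparison.to_frame().reset_index()
        frame["subset"] = frame["subset"].map(
            lambda s: " ".join(str(i) for i in s)
        )
        frame["names"] = frame["names"].map(lambda s: " ".join(s))
        _write_csv(frame, cmp_path)
        written.append(cmp_path)

    log_path = out / "run_log.txt"
    best = seq.best_by_aic
    lines = [
        "revs run log",
        "============",
        f"n predictors: {seq.p}",
        f"primary models: {sum(m is not None for m in seq.models)}",
        f"tie alternatives: {len(seq.alternatives)}",
        f"tie groups (size > 1): "
        f"{sum(1 for g in rank.tie_groups if len(g) > 1)}",
        f"best model (lowest AIC): {best[0]} #{best[1] + 1}"
        if best
        else "best model: none fitted",
        f"best-model AIC: {_fmt(seq.best_model.aic) if best else ''}",
        f"best-model variables: "
        f"{' '.join(seq.best_model.names) if best else ''}",
        "",
        "configuration",
        "-------------",
        config.to_text(),
    ]
    log_path.write_text("\n".join(lines))
    written.append(log_path)
    for path in written:
        logger.info("wrote %s", path)
    return written
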