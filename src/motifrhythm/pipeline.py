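"""End-to-end orchestration: import -> extract -> metrics -> compare /
correlate -> null simulation, with deterministic CSV/JSON outputs.

CSV files are the contract; plots are conveniences written alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import group_stats, io_annotations, null_simulation, rhythm_metrics
from .errors import InsufficientDataError, MotifRhythmError, ValidationError
from .records import SUBSET_ORDER, AnnotatedMotif, IOISequence, SubsetKind, group_motifs_by_nest
from .sequence_matching import MatchConfig, build_analysis_units

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the YAML config file."""

    out_dir: Path
    motifs_csv: Optional[Path] = None
    textgrid_dir: Optional[Path] = None
    tier_name: str = "elements"
    min_intervals: int = 3
    match_mode: str = "subsequence"
    family: str = "per-parameter"
    tutee_subset_for_correlation: str = "everything"
    nullsim_n: int = 1000
    nullsim_min_elements: int = 4
    nullsim_max_elements: int = 22
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.motifs_csv is None and self.textgrid_dir is None:
            raise ValidationError("pipeline needs motifs_csv or textgrid_dir input")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: pipeline config must be a mapping")
        return cls(**raw)


class StageError(MotifRhythmError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def units_to_frame(units: list[IOISequence]) -> pd.DataFrame:
    rows = [
        {
            "nest_id": u.nest_id,
            "bird_id": u.bird_id,
            "motif_id": u.motif_id,
            "subset_kind": u.subset_kind.value,
            "start_index": u.start_index,
            "end_index": u.end_index,
            "n_elements": u.n_elements,
            "n_iois": u.n_iois,
            "ioi_list": ";".join(f"{d:.6f}" for d in u.iois),
        }
        for u in units
    ]
    cols = ["nest_id", "bird_id", "motif_id", "subset_kind", "start_index",
            "end_index", "n_elements", "n_iois", "ioi_list"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(
        ["nest_id", "bird_id", "motif_id", "subset_kind", "start_index"],
        kind="mergesort",
    ).reset_index(drop=True)


def units_from_frame(df: pd.DataFrame) -> list[IOISequence]:
    units = []
    for row in df.itertuples(index=False):
        units.append(
            IOISequence(
                iois=np.array([float(x) for x in str(row.ioi_list).split(";")]),
                nest_id=str(row.nest_id), bird_id=str(row.bird_id),
                motif_id=str(row.motif_id),
                subset_kind=SubsetKind(row.subset_kind),
                start_index=int(row.start_index), end_index=int(row.end_index),
            )
        )
    return units


def extract_all_units(
    motifs: list[AnnotatedMotif], match_config: MatchConfig
) -> list[IOISequence]:
    """Analysis units for every nest in a motif collection."""
    nests = group_motifs_by_nest(motifs)
    units: list[IOISequence] = []
    for nest_id in sorted(nests):
        roles = nests[nest_id]
        if not roles["tutor"]:
            raise ValidationError(f"nest {nest_id} has no tutor motifs")
        units.extend(build_analysis_units(roles["tutor"], roles["tutee"], match_config))
    return units


def _write_plots(units: list[IOISequence], metrics: pd.DataFrame,
                 nest_corr, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = rhythm_metrics.ioi_histogram(units, by="overall")
    fig, ax = plt.subplots(figsize=(6, 4))
    for role, color in (("tutor", "darkred"), ("tutee", "darkgreen")):
        sub = hist[hist["role"] == role]
        ax.bar(sub["bin_left_s"], sub["percent"], width=0.01, align="edge",
               alpha=0.6, label=role, color=color)
    ax.set_xlabel("IOI (s)"); ax.set_ylabel("% of role's IOIs"); ax.legend()
    fig.savefig(out_dir / "ioi_distribution.png", dpi=120); plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(nest_corr.tutor_means, nest_corr.tutee_means, marker="x")
    lims = [min(nest_corr.tutor_means + nest_corr.tutee_means) - 1,
            max(nest_corr.tutor_means + nest_corr.tutee_means) + 1]
    ax.plot(lims, lims, ls=":", c="grey")
    ax.set_xlabel("tutor mean IOI beat (Hz)"); ax.set_ylabel("tutee mean IOI beat (Hz)")
    ax.set_title(f"r = {nest_corr.r:.2f}")
    fig.savefig(out_dir / "beat_per_nest.png", dpi=120); plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    kinds = [k.value for k in SUBSET_ORDER if k.value in set(metrics["subset_kind"])]
    for ax, param in zip(axes, rhythm_metrics.METRIC_COLUMNS):
        data = [metrics.loc[metrics["subset_kind"] == k, param] for k in kinds]
        ax.boxplot(data, tick_labels=kinds)
        ax.set_title(param)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out_dir / "parameters_by_group.png", dpi=120); plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing the report bundle into ``config.out_dir``.

    Returns the summary dictionary (also written as summary.json).  A stage
    failure raises :class:`StageError`; outputs of earlier stages remain on
    disk.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    stage = "import"
    try:
        if config.motifs_csv is not None:
            motifs = io_annotations.read_csv(config.motifs_csv)
        else:
            motifs = io_annotations.read_textgrid_dir(
                config.textgrid_dir, tier_name=config.tier_name
            )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "extract"
    try:
        match_config = MatchConfig(
            min_intervals=config.min_intervals, match_mode=config.match_mode
        )
        units = extract_all_units(motifs, match_config)
        units_df = units_to_frame(units)
        units_df.to_csv(out / "units.csv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "metrics"
    try:
        metrics = rhythm_metrics.summarize_units(units)
        metrics.to_csv(out / "metrics.csv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "compare"
    try:
        comparisons = group_stats.welch_comparisons(metrics, family=config.family)
        group_stats.comparisons_to_frame(comparisons).to_csv(
            out / "comparisons.csv", index=False
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "correlate"
    try:
        nest_corr = group_stats.nest_beat_correlation(
            metrics, SubsetKind(config.tutee_subset_for_correlation)
        )
        length_corr = group_stats.length_correlations(metrics)
        length_corr.to_csv(out / "correlations.csv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "nullsim"
    try:
        pool = np.concatenate([u.iois for u in units])
        null_cfg = null_simulation.NullSimConfig(
            ioi_pool=pool, n_sequences=config.nullsim_n,
            min_elements=config.nullsim_min_elements,
            max_elements=config.nullsim_max_elements, seed=config.seed,
        )
        null_metrics, null_corr = null_simulation.run_null_simulation(null_cfg)
        null_metrics.to_csv(out / "nullsim.csv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "summary"
    try:
        per_nest_beats = {
            nest: {
                role: round(float(
                    metrics.loc[
                        (metrics["nest_id"] == nest) & (metrics["role"] == role)
                        & (metrics["subset_kind"].isin(
                            ["tutor", "everything"]
                        )),
                        "ioi_beat_hz",
                    ].mean()), 6)
                for role in ("tutor", "tutee")
            }
            for nest in sorted(set(metrics["nest_id"]))
        }
        summary = {
            "seed": config.seed,
            "n_motifs": len(motifs),
            "n_units": len(units),
            "unit_counts": {
                k.value: int((units_df["subset_kind"] == k.value).sum())
                for k in SUBSET_ORDER
            },
            "per_nest_mean_ioi_beat_hz": per_nest_beats,
            "nest_beat_correlation": {"r": nest_corr.r, "p": nest_corr.p},
            "length_correlations": {
                row.parameter: row.r for row in length_corr.itertuples(index=False)
            },
            "nullsim_length_correlations": {
                row.parameter: (None if pd.isna(row.r) else row.r)
                for row in null_corr.itertuples(index=False)
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    if config.make_plots:
        stage = "plots"
        try:
            _write_plots(units, metrics, nest_corr, out)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    return summary
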