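"""Comparative statistics over the rhythm-metrics table.

Pairwise Welch (unequal-variance) t-tests between analysis subsets with a
Bonferroni family-wise correction and pooled-sd Cohen's d; per-nest
tutor-mean vs tutee-mean Pearson correlation of the IOI beat; and Pearson
correlations between each rhythm parameter and sequence length.

The observation unit is the analysis sequence (units are pooled across
birds; a per-bird-mean aggregation is available for sensitivity analysis
but is not the default, mirroring the decision not to fit mixed models).
"""

from __future__ import annotations

import itertools
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .records import SUBSET_ORDER, ComparisonResult, NestCorrelation, SubsetKind
from .rhythm_metrics import METRIC_COLUMNS

logger = logging.getLogger(__name__)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-sd Cohen's d, sign = mean(a) - mean(b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def welch_pairwise(
    samples: dict[SubsetKind, np.ndarray], parameter: str, family_size: int
) -> list[ComparisonResult]:
    """Welch t-test + Bonferroni + Cohen's d for every unordered pair of
    groups, ordered TUTOR < EVERYTHING < ALL_SHARED < PART_SHARED <
    NOT_SHARED (group_a precedes group_b)."""
    present = [k for k in SUBSET_ORDER if k in samples]
    results: list[ComparisonResult] = []
    for ga, gb in itertools.combinations(present, 2):
        a, b = samples[ga], samples[gb]
        if a.size < 2 or b.size < 2:
            logger.warning("skipping %s %s vs %s: group with < 2 units",
                           parameter, ga, gb)
            continue
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and a[0] == b[0]:
            t, p = 0.0, 1.0  # identical constant samples: no evidence at all
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        results.append(
            ComparisonResult(
                parameter=parameter, group_a=ga, group_b=gb,
                t_stat=float(t), p_raw=float(p),
                p_adj=min(1.0, float(p) * family_size),
                cohens_d=cohens_d(a, b), n_a=int(a.size), n_b=int(b.size),
            )
        )
    return results


def welch_comparisons(
    metrics: pd.DataFrame,
    parameters: Sequence[str] = METRIC_COLUMNS,
    family: str = "per-parameter",
) -> list[ComparisonResult]:
    """All unordered subset-pair comparisons for each rhythm parameter.

    ``family`` sets the Bonferroni denominator: ``per-parameter`` corrects
    across the pairs within one parameter (10 for five groups);
    ``global`` additionally multiplies by the number of parameters.
    """
    if family not in ("per-parameter", "global"):
        raise ValidationError(f"unknown Bonferroni family {family!r}")
    groups_present = [
        k for k in SUBSET_ORDER if k.value in set(metrics["subset_kind"])
    ]
    if len(groups_present) < 2:
        raise InsufficientDataError("need at least two subset groups to compare")
    n_pairs = len(groups_present) * (len(groups_present) - 1) // 2
    family_size = n_pairs * (len(parameters) if family == "global" else 1)
    out: list[ComparisonResult] = []
    for param in parameters:
        samples = {
            k: metrics.loc[metrics["subset_kind"] == k.value, param].to_numpy()
            for k in groups_present
        }
        out.extend(welch_pairwise(samples, param, family_size))
    return out


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "group_a": r.group_a.value,
                "group_b": r.group_b.value,
                "t_stat": r.t_stat,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "cohens_d": r.cohens_d,
                "n_a": r.n_a,
                "n_b": r.n_b,
            }
            for r in results
        ],
        columns=["parameter", "group_a", "group_b", "t_stat", "p_raw", "p_adj",
                 "cohens_d", "n_a", "n_b"],
    )


def nest_beat_correlation(
    metrics: pd.DataFrame,
    subset_for_tutees: SubsetKind = SubsetKind.EVERYTHING,
    parameter: str = "ioi_beat_hz",
) -> NestCorrelation:
    """Pearson correlation between per-nest tutor mean and tutee mean.

    One point per nest: the tutor's mean over its TUTOR units against the
    mean over all that nest's tutee units of the requested subset.
    """
    tutor = metrics[metrics["subset_kind"] == SubsetKind.TUTOR.value]
    tutee = metrics[metrics["subset_kind"] == subset_for_tutees.value]
    nests = sorted(set(tutor["nest_id"]) & set(tutee["nest_id"]))
    if len(nests) < 3:
        raise InsufficientDataError(
            f"need >= 3 nests with both roles, got {len(nests)}"
        )
    tutor_means = [float(tutor.loc[tutor["nest_id"] == n, parameter].mean()) for n in nests]
    tutee_means = [float(tutee.loc[tutee["nest_id"] == n, parameter].mean()) for n in nests]
    r, p = stats.pearsonr(tutor_means, tutee_means)
    return NestCorrelation(
        parameter=parameter, nest_ids=tuple(nests),
        tutor_means=tuple(tutor_means), tutee_means=tuple(tutee_means),
        r=float(r), p=float(p),
    )


def length_correlations(
    metrics: pd.DataFrame, parameters: Sequence[str] = METRIC_COLUMNS
) -> pd.DataFrame:
    """Pearson r (and p) of each rhythm parameter against the number of
    elements in the analysis unit."""
    if len(metrics) < 3:
        raise InsufficientDataError("need >= 3 units for a length correlation")
    n_elements = metrics["n_elements"].to_numpy(float)
    if np.allclose(n_elements, n_elements[0]):
        raise InsufficientDataError(
            "n_elements is constant; correlation undefined"
        )
    rows = []
    for param in parameters:
        r, p = stats.pearsonr(n_elements, metrics[param].to_numpy(float))
        rows.append({"parameter": param, "r": float(r), "p": float(p),
                     "n_units": len(metrics)})
    return pd.DataFrame(rows, columns=["parameter", "r", "p", "n_units"])


def aggregate_per_bird(metrics: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity-analysis view: mean parameter values per bird x subset."""
    grouped = (
        metrics.groupby(["nest_id", "bird_id", "role", "subset_kind"], sort=True)
        .agg({c: "mean" for c in METRIC_COLUMNS + ["mean_ioi_s", "n_elements", "n_iois"]})
        .reset_index()
    )
    return grouped


def simulate_null_fwer(
    n_groups: int = 5,
    n_per_group: int = 20,
    n_replicates: int = 5000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Family-wise error rate of the Bonferroni-corrected Welch family when
    every group is drawn from the same normal distribution."""
    rng = rng or np.random.default_rng(0)
    kinds = SUBSET_ORDER[:n_groups]
    n_pairs = n_groups * (n_groups - 1) // 2
    n_false = 0
    for _ in range(n_replicates):
        samples = {k: rng.standard_normal(n_per_group) for k in kinds}
        results = welch_pairwise(samples, "ioi_beat_hz", family_size=n_pairs)
        if any(r.p_adj < alpha for r in results):
            n_false += 1
    return n_false / n_replicates
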