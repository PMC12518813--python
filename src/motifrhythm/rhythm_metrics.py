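"""Rhythm parameters of inter-onset-interval sequences.

For a sequence of m intervals d_1..d_m (seconds):

* **IOI beat** [Hz] — ``1 / mean(d)``: the rate of the best-fitting
  metronome under the mean-interval model.
* **CV_adj** — coefficient of variation ``sd(d)/mean(d)`` (sample sd,
  denominator m-1) with the standard small-sample unbiasing factor
  ``(1 + 1/(4m))``.  A global, scale-invariant variability measure.
* **nPVI** — normalized pairwise variability index,
  ``100/(m-1) * sum_k |d_k - d_{k+1}| / ((d_k + d_{k+1})/2)``:
  a local measure over adjacent interval pairs, 0 for a perfectly
  isochronous sequence, approaching 200 for maximally alternating ones.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .records import IOISequence, RhythmMetrics, SubsetKind

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["ioi_beat_hz", "cv_adj", "npvi"]


def _as_array(iois: Sequence[float] | np.ndarray, min_m: int, what: str) -> np.ndarray:
    d = np.asarray(iois, dtype=float)
    if d.ndim != 1:
        raise ValidationError(f"{what}: expected a 1-D interval sequence")
    if d.size < min_m:
        raise InsufficientDataError(
            f"{what}: needs at least {min_m} interval(s), got {d.size}"
        )
    if np.any(d <= 0):
        raise ValidationError(f"{what}: all intervals must be positive")
    return d


def compute_ioi_beat(iois: Sequence[float] | np.ndarray) -> float:
    """IOI beat in Hz: 1 divided by the mean interval duration."""
    d = _as_array(iois, 1, "ioi_beat")
    return float(1.0 / d.mean())


def small_sample_cv_correction(m: int) -> float:
    """Unbiasing factor (1 + 1/(4m)) applied to the sample CV."""
    return 1.0 + 1.0 / (4.0 * m)


def compute_cv_adj(iois: Sequence[float] | np.ndarray, adjust: bool = True) -> float:
    """Coefficient of variation of the intervals, small-sample adjusted.

    ``adjust=False`` returns the raw sample CV (sd with denominator m-1
    over the mean).
    """
    d = _as_array(iois, 2, "cv")
    if np.all(d == d[0]):
        return 0.0  # exact zero for isochronous input, no float residue
    cv = float(d.std(ddof=1) / d.mean())
    return cv * small_sample_cv_correction(d.size) if adjust else cv


def compute_npvi(iois: Sequence[float] | np.ndarray) -> float:
    """Normalized pairwise variability index; 0 iff the sequence is
    perfectly isochronous, always in [0, 200)."""
    d = _as_array(iois, 2, "npvi")
    a, b = d[:-1], d[1:]
    return float(100.0 / (d.size - 1) * np.sum(np.abs(a - b) / ((a + b) / 2.0)))


def compute_metrics(iois: Sequence[float] | np.ndarray) -> RhythmMetrics:
    """All three rhythm parameters for one interval sequence."""
    d = _as_array(iois, 2, "metrics")
    return RhythmMetrics(
        ioi_beat_hz=compute_ioi_beat(d),
        cv_adj=compute_cv_adj(d),
        npvi=compute_npvi(d),
        mean_ioi_s=float(d.mean()),
        n_iois=int(d.size),
        n_elements=int(d.size) + 1,
    )


def summarize_units(units: Iterable[IOISequence]) -> pd.DataFrame:
    """One row of provenance + rhythm parameters per analysis unit.

    Units with fewer than 2 intervals are skipped with a log entry (never
    silently dropped).  Rows are sorted deterministically by provenance.
    """
    rows = []
    for u in units:
        try:
            m = compute_metrics(u.iois)
        except InsufficientDataError as exc:
            logger.warning("skipping unit %s/%s/%s [%s]: %s",
                           u.nest_id, u.bird_id, u.motif_id, u.subset_kind, exc)
            continue
        rows.append(
            {
                "nest_id": u.nest_id,
                "bird_id": u.bird_id,
                "role": u.role,
                "motif_id": u.motif_id,
                "subset_kind": u.subset_kind.value,
                "start_index": u.start_index,
                "end_index": u.end_index,
                "n_elements": m.n_elements,
                "n_iois": m.n_iois,
                "mean_ioi_s": m.mean_ioi_s,
                "ioi_beat_hz": m.ioi_beat_hz,
                "cv_adj": m.cv_adj,
                "npvi": m.npvi,
            }
        )
    cols = [
        "nest_id", "bird_id", "role", "motif_id", "subset_kind",
        "start_index", "end_index", "n_elements", "n_iois",
        "mean_ioi_s", "ioi_beat_hz", "cv_adj", "npvi",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(
        ["nest_id", "bird_id", "motif_id", "subset_kind", "start_index"],
        kind="mergesort",
    ).reset_index(drop=True)


def ioi_histogram(
    units: Iterable[IOISequence],
    by: str = "overall",
    bin_width_s: float = 0.01,
    range_s: tuple[float, float] = (0.0, 0.3),
) -> pd.DataFrame:
    """Binned IOI percentages.

    ``by="overall"``: one panel, percentages normalised *per role* (each
    role's bars sum to 100).  ``by="nest"``: one panel per nest, tutor and
    tutee percentages *jointly* summing to 100 within the nest.
    Returns columns panel, role, bin_left_s, bin_right_s, percent.
    """
    if bin_width_s <= 0:
        raise ValidationError("bin width must be positive")
    if by not in ("overall", "nest"):
        raise ValidationError(f"unknown grouping {by!r}")
    units = list(units)
    records = []
    for u in units:
        panel = "overall" if by == "overall" else u.nest_id
        for d in u.iois:
            records.append((panel, u.role, float(d)))
    if not records:
        raise InsufficientDataError("no intervals to histogram")
    df = pd.DataFrame(records, columns=["panel", "role", "ioi_s"])
    lo, hi = range_s
    hi = max(hi, float(df["ioi_s"].max()) + bin_width_s)  # never drop tail IOIs
    edges = np.arange(lo, hi + bin_width_s, bin_width_s)
    out_rows = []
    for panel, pgrp in df.groupby("panel", sort=True):
        for role, rgrp in pgrp.groupby("role", sort=True):
            counts, _ = np.histogram(rgrp["ioi_s"].to_numpy(), bins=edges)
            denom = len(rgrp) if by == "overall" else len(pgrp)
            pct = 100.0 * counts / denom
            for k in np.nonzero(counts)[0]:
                out_rows.append(
                    {
                        "panel": panel,
                        "role": role,
                        "bin_left_s": float(edges[k]),
                        "bin_right_s": float(edges[k + 1]),
                        "percent": float(pct[k]),
                    }
                )
    return pd.DataFrame(
        out_rows, columns=["panel", "role", "bin_left_s", "bin_right_s", "percent"]
    )
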