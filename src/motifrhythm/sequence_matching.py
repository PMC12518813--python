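"""Classify tutee element sequences against their tutor's motif.

A tutee element is *shared* when its label occurs anywhere in the tutor's
motif (annotators assign tutor letters to copied elements and fresh letters
to new ones), so sharing is decided purely on labels.  Three subset
extractions follow:

* the whole tutee motif (``EVERYTHING``),
* at most one beginning-anchored run of elements that follows the tutor's
  sequence in order — ``ALL_SHARED`` when the tutor's complete sequence was
  copied, ``PART_SHARED`` when only an incomplete beginning portion was,
* every maximal run of ``NOT_SHARED`` elements long enough to analyse.

A run enters the analysis only if it carries at least ``min_intervals``
inter-onset intervals (default 3, i.e. four elements).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import ValidationError
from .records import AnnotatedMotif, IOISequence, SubsetKind, SubsetRun

logger = logging.getLogger(__name__)

#: minimum number of IOIs per analysis unit (3 intervals = 4 elements)
DEFAULT_MIN_INTERVALS = 3

MatchMode = Literal["subsequence", "substring"]


@dataclass(frozen=True)
class MatchConfig:
    """Tunable knobs of the subsetting scheme.

    ``min_intervals``: smallest number of IOIs an analysis unit may carry.
    ``match_mode``: how a tutee run "follows the tutor's sequence" —
    ``subsequence`` (default) lets the tutee skip tutor elements while
    preserving order; ``substring`` demands a contiguous tutor excerpt.
    """

    min_intervals: int = DEFAULT_MIN_INTERVALS
    match_mode: MatchMode = "subsequence"

    def __post_init__(self) -> None:
        if self.min_intervals < 1:
            raise ValidationError("min_intervals must be >= 1")
        if self.match_mode not in ("subsequence", "substring"):
            raise ValidationError(f"unknown match_mode {self.match_mode!r}")

    @property
    def min_elements(self) -> int:
        return self.min_intervals + 1


def mark_shared(tutee_motif: AnnotatedMotif, tutor_labels: Sequence[str]) -> list[bool]:
    """Per-element mask: True where the tutee label occurs in the tutor motif."""
    if len(tutor_labels) == 0:
        raise ValidationError("tutor label sequence must be non-empty")
    tutor_set = set(tutor_labels)
    return [lab in tutor_set for lab in tutee_motif.labels]


def _match_anchored_subsequence(tutee: list[str], tutor: list[str]) -> tuple[int, list[int]]:
    """Greedy in-order match anchored at tutee element 0.

    Each tutee element consumes the leftmost feasible tutor position at or
    after the previous one (monotone, no backtracking).  Returns the length
    of the matched tutee prefix and the matched tutor indices.
    """
    matched: list[int] = []
    pos = 0
    for lab in tutee:
        try:
            nxt = tutor.index(lab, pos)
        except ValueError:
            break
        matched.append(nxt)
        pos = nxt + 1
    return len(matched), matched


def _match_anchored_substring(tutee: list[str], tutor: list[str]) -> tuple[int, list[int]]:
    """Longest tutee prefix that is a contiguous excerpt of the tutor
    sequence; leftmost tutor start wins ties."""
    best_len, best_start = 0, 0
    for start in range(len(tutor)):
        k = 0
        while (
            k < len(tutee)
            and start + k < len(tutor)
            and tutee[k] == tutor[start + k]
        ):
            k += 1
        if k > best_len:
            best_len, best_start = k, start
    return best_len, list(range(best_start, best_start + best_len))


def extract_shared_run(
    tutee_motif: AnnotatedMotif,
    tutor_labels: Sequence[str],
    config: MatchConfig = MatchConfig(),
) -> SubsetRun | None:
    """The at-most-one ALL_SHARED / PART_SHARED run of a tutee motif.

    The run starts at the tutee motif's first element and extends for as
    long as the labels follow the tutor's sequence in order (see
    ``MatchConfig.match_mode``).  ALL_SHARED means every tutor element was
    matched; the run stops at the last tutor-matched tutee element, so
    elements the tutee appended afterwards are excluded.  Returns ``None``
    when the run is shorter than the minimum-length condition.
    """
    tutor = list(tutor_labels)
    tutee = tutee_motif.labels
    if config.match_mode == "subsequence":
        run_len, matched = _match_anchored_subsequence(tutee, tutor)
    else:
        run_len, matched = _match_anchored_substring(tutee, tutor)
    _warn_unanchored_runs(tutee_motif, tutor, run_len, config)
    if run_len < config.min_elements:
        return None
    kind = (
        SubsetKind.ALL_SHARED
        if matched == list(range(len(tutor)))
        else SubsetKind.PART_SHARED
    )
    return SubsetRun(source=tutee_motif, kind=kind, start_index=0, end_index=run_len - 1)


def _warn_unanchored_runs(
    tutee_motif: AnnotatedMotif, tutor: list[str], anchored_len: int, config: MatchConfig
) -> None:
    # in-order shared runs that do not start at element 0 are not classified
    # as ALL/PART; surface them so the choice is visible in logs
    tutee = tutee_motif.labels
    for start in range(max(1, anchored_len), len(tutee)):
        run_len, _ = _match_anchored_subsequence(tutee[start:], tutor)
        if run_len >= config.min_elements:
            logger.warning(
                "motif %s: in-order shared run of %d elements at index %d ignored "
                "(shared runs must start at the motif beginning)",
                tutee_motif.key, run_len, start,
            )
            break


def extract_not_shared_runs(
    tutee_motif: AnnotatedMotif,
    tutor_labels: Sequence[str],
    config: MatchConfig = MatchConfig(),
) -> list[SubsetRun]:
    """All maximal runs of consecutive non-shared elements that satisfy the
    minimum-length condition; zero or more per motif, pairwise disjoint."""
    mask = mark_shared(tutee_motif, tutor_labels)
    runs: list[SubsetRun] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        if j - i >= config.min_elements:
            runs.append(
                SubsetRun(
                    source=tutee_motif, kind=SubsetKind.NOT_SHARED,
                    start_index=i, end_index=j - 1,
                )
            )
        i = j
    return runs


def tutor_reference_labels(tutor_motifs: Sequence[AnnotatedMotif]) -> list[str]:
    """The tutor's canonical label sequence: the most frequent sequence
    across its motifs (song is crystallised, so normally they all agree);
    first-observed wins ties."""
    if len(tutor_motifs) == 0:
        raise ValidationError("tutor has no motifs")
    counts: dict[tuple[str, ...], int] = {}
    order: list[tuple[str, ...]] = []
    for m in tutor_motifs:
        key = tuple(m.labels)
        if key not in counts:
            order.append(key)
        counts[key] = counts.get(key, 0) + 1
    best = max(order, key=lambda k: counts[k])
    return list(best)


def build_analysis_units(
    tutor_motifs: Sequence[AnnotatedMotif],
    tutee_motifs: Sequence[AnnotatedMotif],
    config: MatchConfig = MatchConfig(),
) -> list[IOISequence]:
    """All analysis units of one nest.

    Per tutor motif one TUTOR unit (whole motif); per tutee motif one
    EVERYTHING unit (whole motif), at most one ALL_SHARED or PART_SHARED
    unit, and zero or more NOT_SHARED units.  Units shorter than the
    minimum-length condition are dropped (counted in the log).  IOIs never
    cross a run boundary.
    """
    if len(tutor_motifs) == 0:
        raise ValidationError("nest has no tutor motifs")
    for m in tutor_motifs:
        if m.role != "tutor":
            raise ValidationError(f"motif {m.key} passed as tutor but has role {m.role}")
    for m in tutee_motifs:
        if m.role != "tutee":
            raise ValidationError(f"motif {m.key} passed as tutee but has role {m.role}")
    tutor_labels = tutor_reference_labels(tutor_motifs)
    units: list[IOISequence] = []
    n_short = 0
    for m in tutor_motifs:
        if m.n_elements >= config.min_elements:
            units.append(
                SubsetRun(
                    source=m, kind=SubsetKind.TUTOR,
                    start_index=0, end_index=m.n_elements - 1,
                ).to_ioi_sequence()
            )
        else:
            n_short += 1
    for m in tutee_motifs:
        if m.n_elements >= config.min_elements:
            units.append(
                SubsetRun(
                    source=m, kind=SubsetKind.EVERYTHING,
                    start_index=0, end_index=m.n_elements - 1,
                ).to_ioi_sequence()
            )
        else:
            n_short += 1
        shared = extract_shared_run(m, tutor_labels, config)
        if shared is not None:
            units.append(shared.to_ioi_sequence())
        for run in extract_not_shared_runs(m, tutor_labels, config):
            units.append(run.to_ioi_sequence())
    if n_short:
        logger.info(
            "nest %s: %d motif(s) below the minimum-length condition "
            "(%d intervals) contributed no whole-motif unit",
            tutor_motifs[0].nest_id, n_short, config.min_intervals,
        )
    return units
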