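"""Core record types shared by every pipeline stage.

The analysis operates on annotated song motifs: for each motif of each bird
we know the ordered element labels and their onset times in seconds.  All
downstream quantities (inter-onset intervals, rhythm metrics, subset runs)
are derived from these records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError


class SubsetKind(enum.Enum):
    """Analysis subsets.

    ``TUTOR`` units are whole tutor motifs.  Tutee material is analysed as
    the whole motif (``EVERYTHING``), the beginning-anchored run of elements
    copied from the tutor (``ALL_SHARED`` when the tutor's complete sequence
    was copied, ``PART_SHARED`` when only an incomplete beginning snippet
    follows the tutor's order), and maximal runs of elements whose labels do
    not occur in the tutor's motif (``NOT_SHARED``).
    """

    TUTOR = "tutor"
    EVERYTHING = "everything"
    ALL_SHARED = "all_shared"
    PART_SHARED = "part_shared"
    NOT_SHARED = "not_shared"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical ordering used for group comparisons and output sorting
SUBSET_ORDER = [
    SubsetKind.TUTOR,
    SubsetKind.EVERYTHING,
    SubsetKind.ALL_SHARED,
    SubsetKind.PART_SHARED,
    SubsetKind.NOT_SHARED,
]

ROLES = ("tutor", "tutee")


@dataclass(frozen=True)
class Element:
    """One annotated sound element: a label and its onset (seconds)."""

    label: str
    onset_s: float
    offset_s: Optional[float] = None


@dataclass
class AnnotatedMotif:
    """One motif of one bird: ordered element labels with onset times.

    Invariants (checked by :meth:`validate`): onsets strictly increasing,
    labels non-empty after stripping whitespace, at least one element.
    """

    nest_id: str
    bird_id: str
    role: str
    motif_id: str
    elements: list[Element] = field(default_factory=list)

    def validate(self) -> "AnnotatedMotif":
        if self.role not in ROLES:
            raise ValidationError(
                f"motif {self.key}: role must be one of {ROLES}, got {self.role!r}"
            )
        if len(self.elements) < 1:
            raise ValidationError(f"motif {self.key}: needs at least one element")
        for el in self.elements:
            if not el.label.strip():
                raise ValidationError(f"motif {self.key}: empty element label")
            if el.onset_s < 0:
                raise ValidationError(
                    f"motif {self.key}: negative onset {el.onset_s}"
                )
        onsets = self.onsets
        if np.any(np.diff(onsets) <= 0):
            raise ValidationError(
                f"motif {self.key}: onsets not strictly increasing: {list(onsets)}"
            )
        return self

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.nest_id, self.bird_id, self.motif_id)

    @property
    def labels(self) -> list[str]:
        return [el.label for el in self.elements]

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray([el.onset_s for el in self.elements], dtype=float)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def iois(self) -> np.ndarray:
        """Inter-onset intervals: duration from each element onset to the
        next, ``n_elements - 1`` values."""
        return np.diff(self.onsets)


@dataclass(frozen=True)
class SubsetRun:
    """A contiguous index range of one motif assigned to a subset kind."""

    source: AnnotatedMotif
    kind: SubsetKind
    start_index: int
    end_index: int  # inclusive

    def __post_init__(self) -> None:
        n = self.source.n_elements
        if not (0 <= self.start_index <= self.end_index < n):
            raise ValidationError(
                f"run indices [{self.start_index}, {self.end_index}] out of "
                f"bounds for motif of {n} elements"
            )
        if self.kind is SubsetKind.TUTOR and self.source.role != "tutor":
            raise ValidationError("TUTOR runs may only attach to tutor motifs")
        if self.kind is not SubsetKind.TUTOR and self.source.role != "tutee":
            raise ValidationError(f"{self.kind} runs may only attach to tutee motifs")

    @property
    def labels(self) -> list[str]:
        return self.source.labels[self.start_index : self.end_index + 1]

    @property
    def n_elements(self) -> int:
        return self.end_index - self.start_index + 1

    def iois(self) -> np.ndarray:
        """The n-1 intervals between the run's n consecutive onsets; no
        interval crosses a run boundary."""
        onsets = self.source.onsets[self.start_index : self.end_index + 1]
        return np.diff(onsets)

    def to_ioi_sequence(self) -> "IOISequence":
        m = self.source
        return IOISequence(
            iois=self.iois(),
            nest_id=m.nest_id,
            bird_id=m.bird_id,
            motif_id=m.motif_id,
            subset_kind=self.kind,
            start_index=self.start_index,
            end_index=self.end_index,
        )


@dataclass
class IOISequence:
    """Ordered inter-onset intervals for one analysis unit, with provenance."""

    iois: np.ndarray
    nest_id: str
    bird_id: str
    motif_id: str
    subset_kind: SubsetKind
    start_index: int = 0
    end_index: int = -1

    def __post_init__(self) -> None:
        self.iois = np.asarray(self.iois, dtype=float)
        if self.iois.size < 1:
            raise InsufficientDataError(
                f"unit {self.nest_id}/{self.bird_id}/{self.motif_id}: "
                "needs at least one interval"
            )
        if np.any(self.iois <= 0):
            raise ValidationError(
                f"unit {self.nest_id}/{self.bird_id}/{self.motif_id}: "
                "all intervals must be positive"
            )

    @property
    def n_iois(self) -> int:
        return int(self.iois.size)

    @property
    def n_elements(self) -> int:
        return self.n_iois + 1

    @property
    def role(self) -> str:
        return "tutor" if self.subset_kind is SubsetKind.TUTOR else "tutee"


@dataclass(frozen=True)
class RhythmMetrics:
    """The rhythm-parameter triple for one IOI sequence."""

    ioi_beat_hz: float
    cv_adj: float
    npvi: float
    mean_ioi_s: float
    n_iois: int
    n_elements: int


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise Welch comparison of a rhythm parameter between subsets."""

    parameter: str
    group_a: SubsetKind
    group_b: SubsetKind
    t_stat: float
    p_raw: float
    p_adj: float
    cohens_d: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class NestCorrelation:
    """Per-nest tutor-mean vs tutee-mean correlation of one parameter."""

    parameter: str
    nest_ids: tuple[str, ...]
    tutor_means: tuple[float, ...]
    tutee_means: tuple[float, ...]
    r: float
    p: float


def group_motifs_by_nest(
    motifs: Sequence[AnnotatedMotif],
) -> dict[str, dict[str, list[AnnotatedMotif]]]:
    """Group motifs as nest_id -> {"tutor": [...], "tutee": [...]}"""
    nests: dict[str, dict[str, list[AnnotatedMotif]]] = {}
    for m in motifs:
        nests.setdefault(m.nest_id, {"tutor": [], "tutee": []})[m.role].append(m)
    return nests
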