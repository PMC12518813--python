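import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifrhythm.errors import ValidationError
from motifrhythm.records import SubsetKind
from motifrhythm.sequence_matching import (
    MatchConfig,
    build_analysis_units,
    extract_not_shared_runs,
    extract_shared_run,
    mark_shared,
    tutor_reference_labels,
)

from conftest import motif_from_labels

# Methods-style reading: units need 3 elements (2 intervals)
MIN3EL = MatchConfig(min_intervals=2)


@pytest.mark.parametrize(
    "tutor, tutee, expected",
    [
        ("ABCDE", "ABCXY", [True, True, True, False, False]),
        ("ABCDE", "XYZ", [False, False, False]),
        ("ABCDE", "ABCDE", [True] * 5),
    ],
)
def test_mark_shared_is_label_membership(tutor, tutee, expected):
    motif = motif_from_labels(tutee, role="tutee", bird_id="N01B1")
    assert mark_shared(motif, list(tutor)) == expected


def test_mark_shared_requires_tutor_labels():
    motif = motif_from_labels("AB", role="tutee", bird_id="N01B1")
    with pytest.raises(ValidationError):
        mark_shared(motif, [])


@pytest.mark.parametrize(
    "tutor, tutee, kind, end",
    [
        # complete in-order copy with an appended novel element
        ("ABCDE", "ABCDEF", SubsetKind.ALL_SHARED, 4),
        # incomplete beginning snippet
        ("ABCDE", "ABCXY", SubsetKind.PART_SHARED, 2),
        # in-order copy that skips a tutor element is not a complete copy
        ("ABCDE", "ABDEX", SubsetKind.PART_SHARED, 3),
    ],
)
def test_shared_run_classification(tutor, tutee, kind, end):
    motif = motif_from_labels(tutee, role="tutee", bird_id="N01B1")
    run = extract_shared_run(motif, list(tutor), MIN3EL)
    assert run is not None
    assert run.kind is kind
    assert (run.start_index, run.end_index) == (0, end)


def test_shared_run_stops_at_last_tutor_matched_element():
    # appended elements are by definition not part of the shared run
    motif = motif_from_labels("ABCDEF", role="tutee", bird_id="N01B1")
    run = extract_shared_run(motif, list("ABCDE"), MIN3EL)
    assert run.labels == list("ABCDE")


def test_unanchored_shared_run_not_classified():
    """A shared run that does not start at the tutee motif's first element
    yields no ALL/PART unit, and a too-short leading novel run yields no
    NOT_SHARED unit either: the motif contributes only to EVERYTHING."""
    motif = motif_from_labels("XABCD", role="tutee", bird_id="N01B1")
    cfg = MatchConfig(min_intervals=3)  # 4-element minimum
    assert extract_shared_run(motif, list("ABCDE"), cfg) is None
    assert extract_not_shared_runs(motif, list("ABCDE"), cfg) == []


def test_too_short_shared_run_dropped():
    motif = motif_from_labels("ABXYZW", role="tutee", bird_id="N01B1")
    assert extract_shared_run(motif, list("ABCDE"), MIN3EL) is None


def test_substring_mode_requires_contiguous_tutor_excerpt():
    motif = motif_from_labels("ABDE", role="tutee", bird_id="N01B1")
    sub = MatchConfig(min_intervals=2, match_mode="substring")
    assert extract_shared_run(motif, list("ABCDE"), sub) is None  # AB too short
    motif2 = motif_from_labels("BCDX", role="tutee", bird_id="N01B1")
    run = extract_shared_run(motif2, list("ABCDE"), sub)
    assert run is not None and run.labels == list("BCD")
    assert run.kind is SubsetKind.PART_SHARED


def test_not_shared_runs_maximal_and_disjoint():
    motif = motif_from_labels("ABCXYZWABCQRS", role="tutee", bird_id="N01B1")
    runs = extract_not_shared_runs(motif, list("ABC"), MIN3EL)
    assert [(r.start_index, r.end_index) for r in runs] == [(3, 6), (10, 12)]
    assert [r.labels for r in runs] == [list("XYZW"), list("QRS")]


def test_not_shared_short_runs_dropped():
    motif = motif_from_labels("AXXA", role="tutee", bird_id="N01B1")
    assert extract_not_shared_runs(motif, ["A"], MIN3EL) == []


def test_fully_shared_tutee_has_no_not_shared_runs():
    motif = motif_from_labels("ABCDE", role="tutee", bird_id="N01B1")
    assert extract_not_shared_runs(motif, list("ABCDE"), MIN3EL) == []


def test_build_units_full_copier(tutor_motif):
    """A fully shared 6-element tutee motif yields one EVERYTHING unit
    (5 IOIs) and one ALL_SHARED unit, no NOT_SHARED."""
    tutee = motif_from_labels("ABCDEF", role="tutee", bird_id="N01B1")
    units = build_analysis_units(
        [tutor_motif], [tutee], MatchConfig(min_intervals=3)
    )
    kinds = sorted(u.subset_kind.value for u in units)
    assert kinds == ["all_shared", "everything", "tutor"]
    everything = next(u for u in units if u.subset_kind is SubsetKind.EVERYTHING)
    assert everything.n_iois == 5


def test_build_units_fig1_partial_copier_topology(tutor_motif):
    """Shared beginning + improvised continuation, both long enough: the
    motif contributes EVERYTHING, one PART_SHARED and one NOT_SHARED unit
    with disjoint index ranges and no interval crossing a boundary."""
    from conftest import make_motif

    onsets = [0.0, 0.05, 0.11, 0.18, 0.30, 0.36, 0.43, 0.51, 0.60]
    tutee = make_motif(list("ABCDWXYZQ"), onsets, role="tutee", bird_id="N01B2")
    units = build_analysis_units([tutor_motif], [tutee], MatchConfig())
    by_kind = {u.subset_kind: u for u in units if u.bird_id == "N01B2"}
    assert set(by_kind) == {SubsetKind.EVERYTHING, SubsetKind.PART_SHARED,
                            SubsetKind.NOT_SHARED}
    part = by_kind[SubsetKind.PART_SHARED]
    novel = by_kind[SubsetKind.NOT_SHARED]
    assert (part.start_index, part.end_index) == (0, 3)
    assert (novel.start_index, novel.end_index) == (4, 8)
    # IOIs never cross the run boundary at onset 0.30
    assert part.iois == pytest.approx(np.diff(onsets[:4]))
    assert novel.iois == pytest.approx(np.diff(onsets[4:]))
    # conservation: IOIs of each run sum to its onset span
    assert part.iois.sum() == pytest.approx(onsets[3] - onsets[0], abs=1e-9)
    assert novel.iois.sum() == pytest.approx(onsets[8] - onsets[4], abs=1e-9)


def test_build_units_tutor_whole_motif(tutor_motif):
    units = build_analysis_units([tutor_motif], [], MatchConfig())
    (unit,) = units
    assert unit.subset_kind is SubsetKind.TUTOR
    assert unit.n_iois == tutor_motif.n_elements - 1


def test_build_units_requires_tutor():
    with pytest.raises(ValidationError):
        build_analysis_units([], [], MatchConfig())


def test_tutor_reference_labels_majority():
    a = motif_from_labels("ABCDE", role="tutor", motif_id="m00")
    b = motif_from_labels("ABCDE", role="tutor", motif_id="m01")
    c = motif_from_labels("ABCD", role="tutor", motif_id="m02")
    assert tutor_reference_labels([c, a, b]) == list("ABCDE")


LABELS = st.text(alphabet="ABCDEFXYZW", min_size=1, max_size=12)


@given(tutor=LABELS, tutee=LABELS)
@settings(max_examples=200, deadline=None)
def test_partition_and_disjointness_properties(tutor, tutee):
    """Every tutee element is shared xor not-shared; ALL/PART and
    NOT_SHARED runs never overlap; NOT_SHARED runs are maximal."""
    motif = motif_from_labels(tutee, role="tutee", bird_id="N01B1")
    cfg = MatchConfig(min_intervals=2)
    mask = mark_shared(motif, list(tutor))
    assert len(mask) == motif.n_elements

    covered = set()
    shared_run = extract_shared_run(motif, list(tutor), cfg)
    if shared_run is not None:
        covered.update(range(shared_run.start_index, shared_run.end_index + 1))
    for run in extract_not_shared_runs(motif, list(tutor), cfg):
        idx = set(range(run.start_index, run.end_index + 1))
        assert not idx & covered
        covered.update(idx)
        # maximality: neighbours are shared or out of bounds
        if run.start_index > 0:
            assert mask[run.start_index - 1]
        if run.end_index < motif.n_elements - 1:
            assert mask[run.end_index + 1]
        assert not any(mask[i] for i in idx)


@given(tutee=st.text(alphabet="ABCDE", min_size=4, max_size=10),
       pos=st.integers(min_value=0, max_value=9))
@settings(max_examples=200, deadline=None)
def test_relabelling_never_lengthens_shared_run(tutee, pos):
    """Turning one shared tutee element into a novel label never increases
    the length of the anchored shared run."""
    tutor = list("ABCDE")
    motif = motif_from_labels(tutee, role="tutee", bird_id="N01B1")
    cfg = MatchConfig(min_intervals=1)
    before = extract_shared_run(motif, tutor, cfg)
    pos = pos % len(tutee)
    mutated = tutee[:pos] + "Q" + tutee[pos + 1:]
    after = extract_shared_run(
        motif_from_labels(mutated, role="tutee", bird_id="N01B1"), tutor, cfg
    )
    len_before = 0 if before is None else before.n_elements
    len_after = 0 if after is None else after.n_elements
    assert len_after <= len_before
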