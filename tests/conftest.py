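import numpy as np
import pytest

from motifrhythm.records import AnnotatedMotif, Element


def make_motif(labels, onsets, nest_id="N01", bird_id="N01T", role="tutor",
               motif_id="m00", offsets=None):
    """Build a validated motif from parallel label/onset sequences."""
    offsets = offsets or [None] * len(labels)
    elements = [
        Element(label=lab, onset_s=float(t), offset_s=off)
        for lab, t, off in zip(labels, onsets, offsets)
    ]
    return AnnotatedMotif(
        nest_id=nest_id, bird_id=bird_id, role=role, motif_id=motif_id,
        elements=elements,
    ).validate()


def motif_from_labels(labels, ioi=0.06, **kwargs):
    """Motif with equally spaced onsets, one per label character."""
    onsets = [i * ioi for i in range(len(labels))]
    return make_motif(list(labels), onsets, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tutor_motif():
    return motif_from_labels("ABCDE", role="tutor", bird_id="N01T")


@pytest.fixture
def small_corpus():
    """One nest: a tutor and two tutees (one full copier, one partial
    copier with an improvised tail), equally spaced onsets."""
    tutor = [motif_from_labels("ABCDE", role="tutor", bird_id="N01T",
                               motif_id=f"m{i:02d}") for i in range(3)]
    full = [motif_from_labels("ABCDEF", role="tutee", bird_id="N01B1",
                              motif_id=f"m{i:02d}") for i in range(3)]
    partial = [motif_from_labels("ABCDXYZW", role="tutee", bird_id="N01B2",
                                 motif_id=f"m{i:02d}") for i in range(3)]
    return tutor, full + partial
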