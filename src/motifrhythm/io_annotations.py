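"""Read and write motif annotations.

Two surfaces are supported: Praat TextGrid interval tiers (the format song
annotations are produced in) and a long-format CSV dialect that serves as
the pipeline's canonical interchange format.  Each non-empty-labelled
interval on the chosen tier is one song element; the element onset is the
start time of its interval, in seconds from file start.

Metadata (nest, bird, role, motif) is not stored inside a TextGrid, so it
is taken from the file name via a configurable regex with named groups, or
passed explicitly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._textgrid import TextGrid, TextGridTier, parse_textgrid, write_textgrid_file
from .errors import TextGridDialectError, TierNotFoundError, ValidationError
from .records import AnnotatedMotif, Element

#: default filename convention, e.g. ``N01_B02_tutee_m03.TextGrid``
DEFAULT_FILENAME_PATTERN = (
    r"(?P<nest_id>[^_]+)_(?P<bird_id>[^_]+)_(?P<role>tutor|tutee)_(?P<motif_id>[^.]+)"
)

#: duration written for the last element when its offset is unknown (s)
DEFAULT_ELEMENT_DURATION_S = 0.04

CSV_COLUMNS = [
    "nest_id",
    "bird_id",
    "role",
    "motif_id",
    "element_index",
    "label",
    "onset_s",
    "offset_s",
]

_OVERLAP_TOL = 1e-9


def metadata_from_filename(
    path: str | Path, pattern: str = DEFAULT_FILENAME_PATTERN
) -> dict[str, str]:
    """Extract nest/bird/role/motif identifiers from a file name."""
    stem = Path(path).name
    m = re.search(pattern, stem)
    if m is None:
        raise ValidationError(
            f"filename {stem!r} does not match metadata pattern {pattern!r}"
        )
    return m.groupdict()


def _motif_from_tier(tier: TextGridTier, meta: dict[str, str], path: Path) -> AnnotatedMotif:
    if not tier.is_interval:
        raise TextGridDialectError(
            f"{path}: tier {tier.name!r} is a point tier; an interval tier is required"
        )
    entries = sorted(tier.entries, key=lambda e: e[0])
    labelled = [(a, b, t.strip()) for a, b, t in entries if t.strip()]
    prev_end = None
    for a, b, _ in labelled:
        if prev_end is not None and a < prev_end - _OVERLAP_TOL:
            raise ValidationError(
                f"{path}: overlapping labelled intervals on tier {tier.name!r}"
            )
        prev_end = b
    elements = [Element(label=t, onset_s=a, offset_s=b) for a, b, t in labelled]
    return AnnotatedMotif(elements=elements, **meta).validate()


def read_textgrid(
    path: str | Path,
    tier_name: str = "elements",
    metadata: Optional[dict[str, str]] = None,
    filename_pattern: str = DEFAULT_FILENAME_PATTERN,
) -> list[AnnotatedMotif]:
    """Read one motif (the named interval tier) from a TextGrid file.

    Returns a one-element list so that callers can treat files and CSVs
    uniformly.
    """
    path = Path(path)
    grid = parse_textgrid(path)
    tier = grid.get_tier(tier_name)
    if tier is None:
        raise TierNotFoundError(
            f"{path}: no tier named {tier_name!r}; available: {grid.tier_names()}"
        )
    meta = dict(metadata) if metadata else metadata_from_filename(path, filename_pattern)
    return [_motif_from_tier(tier, meta, path)]


def read_textgrid_dir(
    directory: str | Path,
    tier_name: str = "elements",
    filename_pattern: str = DEFAULT_FILENAME_PATTERN,
) -> list[AnnotatedMotif]:
    """Read every ``*.TextGrid`` file in a directory (sorted by name)."""
    directory = Path(directory)
    motifs: list[AnnotatedMotif] = []
    for p in sorted(directory.glob("*.TextGrid")):
        motifs.extend(read_textgrid(p, tier_name, filename_pattern=filename_pattern))
    return motifs


def write_textgrid(
    motifs: Sequence[AnnotatedMotif],
    path: str | Path,
    tier_name: str = "elements",
    default_element_duration_s: float = DEFAULT_ELEMENT_DURATION_S,
) -> list[Path]:
    """Write motifs as TextGrid files (long dialect, 6-decimal times).

    ``path`` may be a single ``*.TextGrid`` file (one motif only) or a
    directory, in which case files are named by the default filename
    convention.  Unknown offsets are filled with the next element's onset,
    capped at ``default_element_duration_s``.
    """
    if len(motifs) == 0:
        raise ValidationError("refusing to write an empty motif list")
    path = Path(path)
    single_file = path.suffix.lower() == ".textgrid"
    if single_file and len(motifs) > 1:
        raise ValidationError("multiple motifs need a directory, not a single file")
    if not single_file:
        path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for motif in motifs:
        motif.validate()
        onsets = motif.onsets
        intervals: list[tuple[float, float, str]] = []
        cursor = 0.0
        for i, el in enumerate(motif.elements):
            next_onset = onsets[i + 1] if i + 1 < motif.n_elements else None
            offset = el.offset_s
            if offset is None:
                if next_onset is not None:
                    offset = min(next_onset, el.onset_s + default_element_duration_s)
                else:
                    offset = el.onset_s + default_element_duration_s
            if el.onset_s > cursor + _OVERLAP_TOL:
                intervals.append((cursor, el.onset_s, ""))
            intervals.append((el.onset_s, offset, el.label))
            cursor = offset
        xmax = cursor
        tier = TextGridTier(
            name=tier_name, tier_class="IntervalTier", xmin=0.0, xmax=xmax,
            entries=intervals,
        )
        grid = TextGrid(xmin=0.0, xmax=xmax, tiers=[tier])
        if single_file:
            target = path
        else:
            target = path / (
                f"{motif.nest_id}_{motif.bird_id}_{motif.role}_{motif.motif_id}.TextGrid"
            )
        write_textgrid_file(grid, target)
        written.append(target)
    return written


def read_csv(path: str | Path) -> list[AnnotatedMotif]:
    """Read motifs from long-format CSV (one row per element)."""
    df = pd.read_csv(path, dtype={"nest_id": str, "bird_id": str, "motif_id": str})
    required = set(CSV_COLUMNS) - {"offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing CSV columns {sorted(missing)}")
    has_offset = "offset_s" in df.columns
    motifs: list[AnnotatedMotif] = []
    keys = ["nest_id", "bird_id", "motif_id"]
    for (nest, bird, motif_id), grp in df.groupby(keys, sort=True):
        if grp["element_index"].duplicated().any():
            raise ValidationError(
                f"motif ({nest}, {bird}, {motif_id}): duplicate element_index"
            )
        grp = grp.sort_values("element_index")
        roles = grp["role"].unique()
        if len(roles) != 1:
            raise ValidationError(
                f"motif ({nest}, {bird}, {motif_id}): inconsistent role values"
            )
        elements = []
        for row in grp.itertuples(index=False):
            offset = getattr(row, "offset_s", None) if has_offset else None
            offset = None if offset is None or pd.isna(offset) else float(offset)
            elements.append(
                Element(label=str(row.label), onset_s=float(row.onset_s), offset_s=offset)
            )
        try:
            motifs.append(
                AnnotatedMotif(
                    nest_id=str(nest), bird_id=str(bird), role=str(roles[0]),
                    motif_id=str(motif_id), elements=elements,
                ).validate()
            )
        except ValidationError as exc:
            raise ValidationError(
                f"motif ({nest}, {bird}, {motif_id}): {exc}"
            ) from exc
    return motifs


def write_csv(motifs: Iterable[AnnotatedMotif], path: str | Path) -> Path:
    """Write motifs as long-format CSV, deterministic order, 6-decimal times."""
    motifs = list(motifs)
    if len(motifs) == 0:
        raise ValidationError("refusing to write an empty motif list")
    rows = []
    for m in sorted(motifs, key=lambda m: m.key):
        m.validate()
        for i, el in enumerate(m.elements):
            rows.append(
                {
                    "nest_id": m.nest_id,
                    "bird_id": m.bird_id,
                    "role": m.role,
                    "motif_id": m.motif_id,
                    "element_index": i,
                    "label": el.label,
                    "onset_s": f"{el.onset_s:.6f}",
                    "offset_s": "" if el.offset_s is None else f"{el.offset_s:.6f}",
                }
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    return path
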