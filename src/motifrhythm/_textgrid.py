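"""Minimal Praat TextGrid reader/writer.

Supports both text dialects Praat produces ("long" with ``key = value``
lines and "short" with bare values), interval and point tiers, and UTF-8 /
UTF-16 encodings (BOM-detected).  Only the structure needed for onset
annotation work is modelled: tiers with (xmin, xmax, text) intervals or
(time, mark) points.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import TextGridDialectError


@dataclass
class TextGridTier:
    name: str
    tier_class: str  # "IntervalTier" or "TextTier"
    xmin: float
    xmax: float
    # interval tiers: (xmin, xmax, text); point tiers: (time, time, mark)
    entries: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def is_interval(self) -> bool:
        return self.tier_class == "IntervalTier"


@dataclass
class TextGrid:
    xmin: float
    xmax: float
    tiers: list[TextGridTier] = field(default_factory=list)

    def tier_names(self) -> list[str]:
        return [t.name for t in self.tiers]

    def get_tier(self, name: str) -> TextGridTier | None:
        for t in self.tiers:
            if t.name == name:
                return t
        return None


def _decode(raw: bytes) -> str:
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    try:
        return raw.decode("utf-8-sig")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


_LONG_KV = re.compile(r"^\s*[\w?]+(?:\s*\[\d*\])?\s*(?::\s*\w+\s*)?=\s*(.*)$")
_STRUCTURAL = re.compile(r"^\s*(?:item|intervals|points)\s*\[\d*\]\s*:?\s*$")


def _tokenize(text: str) -> list[str]:
    """Reduce either dialect to the common ordered value stream."""
    lines = text.splitlines()
    if not lines or "ooTextFile" not in lines[0]:
        raise TextGridDialectError("not a Praat text TextGrid (missing header)")
    body = lines[2:]  # skip File type / Object class header
    is_long = any(_LONG_KV.match(ln) for ln in body)
    tokens: list[str] = []
    for ln in body:
        stripped = ln.strip()
        if not stripped:
            continue
        if is_long:
            if _STRUCTURAL.match(stripped):
                continue
            m = _LONG_KV.match(ln)
            if m:
                tokens.append(m.group(1).strip())
            elif "<exists>" in stripped:
                tokens.append("<exists>")
            # anything else (e.g. "intervals: size = n" already matched) skipped
        else:
            tokens.append(stripped)
    return tokens


class _Stream:
    def __init__(self, tokens: list[str]):
        self._toks = tokens
        self._i = 0

    def _next(self) -> str:
        if self._i >= len(self._toks):
            raise TextGridDialectError("truncated TextGrid: ran out of values")
        tok = self._toks[self._i]
        self._i += 1
        return tok

    def number(self) -> float:
        tok = self._next()
        try:
            return float(tok)
        except ValueError as exc:
            raise TextGridDialectError(f"expected a number, got {tok!r}") from exc

    def integer(self) -> int:
        return int(round(self.number()))

    def string(self) -> str:
        tok = self._next()
        if len(tok) >= 2 and tok.startswith('"') and tok.endswith('"'):
            return tok[1:-1].replace('""', '"')
        return tok

    def skip_exists(self) -> None:
        if self._i < len(self._toks) and "<exists>" in self._toks[self._i]:
            self._i += 1


def parse_textgrid(path: str | Path) -> TextGrid:
    tokens = _tokenize(_decode(Path(path).read_bytes()))
    s = _Stream(tokens)
    xmin = s.number()
    xmax = s.number()
    s.skip_exists()
    n_tiers = s.integer()
    grid = TextGrid(xmin=xmin, xmax=xmax)
    for _ in range(n_tiers):
        tier_class = s.string()
        name = s.string()
        t_xmin = s.number()
        t_xmax = s.number()
        n = s.integer()
        tier = TextGridTier(name=name, tier_class=tier_class, xmin=t_xmin, xmax=t_xmax)
        for _ in range(n):
            if tier_class == "IntervalTier":
                a, b, txt = s.number(), s.number(), s.string()
                tier.entries.append((a, b, txt))
            else:  # TextTier (points) or unknown point-like tier
                t, mark = s.number(), s.string()
                tier.entries.append((t, t, mark))
        grid.tiers.append(tier)
    return grid


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _quote(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write_textgrid_file(grid: TextGrid, path: str | Path) -> None:
    """Write the long text dialect with 6-decimal times (bit-stable)."""
    out: list[str] = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {_fmt(grid.xmin)}",
        f"xmax = {_fmt(grid.xmax)}",
        "tiers? <exists>",
        f"size = {len(grid.tiers)}",
        "item []:",
    ]
    for i, tier in enumerate(grid.tiers, start=1):
        out.append(f"    item [{i}]:")
        out.append(f"        class = {_quote(tier.tier_class)}")
        out.append(f"        name = {_quote(tier.name)}")
        out.append(f"        xmin = {_fmt(tier.xmin)}")
        out.append(f"        xmax = {_fmt(tier.xmax)}")
        if tier.is_interval:
            out.append(f"        intervals: size = {len(tier.entries)}")
            for j, (a, b, txt) in enumerate(tier.entries, start=1):
                out.append(f"        intervals [{j}]:")
                out.append(f"            xmin = {_fmt(a)}")
                out.append(f"            xmax = {_fmt(b)}")
                out.append(f"            text = {_quote(txt)}")
        else:
            out.append(f"        points: size = {len(tier.entries)}")
            for j, (t, _, mark) in enumerate(tier.entries, start=1):
                out.append(f"        points [{j}]:")
                out.append(f"            number = {_fmt(t)}")
                out.append(f"            mark = {_quote(mark)}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
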