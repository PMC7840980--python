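"""Comparison of mosaic annotations across subtelomeres and strains.

Mosaic annotations are projected to symbol strings (one symbol per tile,
telomere-left order) and compared at two levels: *class* (segment letter
only) and *variant* (letter plus variant number). The module finds all
maximal shared runs of consecutive symbols between two mosaics, tests
whole-pattern equality, and groups chromosome ends by the first-k
segment signature after the telomere — the two archetypal end
architectures being a telomere followed by segments A,B versus a partial
segment F followed by G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .shp_segmenter import (
    FLAG_PARTIAL,
    FLAG_UNMATCHED,
    MosaicAnnotation,
    Tile,
    UNMATCHED_LABEL,
)

Level = Literal["class", "variant"]


@dataclass(frozen=True)
class MosaicSymbol:
    label: str
    variant: str | None
    flags: frozenset[str]

    def key(self, level: Level) -> tuple:
        if level == "class":
            return (self.label,)
        return (self.label, self.variant)


@dataclass
class MosaicString:
    seq_id: str
    symbols: list[MosaicSymbol]

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class SharedRun:
    """A maximal run of symbols shared by two mosaic strings."""

    a_start: int
    b_start: int
    length: int
    level: Level


@dataclass(frozen=True)
class EndArchitecture:
    seq_id: str
    signature: tuple[str, ...]
    short: bool = False  # fewer than k tiles were available


def to_mosaic_string(annotation: MosaicAnnotation) -> MosaicString:
    """Lossless symbol projection of the tiles, in tile order."""
    return MosaicString(
        seq_id=annotation.seq_id,
        symbols=[
            MosaicSymbol(t.label, t.variant, t.flags)
            for t in annotation.tiles
        ],
    )


def _symbols_equal(a: MosaicSymbol, b: MosaicSymbol, level: Level) -> bool:
    # unmatched tiles never compare equal through symbols alone: their
    # content is unknown to the library, so only identity-compatible
    # sequence comparison (not available here) could match them
    if a.label == UNMATCHED_LABEL or b.label == UNMATCHED_LABEL:
        return False
    return a.key(level) == b.key(level)


def shared_runs(
    a: MosaicString, b: MosaicString, level: Level = "class",
    min_run: int = 1,
) -> list[SharedRun]:
    """All maximal common contiguous symbol runs, found exhaustively.

    Symmetric: swapping the arguments exchanges the index ranges.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    n, m = len(a), len(b)
    # run length ending at (i, j)
    prev = [0] * (m + 1)
    runs: list[SharedRun] = []
    ends: set[tuple[int, int, int]] = set()
    table = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if _symbols_equal(a.symbols[i - 1], b.symbols[j - 1], level):
                table[i][j] = table[i - 1][j - 1] + 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ln = table[i][j]
            if ln < min_run:
                continue
            # maximal: not extendable right/down
            if i < n and j < m and table[i + 1][j + 1] > ln:
                continue
            runs.append(SharedRun(i - ln, j - ln, ln, level))
    runs.sort(key=lambda r: (r.a_start, r.b_start, -r.length))
    return runs


def same_pattern(a: MosaicString, b: MosaicString,
                 level: Level = "class") -> bool:
    """Whole-pattern equality at the requested level (flags ignored at
    class level; unmatched tiles compare equal to unmatched only)."""
    if len(a) != len(b):
        return False
    for x, y in zip(a.symbols, b.symbols):
        if x.label == UNMATCHED_LABEL and y.label == UNMATCHED_LABEL:
            continue
        if not _symbols_equal(x, y, level):
            return False
    return True


def classify_end_architecture(
    annotations: Iterable[MosaicAnnotation], k: int = 2
) -> dict[str, EndArchitecture]:
    """Group chromosome ends by their first-k segment signature.

    Signatures keep the partial flag (a truncated leading segment is a
    distinct architecture, the "Tel-∆F-G" pattern) and are taken from
    the telomere-proximal tiles of annotations oriented telomere-left.
    """
    out: dict[str, EndArchitecture] = {}
    for ann in annotations:
        labels = []
        for t in ann.tiles[:k]:
            lab = t.label
            if FLAG_PARTIAL in t.flags:
                lab = "∆" + lab
            labels.append(lab)
        out[ann.seq_id] = EndArchitecture(
            seq_id=ann.seq_id,
            signature=tuple(labels),
            short=len(ann.tiles) < k,
        )
    return out


def architecture_groups(
    archs: dict[str, EndArchitecture]
) -> dict[tuple[str, ...], list[str]]:
    groups: dict[tuple[str, ...], list[str]] = {}
    for sid in sorted(archs):
        groups.setdefault(archs[sid].signature, []).append(sid)
    return groups


def pairwise_pattern_table(
    strings: list[MosaicString],
) -> "pandas.DataFrame":
    """Square table of same_pattern at both levels ('class'/'variant'/
    'both'/'-') for every pair."""
    import pandas as pd

    ids = [s.seq_id for s in strings]
    data = []
    for a in strings:
        row = []
        for b in strings:
            c = same_pattern(a, b, "class")
            v = same_pattern(a, b, "variant")
            row.append("both" if c and v else "class" if c else "-")
        data.append(row)
    return pd.DataFrame(data, index=ids, columns=ids)
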