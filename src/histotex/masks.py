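"""Enumeration of higher-order local autocorrelation (HLAC) templates.

An HLAC feature of order ``N`` is a sum over image positions ``r`` of the
product ``f(r) f(r + a_1) ... f(r + a_N)``.  A template (mask) is therefore a
*displacement set*: the set ``{(0,0), a_1, ..., a_N}`` of integer pixel
offsets, always containing the origin.  Because the sum runs over all image
positions, two displacement sets that are translates of one another produce
the same feature (up to border effects), so templates are enumerated up to
translation equivalence.

Conventions used here
---------------------
* Candidates are origin-containing subsets of the ``w x w`` window centered
  on the origin (``w`` odd).  Offsets are distinct (set semantics): the
  product in the defining sum ranges over distinct pixels.
* Two candidates ``D`` and ``E`` are equivalent iff ``E = D + t`` for an
  integer translation ``t`` and ``E`` is itself a valid candidate.
* The canonical representative of a class is the lexicographically smallest
  valid translate, offsets sorted row-major.
* Masks are ordered by ascending cardinality (order), then lexicographically
  by their canonical offset tuple.  Feature slot names derive from this
  ordering; it is fixed and will not change between releases.

Under these rules the enumeration yields 25 templates for order <= 2 in a
3 x 3 window and 223 for order <= 8 in a 3 x 3 window.  For order <= 2 in a
5 x 5 window it yields 193; a figure of 205 sometimes quoted for that
configuration corresponds to an enumeration that merges translated 3-point
patterns but keeps all 24 directed single-offset pairs unmerged, which is
not a consistent equivalence (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

Offset = tuple[int, int]
DisplacementSet = tuple[Offset, ...]

ORIGIN: Offset = (0, 0)


def _validate_window(window_size: int) -> int:
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError(f"window_size must be an odd integer >= 3, got {window_size}")
    return window_size // 2


def _fits(offsets: Iterable[Offset], half: int) -> bool:
    return all(abs(r) <= half and abs(c) <= half for r, c in offsets)


def canonicalize(offsets: Iterable[Offset], window_size: int) -> DisplacementSet:
    """Return the canonical representative of a displacement set's class.

    The representative is the lexicographically smallest translate of
    ``offsets`` that still contains the origin and fits within the centered
    ``window_size x window_size`` box.  Two displacement sets map to the same
    output iff one is a translate of the other.

    Raises
    ------
    ValueError
        If the origin is missing or an offset lies outside the window.
    """
    half = _validate_window(window_size)
    dset = tuple(sorted(set((int(r), int(c)) for r, c in offsets)))
    if ORIGIN not in dset:
        raise ValueError("displacement set must contain the origin (0, 0)")
    for off in dset:
        if not _fits([off], half):
            raise ValueError(f"offset {off} outside the {window_size}x{window_size} window")
    best: DisplacementSet | None = None
    for pr, pc in dset:  # translating (pr, pc) onto the origin
        translate = tuple(sorted((r - pr, c - pc) for r, c in dset))
        if _fits(translate, half) and (best is None or translate < best):
            best = translate
    assert best is not None  # identity translate always qualifies
    return best


@dataclass(frozen=True)
class MaskSet:
    """An ordered collection of canonical HLAC displacement sets.

    Attributes
    ----------
    masks : tuple of displacement sets
        Canonical representatives, ordered by (cardinality, lexicographic).
    window_size : int
        Odd side length of the centered window the masks were enumerated in.
    max_order : int
        Highest autocorrelation order included (cardinality - 1).
    scale : int
        Integer factor applied to every offset (1 for the base enumeration;
        > 1 for proportionally extended masks).
    """

    masks: tuple[DisplacementSet, ...]
    window_size: int
    max_order: int
    scale: int = 1

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    @property
    def radius(self) -> int:
        """Side length of the window the (possibly scaled) offsets span."""
        return (self.window_size - 1) * self.scale + 1

    @property
    def margin(self) -> int:
        """Largest offset magnitude; the border width excluded by 'valid' traversal."""
        return max(
            (max(abs(r), abs(c)) for mask in self.masks for r, c in mask),
            default=0,
        )

    def names(self) -> list[str]:
        """Stable feature-slot names, ``m01`` ... ``mNN`` in mask order."""
        width = max(2, len(str(len(self.masks))))
        return [f"m{i + 1:0{width}d}" for i in range(len(self.masks))]

    def to_json(self) -> str:
        """Serialize the mask set (offsets, window, order, scale) to JSON."""
        return json.dumps(
            {
                "window_size": self.window_size,
                "max_order": self.max_order,
                "scale": self.scale,
                "masks": [[list(off) for off in mask] for mask in self.masks],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaskSet":
        obj = json.loads(text)
        masks = tuple(
            tuple((int(r), int(c)) for r, c in mask) for mask in obj["masks"]
        )
        return cls(masks, int(obj["window_size"]), int(obj["max_order"]), int(obj["scale"]))


def enumerate_masks(max_order: int, window_size: int) -> MaskSet:
    """Enumerate all HLAC templates up to ``max_order`` in a centered window.

    Every origin-containing displacement set of cardinality 1 to
    ``max_order + 1`` inside the ``window_size x window_size`` window is
    generated; translation-equivalent sets are merged and the canonical
    representatives returned in deterministic order (ascending cardinality,
    then lexicographic).

    >>> len(enumerate_masks(2, 3))
    25
    """
    half = _validate_window(window_size)
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if max_order + 1 > window_size**2:
        raise ValueError("max_order + 1 cannot exceed the number of window cells")
    cells = [
        (r, c)
        for r in range(-half, half + 1)
        for c in range(-half, half + 1)
        if (r, c) != ORIGIN
    ]
    seen: set[DisplacementSet] = set()
    for k in range(max_order + 1):
        for combo in combinations(cells, k):
            seen.add(canonicalize((ORIGIN,) + combo, window_size))
    ordered = tuple(sorted(seen, key=lambda m: (len(m), m)))
    return MaskSet(ordered, window_size, max_order)


def scale_masks(mask_set: MaskSet, radius: int) -> MaskSet:
    """Proportionally extend a 3 x 3 mask set to a larger odd radius.

    Each offset is multiplied by the integer factor ``(radius - 1) / 2``, so
    the template count is unchanged while the spatial support grows.  Only
    mask sets built on a 3 x 3 window can be extended this way.
    """
    if mask_set.window_size != 3 or mask_set.scale != 1:
        raise ValueError("only unscaled 3x3 mask sets can be extended")
    if radius < 3 or radius % 2 == 0:
        raise ValueError(f"radius must be an odd integer >= 3, got {radius}")
    factor = (radius - 1) // 2
    scaled = tuple(
        tuple((r * factor, c * factor) for r, c in mask) for mask in mask_set.masks
    )
    return MaskSet(scaled, mask_set.window_size, mask_set.max_order, scale=factor)


def default_masks() -> MaskSet:
    """The standard 25-template set: order <= 2, 3 x 3 window."""
    return enumerate_masks(2, 3)
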