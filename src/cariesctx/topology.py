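"""FDI primary-dentition positions and context-neighbor selection.

The primary (deciduous) dentition has 20 teeth, written in FDI two-digit
notation: the first digit is the quadrant (5 = upper right, 6 = upper left,
7 = lower left, 8 = lower right) and the second is the position counted from
the dental midline (1 = central incisor ... 5 = second primary molar).

Context for a tooth is defined anatomically:

* ``k=2`` — the mesial and distal neighbors within the same arch, crossing
  the midline between quadrants (so the mesial neighbor of 51 is 61);
* ``k=3`` — additionally the facing (occluding) tooth, i.e. the same index
  in the opposing arch (51 faces 81, 61 faces 71, 55 faces 85);
* ``k=5`` — additionally the facing tooth's own two within-arch neighbors
  (the "diagonal" teeth).

At the distal end of an arch (index-5 molars) the missing within-arch
neighbor is simply omitted, so the returned list is shorter; there is no
wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FdiPosition",
    "ALL_POSITIONS",
    "arch_order",
    "neighbor_set",
    "context_positions",
    "NeighborRule",
]

_QUADRANTS = (5, 6, 7, 8)
_INDICES = (1, 2, 3, 4, 5)

# Facing quadrant: upper right <-> lower right, upper left <-> lower left.
_FACING_QUADRANT = {5: 8, 6: 7, 7: 6, 8: 5}


@dataclass(frozen=True, order=True)
class FdiPosition:
    """One primary-dentition tooth position in FDI notation."""

    quadrant: int
    index: int

    def __post_init__(self) -> None:
        if self.quadrant not in _QUADRANTS or self.index not in _INDICES:
            raise ValueError(
                f"not a primary-dentition FDI position: {self.quadrant}{self.index}"
            )

    @classmethod
    def parse(cls, code: "str | int | FdiPosition") -> "FdiPosition":
        if isinstance(code, FdiPosition):
            return code
        s = str(code)
        if len(s) != 2 or not s.isdigit():
            raise ValueError(f"not a two-digit FDI code: {code!r}")
        return cls(int(s[0]), int(s[1]))

    @property
    def arch(self) -> str:
        return "upper" if self.quadrant in (5, 6) else "lower"

    def facing(self) -> "FdiPosition":
        """Same-index tooth in the opposing arch."""
        return FdiPosition(_FACING_QUADRANT[self.quadrant], self.index)

    def __str__(self) -> str:
        return f"{self.quadrant}{self.index}"


def _build_arch(right_quadrant: int, left_quadrant: int) -> tuple[FdiPosition, ...]:
    right = [FdiPosition(right_quadrant, i) for i in range(5, 0, -1)]
    left = [FdiPosition(left_quadrant, i) for i in range(1, 6)]
    return tuple(right + left)


_ARCH = {
    "upper": _build_arch(5, 6),
    "lower": _build_arch(8, 7),
}

ALL_POSITIONS: tuple[FdiPosition, ...] = _ARCH["upper"] + _ARCH["lower"]


def arch_order(arch: str) -> list[FdiPosition]:
    """The 10 positions of an arch in anatomical order.

    The order runs across the midline (e.g. upper: 55..51 then 61..65), so
    every within-arch neighbor pair is adjacent in the returned list.
    """
    try:
        return list(_ARCH[arch])
    except KeyError:
        raise ValueError(f"arch must be 'upper' or 'lower', got {arch!r}") from None


def _within_arch_neighbors(pos: FdiPosition) -> list[FdiPosition]:
    """Distal and mesial neighbors in the same arch (distal first)."""
    order = _ARCH[pos.arch]
    i = order.index(pos)
    out = []
    # the midline sits between list indices 4 and 5; distal = away from it
    distal_first = (i - 1, i + 1) if i <= 4 else (i + 1, i - 1)
    for j in distal_first:
        if 0 <= j < len(order):
            out.append(order[j])
    return out


def neighbor_set(position: "str | FdiPosition", k: int) -> list[FdiPosition]:
    """Ordered context positions for ``position`` at context size ``k``.

    Order is [distal, mesial, facing, facing-distal, facing-mesial];
    downstream pooling is order-invariant so the order is documentation only.
    For index-5 molars the absent distal neighbor is omitted and the list is
    shorter than ``k``.
    """
    if k not in (2, 3, 5):
        raise ValueError(f"k must be one of 2, 3, 5; got {k}")
    pos = FdiPosition.parse(position)
    out = _within_arch_neighbors(pos)
    if k >= 3:
        out.append(pos.facing())
    if k == 5:
        out.extend(_within_arch_neighbors(pos.facing()))
    return out


def context_positions(position: "str | int | FdiPosition", k: int) -> list[FdiPosition]:
    """Like :func:`neighbor_set` but tolerant of non-primary codes.

    Annotations from mixed-dentition radiographs may carry permanent-teeth
    codes (11–48); these are accepted as opaque labels with no context, so
    the classifier falls back to its context-free path for them. ``k = 0``
    likewise returns no context.
    """
    if k == 0:
        return []
    try:
        pos = FdiPosition.parse(position)
    except ValueError:
        return []
    return neighbor_set(pos, k)


@dataclass(frozen=True)
class NeighborRule:
    """Frozen map position -> ordered context positions for one k."""

    k: int
    mapping: dict[FdiPosition, tuple[FdiPosition, ...]]

    @classmethod
    def build(cls, k: int) -> "NeighborRule":
        return cls(k=k, mapping={p: tuple(neighbor_set(p, k)) for p in ALL_POSITIONS})
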