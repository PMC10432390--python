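"""Landmark scheme: which of the 72 facial points are fixed landmarks,
which are sliding semilandmarks, and how points pair across the midline.

A scheme partitions the 72 point indices into 36 fixed (anatomical)
landmarks and 36 semilandmarks arranged on curves, and assigns every index
either to a bilateral (left, right) pair or to the facial midline. The
published 72-point digitizing layout is not reproduced in any table we can
ship, so :func:`default_scheme` provides a documented synthetic stand-in
with the same bookkeeping structure; users digitizing real faces should
load their own scheme from JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


class SchemeError(ValueError):
    """Raised when a landmark scheme violates its structural invariants."""


@dataclass(frozen=True)
class SemilandmarkCurve:
    """An ordered run of semilandmarks between two fixed anchor landmarks.

    ``anchors = (start, end)`` are fixed-landmark indices;
    ``semilandmarks`` are the interior sliding points ordered from start
    to end along the curve.
    """

    anchors: tuple[int, int]
    semilandmarks: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.anchors) != 2:
            raise SchemeError("curve needs exactly two anchors")
        if len(self.semilandmarks) < 1:
            raise SchemeError("curve needs at least one interior semilandmark")

    @property
    def path(self) -> tuple[int, ...]:
        """Indices along the curve including anchors: start, semis..., end."""
        return (self.anchors[0], *self.semilandmarks, self.anchors[1])


@dataclass(frozen=True)
class LandmarkScheme:
    n_points: int
    fixed_indices: tuple[int, ...]
    semilandmark_curves: tuple[SemilandmarkCurve, ...]
    bilateral_pairs: tuple[tuple[int, int], ...]  # (left, right)
    midline_indices: tuple[int, ...]
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def semilandmark_indices(self) -> tuple[int, ...]:
        out: list[int] = []
        for c in self.semilandmark_curves:
            out.extend(c.semilandmarks)
        return tuple(out)

    def validate(self) -> None:
        all_idx = set(range(self.n_points))
        fixed = set(self.fixed_indices)
        semis = set(self.semilandmark_indices)
        if len(self.fixed_indices) != len(fixed):
            raise SchemeError("duplicate fixed indices")
        if len(self.semilandmark_indices) != len(semis):
            raise SchemeError("a semilandmark appears on more than one curve")
        if fixed & semis:
            raise SchemeError(f"indices both fixed and semilandmark: {sorted(fixed & semis)}")
        if fixed | semis != all_idx:
            raise SchemeError("fixed + semilandmark indices do not cover all points")
        for c in self.semilandmark_curves:
            for a in c.anchors:
                if a not in fixed:
                    raise SchemeError(f"curve anchor {a} is not a fixed landmark")
        paired = [i for pair in self.bilateral_pairs for i in pair]
        sided = set(paired)
        if len(paired) != len(sided):
            raise SchemeError("an index appears in more than one bilateral pair")
        mid = set(self.midline_indices)
        if sided & mid:
            raise SchemeError("an index is both paired and midline")
        if sided | mid != all_idx:
            raise SchemeError("every index must be bilateral-paired or midline")

    # --- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "fixed_indices": list(self.fixed_indices),
            "semilandmark_curves": [
                {"anchors": list(c.anchors), "semilandmarks": list(c.semilandmarks)}
                for c in self.semilandmark_curves
            ],
            "bilateral_pairs": [list(p) for p in self.bilateral_pairs],
            "midline_indices": list(self.midline_indices),
            "names": {str(k): v for k, v in self.names.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkScheme":
        return cls(
            n_points=int(d["n_points"]),
            fixed_indices=tuple(int(i) for i in d["fixed_indices"]),
            semilandmark_curves=tuple(
                SemilandmarkCurve(
                    anchors=tuple(int(a) for a in c["anchors"]),
                    semilandmarks=tuple(int(s) for s in c["semilandmarks"]),
                )
                for c in d["semilandmark_curves"]
            ),
            bilateral_pairs=tuple(tuple(int(i) for i in p) for p in d["bilateral_pairs"]),
            midline_indices=tuple(int(i) for i in d["midline_indices"]),
            names={int(k): v for k, v in d.get("names", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkScheme":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Default synthetic 72-point scheme
# ---------------------------------------------------------------------------

# Midline fixed landmarks (self-paired under mirroring).
_MIDLINE_NAMES = ["glabella", "pronasale", "labiale_superius", "gnathion"]

# Bilateral fixed pairs; k-th pair occupies indices (right=4+2k, left=5+2k).
_PAIR_NAMES = [
    "endocanthion",
    "exocanthion",
    "brow_inner",
    "brow_outer",
    "supraorbital",
    "alare",
    "cheilion",
    "zygion",
    "gonion",
    "temporal",
    "forehead_lateral",
    "mid_mandible",
    "nostril_base",
    "upper_lip_lateral",
    "lower_lip_lateral",
    "infraorbital",
]


def _pair_index(k: int) -> tuple[int, int]:
    """(right, left) indices of the k-th bilateral fixed pair."""
    return 4 + 2 * k, 5 + 2 * k


def _semi_index(curve: int, j: int, side: str) -> int:
    """Index of the j-th semilandmark (0..2) on curve 0..5, side 'R'/'L'."""
    base = 36 + 6 * curve
    return base + j if side == "R" else base + 3 + j


# Curves run between fixed anchors; names reference the pair list above.
# (start_anchor, end_anchor) given for the right side; left is mirrored.
_CURVE_ANCHORS_R = [
    ("temporal", "zygion"),  # upper facial outline
    ("zygion", "gonion"),  # lower facial outline
    ("gonion", "gnathion"),  # mandible to chin (ends on the midline)
    ("endocanthion", "exocanthion"),  # upper eyelid
    ("endocanthion", "exocanthion"),  # lower eyelid
    ("brow_inner", "brow_outer"),  # eyebrow
]


def _anchor_index(name: str, side: str) -> int:
    if name in _MIDLINE_NAMES:
        return _MIDLINE_NAMES.index(name)
    k = _PAIR_NAMES.index(name)
    r, left = _pair_index(k)
    return r if side == "R" else left


def default_scheme() -> LandmarkScheme:
    """The package's synthetic stand-in 72-point scheme.

    4 midline fixed landmarks, 16 bilateral fixed pairs (36 fixed points),
    and 6 bilateral curve pairs with 3 interior semilandmarks each
    (36 semilandmarks). Semilandmarks pair left-right position-wise along
    mirrored curves.
    """
    fixed = tuple(range(36))
    curves: list[SemilandmarkCurve] = []
    for c, (a, b) in enumerate(_CURVE_ANCHORS_R):
        for side in ("R", "L"):
            curves.append(
                SemilandmarkCurve(
                    anchors=(_anchor_index(a, side), _anchor_index(b, side)),
                    semilandmarks=tuple(_semi_index(c, j, side) for j in range(3)),
                )
            )
    pairs: list[tuple[int, int]] = []
    for k in range(16):
        r, left = _pair_index(k)
        pairs.append((left, r))
    for c in range(6):
        for j in range(3):
            pairs.append((_semi_index(c, j, "L"), _semi_index(c, j, "R")))
    names = {i: n for i, n in enumerate(_MIDLINE_NAMES)}
    for k, n in enumerate(_PAIR_NAMES):
        r, left = _pair_index(k)
        names[r] = f"{n}_R"
        names[left] = f"{n}_L"
    return LandmarkScheme(
        n_points=72,
        fixed_indices=fixed,
        semilandmark_curves=tuple(curves),
        bilateral_pairs=tuple(pairs),
        midline_indices=(0, 1, 2, 3),
        names=names,
    )
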