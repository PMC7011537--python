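"""Ordinal rating scales and their harmonization onto the three-level frame.

A Delphi panel may rate the same items on scales of different granularity
(here: a three-point goal scale, a five-point importance scale, and a
numeric nine-point scale).  To compare consensus and reliability across
scales, the finer scales are collapsed deterministically onto the coarse
frame ``MAIN`` ("main goal") > ``SECONDARY`` ("secondary goal") >
``NONE`` ("no goal").  The collapsed variants are conventionally written
with a trailing asterisk (``five_point*``, ``nine_point*``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "ThreeLevel",
    "RatingScale",
    "ScaleRegistry",
    "THREE_POINT",
    "FIVE_POINT",
    "NINE_POINT",
    "builtin_scales",
    "map_to_three",
    "is_top_category",
    "load_scales_yaml",
    "dump_scales_yaml",
]


class ThreeLevel(enum.IntEnum):
    """The harmonized three-level frame, totally ordered MAIN > SECONDARY > NONE."""

    NONE = 0
    SECONDARY = 1
    MAIN = 2

    @property
    def label(self) -> str:
        return {"NONE": "no goal", "SECONDARY": "secondary goal", "MAIN": "main goal"}[self.name]


@dataclass(frozen=True)
class RatingScale:
    """An ordered categorical rating scale with its three-level harmonization map.

    Parameters
    ----------
    scale_id:
        Short identifier, e.g. ``"three_point"``.
    categories:
        Category labels ordered from least to most important.
    to_three:
        Total map from category label to :class:`ThreeLevel`.  Must be
        monotone in the category order (a higher raw category never maps
        below a lower one).
    top_categories:
        The categories counted as "main goal".  Derived from ``to_three``
        when omitted; when given it must equal the MAIN preimage, so that
        top-category membership and harmonized MAIN always coincide.
    """

    scale_id: str
    categories: tuple[str, ...]
    to_three: Mapping[str, ThreeLevel]
    top_categories: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        cats = tuple(self.categories)
        object.__setattr__(self, "categories", cats)
        if len(cats) < 2:
            raise ValueError(f"scale {self.scale_id!r}: needs at least 2 categories")
        if len(set(cats)) != len(cats):
            raise ValueError(f"scale {self.scale_id!r}: duplicate categories")
        mapping = {c: ThreeLevel(self.to_three[c]) for c in cats if c in self.to_three}
        missing = [c for c in cats if c not in mapping]
        if missing:
            raise ValueError(f"scale {self.scale_id!r}: to_three missing {missing}")
        extra = set(self.to_three) - set(cats)
        if extra:
            raise ValueError(f"scale {self.scale_id!r}: to_three maps unknown categories {sorted(extra)}")
        levels = [mapping[c] for c in cats]
        if any(b < a for a, b in zip(levels, levels[1:])):
            raise ValueError(f"scale {self.scale_id!r}: to_three is not monotone in category order")
        object.__setattr__(self, "to_three", mapping)
        derived_top = frozenset(c for c in cats if mapping[c] is ThreeLevel.MAIN)
        if not derived_top:
            raise ValueError(f"scale {self.scale_id!r}: no category maps to MAIN")
        if self.top_categories is None:
            object.__setattr__(self, "top_categories", derived_top)
        else:
            given = frozenset(self.top_categories)
            if given != derived_top:
                raise ValueError(
                    f"scale {self.scale_id!r}: top_categories {sorted(given)} inconsistent "
                    f"with MAIN preimage {sorted(derived_top)}"
                )
            object.__setattr__(self, "top_categories", given)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def index(self, rating: str) -> int:
        """Position of ``rating`` in the least-to-most-important order."""
        try:
            return self.categories.index(rating)
        except ValueError:
            raise KeyError(f"rating {rating!r} is not a category of scale {self.scale_id!r}") from None

    def __contains__(self, rating: str) -> bool:
        return rating in self.categories


def map_to_three(scale: RatingScale, rating: str) -> ThreeLevel:
    """Collapse ``rating`` onto the harmonized three-level frame."""
    if rating not in scale.to_three:
        raise KeyError(f"rating {rating!r} is not a category of scale {scale.scale_id!r}")
    return scale.to_three[rating]


def is_top_category(scale: RatingScale, rating: str) -> bool:
    """True iff ``rating`` harmonizes to MAIN ("main goal")."""
    return map_to_three(scale, rating) is ThreeLevel.MAIN


THREE_POINT = RatingScale(
    scale_id="three_point",
    categories=("no goal", "secondary goal", "main goal"),
    to_three={
        "no goal": ThreeLevel.NONE,
        "secondary goal": ThreeLevel.SECONDARY,
        "main goal": ThreeLevel.MAIN,
    },
)

FIVE_POINT = RatingScale(
    scale_id="five_point",
    categories=(
        "this does not apply to me",
        "I do not expect this",
        "a little important",
        "somewhat important",
        "very important",
    ),
    to_three={
        "this does not apply to me": ThreeLevel.NONE,
        "I do not expect this": ThreeLevel.NONE,
        "a little important": ThreeLevel.SECONDARY,
        "somewhat important": ThreeLevel.SECONDARY,
        "very important": ThreeLevel.MAIN,
    },
)

# Numeric nine-point scale: 1-3 "not important", 4-6 "important, but not
# critical", 7-9 "important"; 7 belongs to the top band.
NINE_POINT = RatingScale(
    scale_id="nine_point",
    categories=tuple(str(i) for i in range(1, 10)),
    to_three={
        **{str(i): ThreeLevel.NONE for i in (1, 2, 3)},
        **{str(i): ThreeLevel.SECONDARY for i in (4, 5, 6)},
        **{str(i): ThreeLevel.MAIN for i in (7, 8, 9)},
    },
)


class ScaleRegistry(Mapping[str, RatingScale]):
    """Lookup of :class:`RatingScale` by ``scale_id``."""

    def __init__(self, scales: Iterable[RatingScale] = ()) -> None:
        self._scales: dict[str, RatingScale] = {}
        for s in scales:
            self.register(s)

    def register(self, scale: RatingScale) -> None:
        if scale.scale_id in self._scales:
            raise ValueError(f"scale {scale.scale_id!r} already registered")
        self._scales[scale.scale_id] = scale

    def __getitem__(self, scale_id: str) -> RatingScale:
        try:
            return self._scales[scale_id]
        except KeyError:
            raise KeyError(f"unknown scale {scale_id!r}; registered: {sorted(self._scales)}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._scales)

    def __len__(self) -> int:
        return len(self._scales)


def builtin_scales() -> ScaleRegistry:
    """Registry with the three built-in study scales."""
    return ScaleRegistry([THREE_POINT, FIVE_POINT, NINE_POINT])


def load_scales_yaml(path: str | Path) -> ScaleRegistry:
    """Read a scale registry from YAML (see :func:`dump_scales_yaml` for the layout)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "scales" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'scales' list")
    registry = ScaleRegistry()
    for entry in doc["scales"]:
        registry.register(
            RatingScale(
                scale_id=entry["scale_id"],
                categories=tuple(str(c) for c in entry["categories"]),
                to_three={str(c): ThreeLevel[str(v)] for c, v in entry["to_three"].items()},
                top_categories=(
                    frozenset(str(c) for c in entry["top_categories"])
                    if "top_categories" in entry
                    else None
                ),
            )
        )
    return registry


def dump_scales_yaml(registry: ScaleRegistry, path: str | Path) -> None:
    doc = {
        "scales": [
            {
                "scale_id": s.scale_id,
                "categories": list(s.categories),
                "top_categories": sorted(s.top_categories),
                "to_three": {c: s.to_three[c].name for c in s.categories},
            }
            for s in registry.values()
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
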