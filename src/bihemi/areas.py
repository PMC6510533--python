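"""Cortical area (ROI) containers with hemisphere labels and midline distances.

Areas come in homotopic pairs: ``PM_L`` / ``PM_R`` share the base name ``PM``
and sit at equal distance from the midline in the two hemispheres.  Masks are
optional boolean images used only when working at the pixel level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class Area:
    """A single ROI: name is ``<base>_<hemisphere>``, e.g. ``PM_L``."""

    name: str
    base: str
    hemisphere: str
    distance_mm: float
    mask: Optional[np.ndarray] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        if not np.isfinite(self.distance_mm) or self.distance_mm < 0:
            raise ValueError(f"distance_mm must be finite and >= 0, got {self.distance_mm}")


class AreaSet:
    """Ordered collection of ROIs with homotopic-partner lookup.

    The ordering of areas fixes the row ordering of every area x frame matrix
    produced by the generator and the extractors.
    """

    def __init__(self, areas: Sequence[Area]):
        names = [a.name for a in areas]
        if len(set(names)) != len(names):
            raise ValueError("duplicate area names")
        self._areas = list(areas)
        self._by_name = {a.name: a for a in self._areas}

    @classmethod
    def bilateral(
        cls,
        bases: Sequence[str],
        distances_mm: Sequence[float],
        masks: Optional[dict] = None,
    ) -> "AreaSet":
        """Build an L/R pair for every base name; row order L, R per base."""
        if len(bases) != len(distances_mm):
            raise ValueError("bases and distances_mm must have equal length")
        areas = []
        for base, d in zip(bases, distances_mm):
            for hemi in HEMISPHERES:
                name = f"{base}_{hemi}"
                mask = masks.get(name) if masks else None
                areas.append(Area(name, base, hemi, float(d), mask))
        return cls(areas)

    def __len__(self) -> int:
        return len(self._areas)

    def __iter__(self) -> Iterator[Area]:
        return iter(self._areas)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Area:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [a.name for a in self._areas]

    @property
    def bases(self) -> list[str]:
        out: list[str] = []
        for a in self._areas:
            if a.base not in out:
                out.append(a.base)
        return out

    def index(self, name: str) -> int:
        return self.names.index(name)

    def partner(self, name: str) -> Area:
        """Homotopic partner of an area (PM_L <-> PM_R)."""
        a = self._by_name[name]
        other = f"{a.base}_{'R' if a.hemisphere == 'L' else 'L'}"
        if other not in self._by_name:
            raise KeyError(f"area {name} has no contralateral partner {other}")
        return self._by_name[other]

    def hemisphere(self, hemi: str) -> list[Area]:
        return [a for a in self._areas if a.hemisphere == hemi]

    def with_masks(self, masks: dict) -> "AreaSet":
        return AreaSet(
            [
                Area(a.name, a.base, a.hemisphere, a.distance_mm, masks.get(a.name, a.mask))
                for a in self._areas
            ]
        )
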