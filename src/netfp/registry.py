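"""Region-of-interest registry.

The default parcellation combines the bilateral Desikan--Killiany cortical
atlas (34 regions per hemisphere), the standard bilateral subcortical
structures, the bilateral cerebellar cortex, and the brainstem, for a total
of 87 regions.  The registry fixes a canonical region order; every edge
index used elsewhere in the package (edge vectors, harmonization tables,
classifier coefficients) derives from this order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = [
    "RoiEntry",
    "RoiRegistry",
    "build_default_registry",
    "DESIKAN_KILLIANY_CORTICAL",
    "SUBCORTICAL_STRUCTURES",
]

#: The 34 Desikan--Killiany cortical parcels (per hemisphere).
DESIKAN_KILLIANY_CORTICAL: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: The 8 standard bilateral subcortical structures (per hemisphere).
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
    "ventraldc",
)

HEMISPHERES = ("L", "R", "midline")
ROI_CLASSES = ("cortical", "subcortical", "cerebellar", "brainstem")


@dataclass(frozen=True)
class RoiEntry:
    """One region: unique name, hemisphere, and anatomical class."""

    name: str
    hemisphere: str  # "L", "R" or "midline"
    roi_class: str  # "cortical", "subcortical", "cerebellar", "brainstem"

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.roi_class not in ROI_CLASSES:
            raise ValueError(f"unknown ROI class {self.roi_class!r}")

    @property
    def base_name(self) -> str:
        """Name with the hemisphere prefix stripped (for homologue matching)."""
        for prefix in ("lh_", "rh_"):
            if self.name.startswith(prefix):
                return self.name[len(prefix):]
        return self.name


class RoiRegistry:
    """Ordered, immutable collection of :class:`RoiEntry`.

    The entry order is canonical: all similarity matrices and edge vectors
    produced by this package index regions in registry order.
    """

    def __init__(self, entries: Sequence[RoiEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")
        self._entries: tuple[RoiEntry, ...] = tuple(entries)
        self._index = {e.name: i for i, e in enumerate(self._entries)}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[RoiEntry]:
        return iter(self._entries)

    def __getitem__(self, key: int | str) -> RoiEntry:
        if isinstance(key, str):
            return self._entries[self._index[key]]
        return self._entries[key]

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RoiRegistry):
            return NotImplemented
        return self._entries == other._entries

    @property
    def names(self) -> list[str]:
        return [e.name for e in self._entries]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"ROI {name!r} is not in the registry") from None

    def by_class(self, roi_class: str) -> list[RoiEntry]:
        return [e for e in self._entries if e.roi_class == roi_class]

    def homologous_pairs(self) -> list[tuple[str, str]]:
        """(left, right) name pairs sharing a base name; midline excluded."""
        left = {e.base_name: e.name for e in self._entries if e.hemisphere == "L"}
        right = {e.base_name: e.name for e in self._entries if e.hemisphere == "R"}
        return [(left[b], right[b]) for b in left if b in right]

    def n_edges(self) -> int:
        r = len(self)
        return r * (r - 1) // 2


def build_default_registry() -> RoiRegistry:
    """Build the canonical 87-region registry.

    Order: left cortical (34), right cortical (34), left subcortical (8),
    right subcortical (8), left cerebellar cortex, right cerebellar cortex,
    brainstem.
    """
    entries: list[RoiEntry] = []
    for hemi, prefix in (("L", "lh_"), ("R", "rh_")):
        entries += [
            RoiEntry(prefix + n, hemi, "cortical") for n in DESIKAN_KILLIANY_CORTICAL
        ]
    # reorder: all left cortical first, then all right cortical (already so)
    for hemi, prefix in (("L", "lh_"), ("R", "rh_")):
        entries += [
            RoiEntry(prefix + n, hemi, "subcortical") for n in SUBCORTICAL_STRUCTURES
        ]
    entries.append(RoiEntry("lh_cerebellum_cortex", "L", "cerebellar"))
    entries.append(RoiEntry("rh_cerebellum_cortex", "R", "cerebellar"))
    entries.append(RoiEntry("brainstem", "midline", "brainstem"))
    return RoiRegistry(entries)
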