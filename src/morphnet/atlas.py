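"""Cortical parcellation atlases.

ROI indices are 1-based in every user-facing table and edge list, matching
the conventional numbering of the Desikan-Killiany parcellation (region 1 =
banks of the superior temporal sulcus ... region 35 = insula).  Internally
arrays are 0-based; any function that accepts or emits ROI indices states
which convention it uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["ROIAtlas", "desikan_killiany", "read_atlas", "write_atlas"]

#: FreeSurfer aparc (Desikan-Killiany) cortical labels, one hemisphere,
#: in annotation order.  Index in this list + 1 = region number.
DESIKAN_KILLIANY_35 = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "corpuscallosum",
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


@dataclass(frozen=True)
class ROIAtlas:
    """An ordered list of unique region-of-interest labels.

    Parameters
    ----------
    names
        ROI labels; position ``i`` (0-based) is region ``i + 1`` (1-based).
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ValueError("atlas must contain at least one ROI")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate ROI labels in atlas: {dupes}")

    @property
    def count(self) -> int:
        return len(self.names)

    def name_of(self, region: int) -> str:
        """Label of a 1-based region number."""
        if not 1 <= region <= self.count:
            raise IndexError(
                f"region {region} out of range for {self.count}-ROI atlas"
            )
        return self.names[region - 1]

    def index_of(self, name: str) -> int:
        """1-based region number of a label."""
        try:
            return self.names.index(name) + 1
        except ValueError:
            raise KeyError(f"unknown ROI label {name!r}") from None


def desikan_killiany() -> ROIAtlas:
    """The 35-region single-hemisphere Desikan-Killiany cortical atlas."""
    return ROIAtlas(DESIKAN_KILLIANY_35)


def read_atlas(path: str | Path) -> ROIAtlas:
    """Read an atlas file: one ROI name per line, line order = region order."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    names = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    return ROIAtlas(tuple(names))


def write_atlas(atlas: ROIAtlas, path: str | Path) -> None:
    Path(path).write_text("\n".join(atlas.names) + "\n", encoding="utf-8")
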