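"""Class legends for coastal plant-community maps.

The default legend covers the ten mapped categories of the south-Florida
coastal fringe: seven plant communities (three mangrove forests, two
buttonwood forests distinguished by their understory, halophyte prairie and
tropical hardwood hammock), two invasive shrubs (Brazilian pepper, latherleaf)
that are merged into a single class for accuracy assessment, plus mud flat and
open water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ClassLegend", "default_legend", "UNASSIGNED"]

#: sentinel for pixels without a class label (nodata / not yet filled)
UNASSIGNED = 0


@dataclass(frozen=True)
class ClassLegend:
    """Ordered class identifiers with display names and assessment merge-groups.

    Parameters
    ----------
    names
        Mapping of integer class id (>0) to display name; order is meaningful.
    merge_groups
        Mapping of assessment-class name to the list of member class ids.
        Must be a partition of the class ids.  Classes absent from every group
        are implicitly singleton groups under their own name.
    """

    names: dict[int, str]
    merge_groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("legend needs at least two classes")
        if UNASSIGNED in self.names:
            raise ValueError(f"class id {UNASSIGNED} is reserved for unassigned pixels")
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("class display names must be unique")
        seen: set[int] = set()
        for group, members in self.merge_groups.items():
            for m in members:
                if m not in self.names:
                    raise ValueError(f"merge group {group!r} references unknown class {m}")
                if m in seen:
                    raise ValueError(f"class {m} appears in more than one merge group")
                seen.add(m)

    @property
    def class_ids(self) -> tuple[int, ...]:
        return tuple(self.names)

    @property
    def assessment_classes(self) -> tuple[str, ...]:
        """Assessment-legend names, in legend order (merged groups appear once)."""
        out: list[str] = []
        grouped = {m: g for g, ms in self.merge_groups.items() for m in ms}
        for cid, name in self.names.items():
            label = grouped.get(cid, name)
            if label not in out:
                out.append(label)
        return tuple(out)

    def assessment_label(self, class_id: int) -> str:
        for group, members in self.merge_groups.items():
            if class_id in members:
                return group
        return self.names[class_id]

    def members(self, assessment_class: str) -> tuple[int, ...]:
        if assessment_class in self.merge_groups:
            return self.merge_groups[assessment_class]
        for cid, name in self.names.items():
            if name == assessment_class:
                return (cid,)
        raise KeyError(assessment_class)


# canonical class ids, ordered roughly low to high elevation
BLACK_MANGROVE = 1
RED_MANGROVE = 2
WHITE_MANGROVE = 3
BUTTONWOOD_GLYCOPHYTE = 4
BUTTONWOOD_HALOPHYTE = 5
HALOPHYTE_PRAIRIE = 6
HARDWOOD_HAMMOCK = 7
SCHINUS = 8
COLUBRINA = 9
MUD_FLAT = 10
WATER = 11


def default_legend() -> ClassLegend:
    """The 11-class map legend; the two invasives merge for assessment (10 classes)."""
    return ClassLegend(
        names={
            BLACK_MANGROVE: "black mangrove",
            RED_MANGROVE: "red mangrove",
            WHITE_MANGROVE: "white mangrove",
            BUTTONWOOD_GLYCOPHYTE: "buttonwood/glycophyte",
            BUTTONWOOD_HALOPHYTE: "buttonwood/halophyte",
            HALOPHYTE_PRAIRIE: "halophyte prairie",
            HARDWOOD_HAMMOCK: "hardwood hammock",
            SCHINUS: "Schinus",
            COLUBRINA: "Colubrina",
            MUD_FLAT: "mud flat",
            WATER: "water",
        },
        merge_groups={"invasive species": (SCHINUS, COLUBRINA)},
    )
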