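"""Canonical 22-marker set and label aliasing.

The marker set covers four head markers (anterior/posterior x left/right),
bilateral wrist (ulna styloid), elbow (lateral humeral epicondyle), acromion,
posterior and anterior iliac spine, knee (lateral femoral epicondyle), ankle
(lateral malleolus) and toe (distal phalange 1), plus a sternum marker and one
on the right thigh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

HEAD_MARKERS = ("head_ant_L", "head_ant_R", "head_post_L", "head_post_R")

BILATERAL_STEMS = ("wrist", "elbow", "acromion", "psis", "asis", "knee", "ankle", "toe")

UNILATERAL_MARKERS = ("sternum", "thigh_R")

CANONICAL_MARKERS: tuple[str, ...] = (
    HEAD_MARKERS
    + tuple(f"{stem}_{side}" for stem in BILATERAL_STEMS for side in ("L", "R"))
    + UNILATERAL_MARKERS
)

assert len(CANONICAL_MARKERS) == 22

#: Common vendor-style labels mapped onto canonical names.  Extend via the
#: ``aliases`` argument of :func:`exerstep.mocap_io.load_recording`.
DEFAULT_ALIASES: dict[str, str] = {
    "HeadLF": "head_ant_L",
    "HeadRF": "head_ant_R",
    "HeadLB": "head_post_L",
    "HeadRB": "head_post_R",
    "WristL": "wrist_L",
    "WristR": "wrist_R",
    "LWRA": "wrist_L",
    "RWRA": "wrist_R",
    "ElbowL": "elbow_L",
    "ElbowR": "elbow_R",
    "ShoulderL": "acromion_L",
    "ShoulderR": "acromion_R",
    "LPSI": "psis_L",
    "RPSI": "psis_R",
    "LASI": "asis_L",
    "RASI": "asis_R",
    "KneeL": "knee_L",
    "KneeR": "knee_R",
    "AnkleL": "ankle_L",
    "AnkleR": "ankle_R",
    "LANK": "ankle_L",
    "RANK": "ankle_R",
    "ToeL": "toe_L",
    "ToeR": "toe_R",
    "LTOE": "toe_L",
    "RTOE": "toe_R",
    "STRN": "sternum",
    "Chest": "sternum",
    "ThighR": "thigh_R",
    "RTHI": "thigh_R",
}


@dataclass(frozen=True)
class MarkerSet:
    """Ordered set of marker labels with side tags on bilateral markers."""

    names: tuple[str, ...] = CANONICAL_MARKERS

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate marker labels")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    @property
    def head(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n.startswith("head_"))

    def side_of(self, name: str) -> str | None:
        """Return 'L'/'R' for side-tagged markers, None for unilateral sternum."""
        if name == "sternum":
            return None
        if name.endswith("_L"):
            return "L"
        if name.endswith("_R"):
            return "R"
        return None


def resolve_label(label: str, aliases: dict[str, str] | None = None) -> str:
    """Map a raw trajectory-file label onto a canonical marker name."""
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    if label in CANONICAL_MARKERS:
        return label
    return table.get(label, label)
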