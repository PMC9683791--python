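"""Spatial three-group classification of hotspot residues.

Hotspot residues fall into functional neighbourhoods of the transporter:
those lining the substrate cavity (substrate coordination), elsewhere on
the transmembrane helices (conformational-change region), on the
nucleotide-binding domain (ATP hydrolysis), or on the C-terminal helix.
The published grouping is descriptive; here it is made algorithmic with a
fixed precedence so every residue gets exactly one label:

    cavity_lining > tmd_other > nbd > ch_other > unassigned

A residue inside any TM range that is also in the lining set is
``cavity_lining``; inside TM ranges only, ``tmd_other``; then NBD, then CH;
anything else is ``unassigned`` and reported. Because the C-terminal helix
is a distinct structural element, CH residues keep their own label; the
conventional three-way split reported alongside counts nbd + ch_other as
group 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .structure_model import ResidueRef, SegmentAnnotation, TM_SEGMENTS
from .variants import HotspotTable

GROUPS = ("cavity_lining", "tmd_other", "nbd", "ch_other", "unassigned")


@dataclass
class GroupAssignment:
    """Exactly one group label per hotspot residue, plus counts."""

    labels: dict[int, str]
    group_counts: dict[str, int]
    warning: str | None = None

    def residues(self, group: str) -> list[int]:
        return sorted(r for r, g in self.labels.items() if g == group)

    def three_group_counts(self) -> tuple[int, int, int]:
        """(cavity_lining, tmd_other, nbd + ch_other) — the conventional
        three-way split of the structural mapping."""
        c = self.group_counts
        return (
            c.get("cavity_lining", 0),
            c.get("tmd_other", 0),
            c.get("nbd", 0) + c.get("ch_other", 0),
        )


def _lining_numbers(lining: Iterable[ResidueRef | int]) -> set[int]:
    nums = set()
    for item in lining:
        nums.add(item.residue_number if isinstance(item, ResidueRef) else int(item))
    return nums


def classify_hotspots(
    hotspots: HotspotTable | Iterable[int],
    annotation: SegmentAnnotation,
    lining: Iterable[ResidueRef | int],
) -> GroupAssignment:
    """Assign every hotspot residue to one spatial group by precedence.

    ``lining`` accepts ResidueRefs (from cavity detection) or bare residue
    numbers; the homodimer makes numbering chain-agnostic. When at least
    half of the hotspots end up unassigned the result carries a loud
    warning — the usual cause is a numbering mismatch between the variant
    table and the segment annotation.
    """
    residues = (
        hotspots.hotspot_residues if isinstance(hotspots, HotspotTable) else sorted(set(hotspots))
    )
    lining_nums = _lining_numbers(lining)

    def in_any(segments: tuple[str, ...], num: int) -> bool:
        return any(annotation.contains_number(s, num) for s in segments if s in annotation.ranges)

    labels: dict[int, str] = {}
    for num in residues:
        in_tm = in_any(TM_SEGMENTS, num)
        if in_tm and num in lining_nums:
            labels[num] = "cavity_lining"
        elif in_tm:
            labels[num] = "tmd_other"
        elif in_any(("NBD",), num):
            labels[num] = "nbd"
        elif in_any(("CH",), num):
            labels[num] = "ch_other"
        else:
            labels[num] = "unassigned"

    counts = {g: 0 for g in GROUPS}
    for g in labels.values():
        counts[g] += 1
    warning = None
    if residues and counts["unassigned"] >= 0.5 * len(residues):
        warning = (
            f"{counts['unassigned']}/{len(residues)} hotspots unassigned — "
            "check residue-numbering agreement between variants and annotation"
        )
    return GroupAssignment(labels=labels, group_counts=counts, warning=warning)


def group_summary(assignment: GroupAssignment) -> dict:
    """Counts and residue lists per group, JSON/TSV-ready."""
    g1, g2, g3 = assignment.three_group_counts()
    return {
        "group_counts": dict(assignment.group_counts),
        "three_group_counts": {"cavity_lining": g1, "tmd_other": g2, "nbd_and_ch": g3},
        "total": sum(assignment.group_counts.values()),
        "residues": {g: assignment.residues(g) for g in GROUPS},
        "warning": assignment.warning,
    }


def summary_frame(assignment: GroupAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        [{"residue": r, "group": g} for r, g in sorted(assignment.labels.items())],
        columns=["residue", "group"],
    )


def viewer_triples(assignment: GroupAssignment, chains: tuple[str, ...] = ("A", "B")) -> str:
    """Plain ``chain resi group`` triples for molecular-viewer colouring."""
    lines = []
    for res, group in sorted(assignment.labels.items()):
        for chain in chains:
            lines.append(f"{chain} {res} {group}")
    return "\n".join(lines) + "\n"
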