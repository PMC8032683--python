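"""Per-frame and per-trajectory beta-sheet summaries.

The quantities tracked per snapshot are: the number of aligned triples, the
number of sheet components, the number and fraction of grains inside any
component, the residue-type composition of sheet grains (each sheet grain
counted once under its residue name — non-standard names such as "BTN" for
biotin are first-class keys), and per-component detail.  A residue-type
ratio helper supports observations like the Lys/Asp balance of
complementary-peptide bilayers: 0/0 reports NaN ("undefined") and x/0
reports +inf, as markers rather than exceptions, so a time series over
frames stays numerically aligned.
"""

from __future__ import annotations

import csv
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .components import SheetComponent, connected_components, grains_in_sheets
from .gro_io import Frame, Trajectory
from .triples import AlignedTriple, DetectionParams, find_aligned_triples

__all__ = [
    "FrameStats",
    "TrajectoryStats",
    "frame_statistics",
    "residue_ratio",
    "trajectory_statistics",
    "analyze_frame",
    "write_csv",
    "write_json",
]

CSV_COLUMNS = ["frame", "n_triples", "n_components", "n_grains_in_sheets",
               "fraction_in_sheets"]


@dataclass
class FrameStats:
    frame_index: int
    n_grains: int
    n_triples: int
    n_components: int
    n_grains_in_sheets: int
    fraction_in_sheets: float
    composition: dict[str, int]
    per_component: list[dict] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "frame": self.frame_index,
            "n_triples": self.n_triples,
            "n_components": self.n_components,
            "n_grains_in_sheets": self.n_grains_in_sheets,
            "fraction_in_sheets": self.fraction_in_sheets,
        }

    def to_dict(self) -> dict:
        d = self.to_row()
        d["n_grains"] = self.n_grains
        d["composition"] = dict(self.composition)
        d["per_component"] = self.per_component
        return d


@dataclass
class TrajectoryStats:
    per_frame: list[FrameStats]
    params: DetectionParams
    group_length: int

    def __iter__(self):
        return iter(self.per_frame)


def frame_statistics(frame: Frame, triples: set[AlignedTriple],
                     components: list[SheetComponent]) -> FrameStats:
    """Summarize one frame given its triples and components."""
    by_id = {g.grain_id: g for g in frame.grains}
    sheet_grains = grains_in_sheets(components)
    comp_counts = Counter(by_id[g].residue_name for g in sheet_grains)
    per_component = [
        {
            "component_id": c.component_id,
            "n_grains": c.n_grains,
            "n_triples": c.n_triples,
            "n_peptides": len(c.peptide_ids),
            "composition": dict(Counter(by_id[g].residue_name
                                        for g in c.grain_ids)),
        }
        for c in components
    ]
    n = len(frame)
    return FrameStats(
        frame_index=frame.frame_index,
        n_grains=n,
        n_triples=len(triples),
        n_components=len(components),
        n_grains_in_sheets=len(sheet_grains),
        fraction_in_sheets=(len(sheet_grains) / n) if n else 0.0,
        composition=dict(comp_counts),
        per_component=per_component,
    )


def residue_ratio(stats: FrameStats, name_a: str, name_b: str) -> float:
    """composition[name_a] / composition[name_b].

    Returns NaN when both counts are zero (undefined) and +inf when only the
    denominator is zero.
    """
    a = stats.composition.get(name_a, 0)
    b = stats.composition.get(name_b, 0)
    if b == 0:
        return math.nan if a == 0 else math.inf
    return a / b


def analyze_frame(frame: Frame,
                  params: DetectionParams = DetectionParams()
                  ) -> tuple[set[AlignedTriple], list[SheetComponent], FrameStats]:
    """Run detection, gluing and summary on one frame."""
    triples = find_aligned_triples(frame, params)
    comps = connected_components(triples, frame)
    return triples, comps, frame_statistics(frame, triples, comps)


def trajectory_statistics(traj: Trajectory,
                          params: DetectionParams = DetectionParams()
                          ) -> TrajectoryStats:
    """Analyze every frame independently, in order.

    Frames are independent units of work; a failure is re-raised with the
    frame index attached.
    """
    per_frame = []
    for frame in traj.frames:
        try:
            _, _, fs = analyze_frame(frame, params)
        except Exception as exc:
            raise RuntimeError(f"frame {frame.frame_index}: {exc}") from exc
        per_frame.append(fs)
    return TrajectoryStats(per_frame=per_frame, params=params,
                           group_length=traj.group_length)


def write_csv(stats: TrajectoryStats, sink) -> None:
    """One row per frame: frame, n_triples, n_components,
    n_grains_in_sheets, fraction_in_sheets."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", newline="") if own else sink
    try:
        w = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        w.writeheader()
        for fs in stats.per_frame:
            w.writerow(fs.to_row())
    finally:
        if own:
            fh.close()


def write_json(stats: TrajectoryStats, sink) -> None:
    """Full report: parameters plus per-frame detail with compositions."""
    doc = {
        "params": {
            "alpha": stats.params.alpha,
            "epsilon": stats.params.epsilon,
            "use_pbc": stats.params.use_pbc,
        },
        "group_length": stats.group_length,
        "frames": [fs.to_dict() for fs in stats.per_frame],
    }
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w") if own else sink
    try:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    finally:
        if own:
            fh.close()
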