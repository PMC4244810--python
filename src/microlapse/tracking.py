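"""Founder registration, frame-to-frame lineage linking, merge censoring,
and dividing / non-dividing classification.

Linking assumes colonies are immobilized under the agar and move negligibly
between frames, so the colony that grew from a founder is the current-frame
component with maximal pixel overlap against the founder's previous-frame
component.  When one current-frame component overlaps two or more lineages,
the colonies have merged: their areas are no longer attributable, so every
involved lineage is censored at that frame and its series ends one frame
earlier.  This per-lineage censoring preserves more data than stopping the
whole experiment at the first merge; the global rule is recoverable as the
minimum censoring frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .segmentation import LabelMask, ObjectMeasure

__all__ = [
    "Founder",
    "Lineage",
    "GrowthSeries",
    "FounderClassification",
    "register_founders",
    "link_frames",
    "build_growth_series",
    "classify_founders",
]


@dataclass(frozen=True)
class Founder:
    """One time-zero cell; ids are assigned by (row, col) centroid order so
    two identical runs always agree."""

    founder_id: int
    label_t0: int
    centroid: tuple[float, float]
    area_t0: int
    pi_positive_t0: bool


@dataclass
class Lineage:
    """Per-frame assignment of one founder to a segmented component."""

    founder_id: int
    frame_labels: list[int | None]
    areas: list[int | None]
    censored_at_frame: int | None = None  # first merge frame
    merged_with: list[int] = field(default_factory=list)
    lost_at_frame: int | None = None

    @property
    def n_observed(self) -> int:
        if self.censored_at_frame is not None:
            return self.censored_at_frame
        if self.lost_at_frame is not None:
            return self.lost_at_frame
        return sum(a is not None for a in self.areas)

    def observed_areas(self) -> list[int]:
        return [a for a in self.areas[: self.n_observed] if a is not None]


@dataclass
class GrowthSeries:
    """(time, area) observations for one founder, merge-censored."""

    founder_id: int
    times: np.ndarray     # hours, strictly increasing, prefix of frame times
    areas: np.ndarray     # pixels, > 0
    censored: bool

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if len(self.times) < 1 or len(self.times) != len(self.areas):
            raise ValueError("series needs matching, non-empty times and areas")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")

    @property
    def ln_areas(self) -> np.ndarray:
        return np.log(self.areas)


@dataclass(frozen=True)
class FounderClassification:
    founder_id: int
    label_class: str  # "dividing" | "non_dividing"
    pi_positive_t0: bool
    max_area_ratio: float


def register_founders(mask_t0: LabelMask,
                      measures_t0: list[ObjectMeasure]) -> list[Founder]:
    """One founder per time-zero object, ids sorted by (row, col) centroid.

    An empty frame yields an empty registry — fields with zero cells are a
    legitimate observation.
    """
    ordered = sorted(measures_t0, key=lambda m: m.centroid)
    return [
        Founder(founder_id=i, label_t0=m.label, centroid=m.centroid,
                area_t0=m.area, pi_positive_t0=m.pi_positive)
        for i, m in enumerate(ordered)
    ]


def link_frames(masks: list[LabelMask],
                founders: list[Founder] | None = None,
                measures_t0: list[ObjectMeasure] | None = None) -> list[Lineage]:
    """Track every founder through a stack of per-frame label masks.

    Assignment is by maximal pixel overlap between consecutive frames, with
    deterministic tie-breaks (lowest label, then lowest founder id).  Any
    current-frame component overlapping two or more lineages triggers a
    merge event censoring all of them at that frame.  Objects that lose all
    overlap end their series without the merge flag.
    """
    if not masks:
        raise ValueError("need at least one frame")
    if founders is None:
        if measures_t0 is None:
            from .segmentation import measure_objects
            measures_t0 = measure_objects(masks[0], np.zeros_like(masks[0], dtype=float))
        founders = register_founders(masks[0], measures_t0)
    n_frames = len(masks)
    lineages = {
        f.founder_id: Lineage(f.founder_id, [f.label_t0], [f.area_t0])
        for f in founders
    }
    # current assignment: founder -> label in the latest frame.  Censored
    # lineages stay in the map as "ghosts": they emit no further areas but
    # keep claiming their pixels, so a colony that later collides with an
    # already-merged blob is itself censored.
    current = {f.founder_id: f.label_t0 for f in founders}
    ghosts: set[int] = set()

    for t in range(1, n_frames):
        prev, cur = masks[t - 1], masks[t]
        if prev.shape != cur.shape:
            raise ValueError("frames must share dimensions")
        tracked = sorted(current)
        if not tracked:
            break
        # map previous labels to lineage slots (0 = unclaimed)
        lab2slot = np.zeros(int(prev.max()) + 1, dtype=np.int64)
        for slot, fid in enumerate(tracked, start=1):
            lab2slot[current[fid]] = slot
        slot_img = lab2slot[prev]
        k_cur = int(cur.max())
        sel = (slot_img > 0) & (cur > 0)
        overlap = np.zeros((len(tracked) + 1, k_cur + 1), dtype=np.int64)
        if np.any(sel):
            codes = slot_img[sel] * (k_cur + 1) + cur[sel]
            counts = np.bincount(codes, minlength=(len(tracked) + 1) * (k_cur + 1))
            overlap = counts.reshape(len(tracked) + 1, k_cur + 1)
        overlap = overlap[1:, :]  # drop the unclaimed row

        # merge events: a current component claimed by >= 2 lineages
        assigned: dict[int, int] = {}
        for c in range(1, k_cur + 1):
            claimants = [tracked[i] for i in np.flatnonzero(overlap[:, c])]
            if len(claimants) >= 2:
                for fid in claimants:
                    lin = lineages[fid]
                    if lin.censored_at_frame is None and fid not in ghosts:
                        lin.censored_at_frame = t
                        lin.merged_with = sorted(set(claimants) - {fid})
                    assigned[fid] = c
                ghosts.update(claimants)

        areas_cur = np.bincount(cur.ravel(), minlength=k_cur + 1)
        next_current: dict[int, int] = {}
        for i, fid in enumerate(tracked):
            lin = lineages[fid]
            if fid in assigned:  # merged this frame or ghost pulled into a blob
                lin.frame_labels.append(None)
                lin.areas.append(None)
                next_current[fid] = assigned[fid]
                continue
            row = overlap[i]
            if row.sum() == 0:
                if fid not in ghosts:
                    lin.lost_at_frame = t
                lin.frame_labels.append(None)
                lin.areas.append(None)
                continue
            best = int(np.argmax(row))  # argmax -> lowest label on ties
            next_current[fid] = best
            if fid in ghosts:
                lin.frame_labels.append(None)
                lin.areas.append(None)
            else:
                lin.frame_labels.append(best)
                lin.areas.append(int(areas_cur[best]))
        # pad lineages that dropped out of tracking this frame
        for fid in list(lineages):
            if len(lineages[fid].frame_labels) < t + 1:
                lineages[fid].frame_labels.append(None)
                lineages[fid].areas.append(None)
        current = next_current

    # pad to full length
    for lin in lineages.values():
        while len(lin.frame_labels) < n_frames:
            lin.frame_labels.append(None)
            lin.areas.append(None)
    return [lineages[f.founder_id] for f in founders]


def build_growth_series(lineage: Lineage, frame_times: np.ndarray) -> GrowthSeries:
    """Extract the uncensored (time, area) prefix of a lineage."""
    n = lineage.n_observed
    times = np.asarray(frame_times[:n], dtype=float)
    areas = np.asarray(lineage.areas[:n], dtype=float)
    return GrowthSeries(lineage.founder_id, times, areas,
                        censored=lineage.censored_at_frame is not None)


def classify_founders(lineages: list[Lineage], founders: list[Founder],
                      config: AnalysisConfig) -> list[FounderClassification]:
    """Dividing iff the maximum observed area ratio reaches the configured
    threshold (default 4x, about two doublings).  PI positivity at time zero
    is reported as an orthogonal flag."""
    pi_flags = {f.founder_id: f.pi_positive_t0 for f in founders}
    out = []
    for lin in lineages:
        obs = lin.observed_areas()
        a0 = obs[0]
        ratio = max(obs) / a0 if a0 > 0 else float("nan")
        label = "dividing" if ratio >= config.dividing_ratio else "non_dividing"
        out.append(FounderClassification(
            founder_id=lin.founder_id,
            label_class=label,
            pi_positive_t0=pi_flags.get(lin.founder_id, False),
            max_area_ratio=float(ratio),
        ))
    return out
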