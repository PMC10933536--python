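"""Cross-tag call matching and focal / non-focal caller assignment.

When every member of a small group carries an acoustic tag, one physical
call is often audible on several records.  Because the tag on the calling
animal is closest to the sound source, that tag should receive the call at
the highest level regardless of the source level the animal chose.  The
procedure is therefore:

1. cluster near-simultaneous detections across tags into unique calls
   (single-linkage on start-time proximity and span overlap),
2. label each unique call *focal* on the tag with the clearly highest
   received level, *non-focal* on the others, or *indeterminate* when no
   tag stands out by at least ``delta_db``;
3. calls seen on only one tag are assumed focal there, and when every tag
   but one was noise-obscured the call is focal on the clean tag.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .acoustics import RLMeasurement

FOCAL = "focal"
NON_FOCAL = "non_focal"
INDETERMINATE = "indeterminate"

DEFAULT_DELTA_DB = 3.0
DEFAULT_START_TOLERANCE = 0.5
DEFAULT_MIN_OVERLAP_FRAC = 0.3

__all__ = [
    "Detection",
    "UniqueCall",
    "AssignmentSummary",
    "match_across_tags",
    "assign_caller",
    "rl_difference_stats",
    "FOCAL",
    "NON_FOCAL",
    "INDETERMINATE",
]


@dataclass
class Detection:
    """One analyst (or simulator) call annotation on one tag."""

    detection_id: str
    tag_id: str
    t_start: float
    t_end: float
    f_low: Optional[float] = None
    f_high: Optional[float] = None
    noise_flag: bool = False
    rl: Optional[RLMeasurement] = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"{self.detection_id}: t_start must precede t_end "
                f"({self.t_start} >= {self.t_end})"
            )
        if self.f_low is not None and self.f_high is not None and not self.f_low < self.f_high:
            raise ValueError(f"{self.detection_id}: f_low must be below f_high")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def rl_db(self) -> Optional[float]:
        """Valid measured level (usable for RL statistics), or None."""
        if self.rl is not None and self.rl.valid:
            return self.rl.rl_db
        return None

    @property
    def assignment_level(self) -> Optional[float]:
        """Level usable for *relative* cross-tag comparison, or None.

        Includes overlap-contaminated measurements: when two calls overlap,
        every tag sees the same pair, so the ranking across tags still
        identifies the closest tag even though the absolute level is not a
        clean single-call RL.
        """
        if self.rl is None or not np.isfinite(self.rl.rl_db):
            return None
        if self.rl.valid or self.rl.invalid_reason in ("overlap_call", "clipped"):
            return self.rl.rl_db
        return None

    @property
    def is_clipped(self) -> bool:
        return self.rl is not None and self.rl.invalid_reason == "clipped"


@dataclass
class UniqueCall:
    """A cluster of detections across tags judged to be one physical call."""

    call_id: str
    detections: dict[str, Detection]  # tag_id -> detection (<=1 per tag)
    labels: dict[str, str] = field(default_factory=dict)  # tag_id -> label
    focal_tag: Optional[str] = None
    rl_difference: Optional[float] = None  # focal RL - loudest valid non-focal RL
    masked: bool = False  # masked-tag rule applied

    @property
    def multi_tag(self) -> bool:
        return len(self.detections) > 1

    @property
    def t_start(self) -> float:
        return min(d.t_start for d in self.detections.values())

    @property
    def indeterminate(self) -> bool:
        return bool(self.labels) and self.focal_tag is None


def _iter_detections(detections) -> list[Detection]:
    if isinstance(detections, Mapping):
        flat: list[Detection] = []
        for lst in detections.values():
            flat.extend(lst)
        return flat
    return list(detections)


def match_across_tags(
    detections,
    start_tolerance: float = DEFAULT_START_TOLERANCE,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> list[UniqueCall]:
    """Cluster per-tag detections into unique calls.

    Two detections on *different* tags are linked when their start times
    differ by at most ``start_tolerance`` seconds and their spans overlap by
    at least ``min_overlap_frac`` of the shorter span.  Clusters are the
    single-linkage connected components of that graph, with the constraint
    that a cluster never holds two detections from one tag: links are added
    strongest-first (smallest start-time difference), and a link whose
    addition would put two same-tag detections in one cluster is cut.

    ``detections`` may be a flat iterable or a mapping tag_id -> list.
    """
    dets = sorted(_iter_detections(detections), key=lambda d: (d.t_start, d.tag_id, d.detection_id))
    n = len(dets)
    edges: list[tuple[float, int, int]] = []
    for i in range(n):
        a = dets[i]
        for j in range(i + 1, n):
            b = dets[j]
            dt = b.t_start - a.t_start
            if dt > start_tolerance:
                break
            if b.tag_id == a.tag_id:
                continue
            overlap = min(a.t_end, b.t_end) - max(a.t_start, b.t_start)
            if overlap + 1e-12 >= min_overlap_frac * min(a.duration, b.duration):
                edges.append((abs(dt), i, j))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))

    parent = list(range(n))
    tags: list[set[str]] = [{d.tag_id} for d in dets]

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if tags[ri] & tags[rj]:
            continue  # would merge two same-tag detections: cut this weaker link
        parent[rj] = ri
        tags[ri] |= tags[rj]

    groups: dict[int, list[Detection]] = {}
    for i, det in enumerate(dets):
        groups.setdefault(find(i), []).append(det)
    clusters = sorted(groups.values(), key=lambda g: min(d.t_start for d in g))
    return [
        UniqueCall(call_id=f"uc{k:05d}", detections={d.tag_id: d for d in grp})
        for k, grp in enumerate(clusters)
    ]


def assign_caller(call: UniqueCall, delta_db: float = DEFAULT_DELTA_DB) -> UniqueCall:
    """Label one unique call focal / non-focal / indeterminate (in place).

    Rules, in priority order:

    * a call seen on only one tag is focal there (a non-focal call loud
      enough to be detected would also be detected on its own tag);
    * when every member but one carries the noise flag, the call is focal on
      the clean tag regardless of levels (masked-tag rule);
    * otherwise the tag with the highest usable level (clean, overlap-
      contaminated, or clipped - the latter only as a winning lower bound)
      is focal iff it beats the runner-up by at least ``delta_db``; with
      fewer than two usable levels, or a smaller gap, every member is
      indeterminate.
    """
    if not call.detections:
        raise ValueError("empty cluster")
    tags = sorted(call.detections)
    call.labels = {}
    call.focal_tag = None
    call.rl_difference = None
    call.masked = False

    if len(tags) == 1:
        call.focal_tag = tags[0]
        call.labels[tags[0]] = FOCAL
        return call

    unflagged = [t for t in tags if not call.detections[t].noise_flag]
    if len(unflagged) == 1:
        call.masked = True
        call.focal_tag = unflagged[0]
        for t in tags:
            call.labels[t] = FOCAL if t == unflagged[0] else NON_FOCAL
        return call

    levels = {
        t: call.detections[t].assignment_level
        for t in tags
        if call.detections[t].assignment_level is not None
    }
    if len(levels) >= 2:
        ordered = sorted(levels, key=lambda t: (-levels[t], t))
        top, second = ordered[0], ordered[1]
        # a clipped level understates the true one: it may win (its lower
        # bound already beats the rest) but a losing clipped member makes
        # the ranking unsafe
        losing_clipped = any(call.detections[t].is_clipped for t in ordered[1:])
        if levels[top] - levels[second] >= delta_db and not losing_clipped:
            call.focal_tag = top
            for t in tags:
                call.labels[t] = FOCAL if t == top else NON_FOCAL
            # the reported RL difference uses clean (valid) levels only
            valid = {t: call.detections[t].rl_db for t in tags if call.detections[t].rl_db is not None}
            if top in valid and len(valid) >= 2:
                call.rl_difference = valid[top] - max(valid[t] for t in valid if t != top)
            return call
    for t in tags:
        call.labels[t] = INDETERMINATE
    return call


@dataclass
class AssignmentSummary:
    """Bookkeeping over a set of assigned unique calls."""

    n_calls: int
    n_assigned: int
    n_indeterminate: int
    frac_assigned: float
    n_focal_detections: int
    n_nonfocal_detections: int
    n_indeterminate_detections: int
    n_multi_tag: int
    frac_multi_tag: float
    n_rl_pairs: int
    mean_rl_difference: float
    sd_rl_difference: float


def rl_difference_stats(calls: Sequence[UniqueCall]) -> AssignmentSummary:
    """Counts by label, multi-tag fraction, and focal-minus-non-focal dB stats.

    The RL-difference statistics are computed only over calls that have a
    focal tag and at least one valid non-focal RL (the pairs the difference
    is defined for); the counts partition the full call set.
    """
    n_calls = len(calls)
    n_assigned = sum(1 for c in calls if c.focal_tag is not None)
    n_multi = sum(1 for c in calls if c.multi_tag)
    label_counts = {FOCAL: 0, NON_FOCAL: 0, INDETERMINATE: 0}
    diffs: list[float] = []
    for c in calls:
        for lab in c.labels.values():
            label_counts[lab] += 1
        if c.rl_difference is not None:
            diffs.append(c.rl_difference)
    d = np.asarray(diffs, dtype=float)
    return AssignmentSummary(
        n_calls=n_calls,
        n_assigned=n_assigned,
        n_indeterminate=n_calls - n_assigned,
        frac_assigned=n_assigned / n_calls if n_calls else float("nan"),
        n_focal_detections=label_counts[FOCAL],
        n_nonfocal_detections=label_counts[NON_FOCAL],
        n_indeterminate_detections=label_counts[INDETERMINATE],
        n_multi_tag=n_multi,
        frac_multi_tag=n_multi / n_calls if n_calls else float("nan"),
        n_rl_pairs=d.size,
        mean_rl_difference=float(d.mean()) if d.size else float("nan"),
        sd_rl_difference=float(d.std(ddof=1)) if d.size > 1 else float("nan"),
    )
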