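"""Lineage reconstruction and division-synchrony morphokinetics.

The central quantities are per-blastomere cell-cycle durations grouped by
division round: the *second duration* is the lifetime of the two cells taking
the embryo from 2 to 4 cells, the *third duration* that of the four cells
taking it from 4 to 8, the *fourth duration* that of the eight cells taking
it from 8 to 16.  The within-embryo coefficient of variation (CV) of the
third durations is the synchrony index; embryos at or above the cutoff
(default 0.15) are classed as asynchronous ("high").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Default synchrony cutoff on the third-duration CV.
DEFAULT_CUTOFF = 0.15

#: Cell counts at which the embryo sits between division waves.
INTRA_STAGES = (2, 4, 8, 16, 32)
#: Count bands traversed while a division wave is in progress.
INTER_BANDS = ((3, 3), (5, 7), (9, 15), (17, 31))


class TrackingError(RuntimeError):
    """Raised when a recording cannot be turned into a consistent lineage."""


class IncompleteRoundError(ValueError):
    """Raised when a division round still contains undivided blastomeres."""


@dataclass
class CellNode:
    """One blastomere: a node of the lineage tree.

    ``round_index`` counts division rounds from 1 (zygote); the cells with
    round index ``r`` are the ones whose divisions take the embryo from
    ``2**(r-1)`` to ``2**r`` cells.
    """

    node_id: int
    parent_id: int | None
    round_index: int
    birth_time: float
    division_time: float | None = None

    @property
    def duration(self) -> float | None:
        if self.division_time is None:
            return None
        return self.division_time - self.birth_time


@dataclass
class LineageTree:
    """Rooted blastomere genealogy of one embryo."""

    embryo_id: str
    nodes: dict[int, CellNode] = field(default_factory=dict)

    def add(self, node: CellNode) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id}")
        if node.division_time is not None and node.division_time <= node.birth_time:
            raise ValueError("division_time must exceed birth_time")
        self.nodes[node.node_id] = node

    def children_of(self, node_id: int) -> list[CellNode]:
        return [n for n in self.nodes.values() if n.parent_id == node_id]

    def roots(self) -> list[CellNode]:
        return [n for n in self.nodes.values() if n.parent_id is None]

    def round_nodes(self, round_index: int) -> list[CellNode]:
        return sorted(
            (n for n in self.nodes.values() if n.round_index == round_index),
            key=lambda n: n.node_id,
        )

    def n_cells_at(self, t: float) -> int:
        """Number of live cells at time t (birth inclusive, division exclusive)."""
        return sum(
            1
            for n in self.nodes.values()
            if n.birth_time <= t and (n.division_time is None or n.division_time > t)
        )

    def validate(self) -> None:
        """Check the binary-division and time-consistency invariants."""
        for n in self.nodes.values():
            kids = self.children_of(n.node_id)
            if n.division_time is not None:
                if len(kids) != 2:
                    raise ValueError(
                        f"node {n.node_id} divided but has {len(kids)} children"
                    )
                for k in kids:
                    if not np.isclose(k.birth_time, n.division_time):
                        raise ValueError(
                            f"child {k.node_id} birth != parent {n.node_id} division"
                        )
            elif kids:
                raise ValueError(f"undivided node {n.node_id} has children")


# ---------------------------------------------------------------------------
# Track linking


def link_tracks(
    observations: pd.DataFrame,
    embryo_id: str | None = None,
    max_missing_frames: int = 2,
) -> LineageTree:
    """Reconstruct a lineage tree from per-frame centroid observations.

    Frame-to-frame correspondence is solved as an optimal one-to-one
    assignment on Euclidean distance (Hungarian algorithm).  A count increase
    spawns a division: each unmatched new centroid is attributed to the
    nearest active track, which is closed at the midpoint of the two frame
    times and replaced by two daughters.  A count decrease persisting more
    than ``max_missing_frames`` frames marks the embryo unanalyzable.

    Parameters
    ----------
    observations : DataFrame
        Tidy coordinate table with columns ``frame``, ``time_h``, ``x``,
        ``y``, ``z`` for a single embryo.
    """
    df = observations
    if embryo_id is None:
        ids = df["embryo_id"].unique()
        if len(ids) != 1:
            raise ValueError("observations must come from a single embryo")
        embryo_id = str(ids[0])
    frames = np.sort(df["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to link tracks")

    tree = LineageTree(embryo_id=embryo_id)
    next_id = 0

    def positions(fr: int) -> np.ndarray:
        sub = df[df["frame"] == fr]
        return sub[["x", "y", "z"]].to_numpy(dtype=float)

    frame_times = {
        int(fr): float(df.loc[df["frame"] == fr, "time_h"].iloc[0]) for fr in frames
    }

    # active tracks: node_id -> [position, n_consecutive_misses]
    active: dict[int, list] = {}
    t0 = frame_times[int(frames[0])]
    for pos in positions(frames[0]):
        tree.add(CellNode(next_id, None, 1, t0))
        active[next_id] = [pos, 0]
        next_id += 1

    for prev_fr, fr in zip(frames[:-1], frames[1:]):
        t_prev, t_cur = frame_times[int(prev_fr)], frame_times[int(fr)]
        cur = positions(fr)
        ids = list(active.keys())
        prev_pos = np.array([active[i][0] for i in ids])
        cost = cdist(prev_pos, cur)
        rows, cols = linear_sum_assignment(cost)
        matched_tracks = {}
        for r, c in zip(rows, cols):
            matched_tracks[ids[r]] = c

        unmatched_cur = [c for c in range(len(cur)) if c not in matched_tracks.values()]
        unmatched_tracks = [i for i in ids if i not in matched_tracks]

        # divisions: attribute each extra centroid to the track whose previous
        # position best matches the midpoint of the putative daughter pair
        # (the parent sat between its two daughters a moment ago)
        divided: set[int] = set()

        def _division_cost(i: int, c: int) -> float:
            # gain of the division hypothesis over plain continuation: a true
            # parent sits near the daughters' midpoint and far from either
            # daughter; a bystander loses nothing by staying put
            mid = 0.5 * (cur[matched_tracks[i]] + cur[c])
            continuation = np.linalg.norm(active[i][0] - cur[matched_tracks[i]])
            return float(np.linalg.norm(active[i][0] - mid) - continuation)

        for c in sorted(
            unmatched_cur,
            key=lambda c: min(np.linalg.norm(active[i][0] - cur[c]) for i in ids),
        ):
            candidates = [i for i in matched_tracks if i not in divided]
            if not candidates:
                raise TrackingError(
                    f"{embryo_id}: frame {fr}: more new objects than dividable tracks"
                )
            parent = min(candidates, key=lambda i: _division_cost(i, c))
            divided.add(parent)
            t_div = 0.5 * (t_prev + t_cur)
            pnode = tree.nodes[parent]
            pnode.division_time = t_div
            sib = matched_tracks.pop(parent)
            for col in (sib, c):
                tree.add(CellNode(next_id, parent, pnode.round_index + 1, t_div))
                active[next_id] = [cur[col], 0]
                next_id += 1
            del active[parent]

        for i, c in matched_tracks.items():
            active[i] = [cur[c], 0]
        for i in unmatched_tracks:
            active[i][1] += 1
            if active[i][1] > max_missing_frames:
                raise TrackingError(
                    f"{embryo_id}: object lost for more than "
                    f"{max_missing_frames} frames at frame {fr}"
                )
    logger.info("%s: linked %d nodes over %d frames", embryo_id, next_id, len(frames))
    return tree


def lineage_to_frame(tree: LineageTree) -> pd.DataFrame:
    """Flatten a lineage tree into a tidy node table."""
    rows = [
        (tree.embryo_id, n.node_id, n.parent_id, n.round_index, n.birth_time,
         n.division_time)
        for n in sorted(tree.nodes.values(), key=lambda n: n.node_id)
    ]
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "node_id", "parent_id", "round", "birth_h", "division_h"],
    )


# ---------------------------------------------------------------------------
# Count curves and stage durations


@dataclass
class CountCurve:
    """Cell-count trajectory aligned to the first mitosis (t = 0)."""

    times: np.ndarray
    raw_counts: np.ndarray
    cleaned_counts: np.ndarray


def _clean_counts(raw: np.ndarray) -> np.ndarray:
    """Remove single-frame dips and spikes, then enforce monotonicity.

    Counts only ever increase, so a one-frame decrease is a missed detection:
    frames strictly below both neighbours are lifted to the lower neighbour
    first.  A one-frame increase that immediately reverts is a false
    detection: frames still strictly above both neighbours are then pulled
    down.  A running maximum finally makes the curve non-decreasing.
    """
    c = raw.astype(int).copy()
    for i in range(1, len(c) - 1):
        lo = min(c[i - 1], c[i + 1])
        if c[i] < lo:
            c[i] = lo
    for i in range(1, len(c) - 1):
        hi = max(c[i - 1], c[i + 1])
        if c[i] > hi:
            c[i] = hi
    return np.maximum.accumulate(c)


def count_curve(source) -> CountCurve:
    """Build the aligned count curve from observations or a lineage tree.

    Times are shifted so the first (persistent) 1→2 transition is t = 0.
    """
    if isinstance(source, LineageTree):
        times = sorted(
            {n.birth_time for n in source.nodes.values()}
            | {n.division_time for n in source.nodes.values() if n.division_time}
        )
        times = np.asarray(times, dtype=float)
        raw = np.array([source.n_cells_at(t) for t in times])
    else:
        grouped = source.groupby("frame")
        times = grouped["time_h"].first().to_numpy(dtype=float)
        raw = grouped.size().to_numpy()
        order = np.argsort(times)
        times, raw = times[order], raw[order]

    cleaned = _clean_counts(np.asarray(raw))
    above = np.nonzero(cleaned >= 2)[0]
    if len(above) == 0 or above[0] == 0:
        raise ValueError("first mitosis not observed")
    t0 = times[above[0]]
    return CountCurve(times=times - t0, raw_counts=np.asarray(raw), cleaned_counts=cleaned)


@dataclass
class StageDurations:
    """Time spent at each plateau count (intra) and in between (inter)."""

    intra: dict[int, float]
    inter: dict[str, float]
    incomplete: set = field(default_factory=set)


def stage_durations(curve: CountCurve) -> StageDurations:
    """Intra-/inter-stage residence times from a cleaned monotone curve.

    The count is piecewise constant: it holds its value from one frame until
    the next.  Intra duration for stage *s* is the total time the count
    equals *s*; inter duration for a band is the total time the count lies
    inside the band.  Stages the recording never exits are reported but
    flagged incomplete.
    """
    t = curve.times
    c = curve.cleaned_counts
    if np.any(np.diff(c) < 0):
        raise ValueError("cleaned curve must be monotone non-decreasing")
    seg = np.diff(t)
    max_count = int(c[-1])

    def residence(lo: int, hi: int) -> float:
        inside = (c[:-1] >= lo) & (c[:-1] <= hi)
        return float(seg[inside].sum())

    intra: dict[int, float] = {}
    inter: dict[str, float] = {}
    incomplete: set = set()
    for s in INTRA_STAGES:
        if max_count < s:
            continue
        intra[s] = residence(s, s)
        if max_count == s:
            incomplete.add(s)
    for lo, hi in INTER_BANDS:
        name = str(lo) if lo == hi else f"{lo}-{hi}"
        if max_count < lo:
            continue
        inter[name] = residence(lo, hi)
        if max_count <= hi:
            incomplete.add(name)
    return StageDurations(intra=intra, inter=inter, incomplete=incomplete)


# ---------------------------------------------------------------------------
# Division durations and synchrony statistics


def division_durations(tree: LineageTree, round_index: int) -> list[float]:
    """Per-blastomere cell-cycle times for one division round (hours).

    Round 2 gives the two second durations, round 3 the four third
    durations, round 4 the eight fourth durations.
    """
    nodes = tree.round_nodes(round_index)
    if not nodes:
        raise IncompleteRoundError(f"no cells in round {round_index}")
    undivided = [n.node_id for n in nodes if n.division_time is None]
    if undivided:
        raise IncompleteRoundError(
            f"round {round_index} incomplete; undivided nodes: {undivided}"
        )
    return [float(n.duration) for n in nodes]


def second_diff_norm(durations) -> float:
    """Normalized second-duration difference |d1 - d2| / mean(d1, d2)."""
    d = np.asarray(durations, dtype=float)
    if d.shape != (2,):
        raise ValueError("expected exactly two second durations")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return float(abs(d[0] - d[1]) / d.mean())


def duration_cv(durations) -> float:
    """Coefficient of variation (sample SD / mean) of a duration list."""
    d = np.asarray(durations, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 durations")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return float(d.std(ddof=1) / d.mean())


def classify_synchrony(third_cv: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Class label: 'high' (asynchronous) iff third CV >= cutoff, else 'low'."""
    if third_cv < 0:
        raise ValueError("CV must be non-negative")
    return "high" if third_cv >= cutoff else "low"


@dataclass
class SynchronyProfile:
    """Per-embryo division-asynchrony summary."""

    embryo_id: str
    second_diff_norm: float
    third_cv: float
    fourth_cv: float | None
    synchrony_class: str
    cutoff: float = DEFAULT_CUTOFF


def synchrony_profile(
    tree: LineageTree, cutoff: float = DEFAULT_CUTOFF, require_fourth: bool = False
) -> SynchronyProfile:
    """Compute the synchrony statistics of one embryo from its lineage."""
    second = division_durations(tree, 2)
    third = division_durations(tree, 3)
    try:
        fourth_cv = duration_cv(division_durations(tree, 4))
    except IncompleteRoundError:
        if require_fourth:
            raise
        fourth_cv = None
    third_cv = duration_cv(third)
    return SynchronyProfile(
        embryo_id=tree.embryo_id,
        second_diff_norm=second_diff_norm(second),
        third_cv=third_cv,
        fourth_cv=fourth_cv,
        synchrony_class=classify_synchrony(third_cv, cutoff),
        cutoff=cutoff,
    )
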