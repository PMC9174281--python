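"""Shape and motility descriptors computed from nucleus coordinates.

Three per-frame descriptors of the blastomere arrangement:

- ``distance_cv`` — CV of the nucleus-to-barycenter distances (radial
  shape regularity; scale- and rotation-invariant);
- ``motility`` — summed matched nucleus displacement per unit time;
- ``procrustes_distance`` — full Procrustes distance between two
  configurations after optimal translation, scaling and (proper) rotation,
  with landmark correspondence resolved exhaustively for small point sets.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


def distance_cv(points) -> float:
    """CV of the distances from each nucleus to the frame's barycenter.

    All points coincident (zero mean distance) is defined as 0.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or len(p) < 2:
        raise ValueError("need at least 2 points")
    d = np.linalg.norm(p - p.mean(axis=0), axis=1)
    if d.mean() == 0:
        return 0.0
    return float(d.std(ddof=1) / d.mean())


def motility(frame_a, frame_b, dt: float) -> float:
    """Summed matched displacement magnitude per hour between two frames.

    Points are matched one-to-one by optimal assignment on Euclidean
    distance; unmatched points (count change across a division) are
    excluded.  Not rigid-motion invariant, by design.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both frames must contain points")
    cost = cdist(a, b)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() / dt)


def _preshape(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=0)
    s = np.linalg.norm(c)
    if s == 0:
        raise ValueError("degenerate (all-coincident) shape")
    return c / s


def _procrustes_given(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance for corresponding landmark rows.

    Proper rotations only (no reflection): the smallest singular value of the
    cross-covariance takes the sign of its determinant.
    """
    A, B = _preshape(a), _preshape(b)
    u, s, vt = np.linalg.svd(B.T @ A)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0] * (len(s) - 1) + [d]) @ vt
    scale = s[:-1].sum() + d * s[-1]  # optimal scale for unit-norm preshapes
    # residual computed directly: stable for near-identical shapes, where
    # sqrt(1 - trace^2) loses half the significant digits to cancellation
    return float(np.linalg.norm(A - scale * (B @ rot)))


def _procrustes_exhaustive(a: np.ndarray, b: np.ndarray) -> float:
    """Minimize the distance over every landmark permutation.

    The winning permutation is found with a batched SVD on the achievable
    superposition traces; the distance itself is then recomputed stably.
    """
    A, B = _preshape(a), _preshape(b)
    perms = np.array(list(permutations(range(len(a)))))
    M = np.einsum("ni,pnj->pij", A, B[perms])
    u, s, vt = np.linalg.svd(M)
    sign = np.sign(np.linalg.det(u @ vt))
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    best = perms[int(np.argmax(trace))]
    return _procrustes_given(a, b[best, :])


def _greedy_correspondence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nearest-landmark correspondence on the preshapes (for large n)."""
    A, B = _preshape(a), _preshape(b)
    cost = cdist(A, B)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(a), dtype=int)
    perm[rows] = cols
    return perm


def procrustes_distance(
    shape_a, shape_b, correspondence: str = "auto", max_exhaustive: int = 8
) -> float:
    """Full Procrustes distance between two nucleus configurations.

    Nuclei carry no labels, so unless ``correspondence="given"`` the
    landmark pairing is unknown: for n ≤ ``max_exhaustive`` the distance is
    minimized over all permutations (exhaustive); for larger n a greedy
    nearest-landmark assignment initializes the pairing.
    """
    a = np.asarray(shape_a, dtype=float)
    b = np.asarray(shape_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shapes must have equal point counts and dimension")
    if len(a) < 3:
        raise ValueError("need at least 3 landmarks")
    if correspondence == "given":
        return _procrustes_given(a, b)
    if correspondence == "greedy" or len(a) > max_exhaustive:
        return _procrustes_given(a, b[_greedy_correspondence(a, b), :])
    return _procrustes_exhaustive(a, b)


def morphometric_series(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-frame morphometrics for one embryo's coordinate table.

    Motility and Procrustes distance are computed against the previous
    frame; the Procrustes entry is NaN at count changes (no landmark
    correspondence across a division) and for frames with < 3 nuclei.
    """
    ids = observations["embryo_id"].unique()
    if len(ids) != 1:
        raise ValueError("observations must come from a single embryo")
    rows = []
    prev_pts, prev_t = None, None
    for fr in np.sort(observations["frame"].unique()):
        sub = observations[observations["frame"] == fr]
        pts = sub[["x", "y", "z"]].to_numpy(dtype=float)
        t = float(sub["time_h"].iloc[0])
        bary = pts.mean(axis=0)
        dcv = distance_cv(pts) if len(pts) >= 2 else np.nan
        mot = np.nan
        pro = np.nan
        if prev_pts is not None and t > prev_t:
            mot = motility(prev_pts, pts, t - prev_t)
            if len(pts) == len(prev_pts) >= 3:
                try:
                    # consecutive frames are near-identical configurations, so
                    # greedy nearest-landmark correspondence is reliable and fast
                    pro = procrustes_distance(prev_pts, pts, correspondence="greedy")
                except ValueError:
                    pro = np.nan
        rows.append((str(ids[0]), int(fr), t, *bary, dcv, mot, pro))
        prev_pts, prev_t = pts, t
    return pd.DataFrame(
        rows,
        columns=[
            "embryo_id",
            "frame",
            "time_h",
            "bary_x",
            "bary_y",
            "bary_z",
            "distance_cv",
            "motility",
            "procrustes_distance",
        ],
    )
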