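"""Synthetic preimplantation-embryo generator.

Produces ground-truth lineages with controllable per-round division
asynchrony, confined nucleus trajectories inside a spherical embryo, and
rendered 4D fluorescence stacks (Gaussian nuclei, depth attenuation,
anisotropic voxel sampling, additive noise).  Every downstream stage of the
pipeline — detection, tracking, synchrony statistics, outcome statistics —
can therefore be exercised against known truth without any external data.

Units: durations in hours, lengths in µm internally; emitted observation
coordinates are in isotropic units (1 unit = dx, z pre-scaled by dz/dx) so
they line up voxel-for-voxel with rendered stacks and detected centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .lineage import CellNode, LineageTree, division_durations, duration_cv
from .types import DEFAULT_SPACING, VoxelGrid


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a mouse preimplantation time-lapse: 10-min frame
    interval, 0.8/0.8/2.0 µm voxels, ~30 µm embryo radius, cell-cycle means
    near 17/14/12/11/10 h for rounds 1-5.
    """

    n_embryos: int = 20
    round_mean_duration: tuple = (17.0, 14.0, 12.0, 11.0, 10.0)
    round_cv: tuple = (0.05, 0.05, 0.10, 0.10, 0.10)
    n_rounds: int = 5
    embryo_radius: float = 30.0
    nucleus_radius: float = 5.0
    motion_step_sd: float = 0.5
    frame_interval: float = 1.0 / 6.0  # 10-min frames
    psf_sigma: float = 3.0
    noise_sd: float = 0.05
    z_attenuation: float = 0.01  # per µm depth
    voxel_spacing: tuple = DEFAULT_SPACING
    grid_shape: tuple = (64, 128, 128)  # (nz, ny, nx)
    # outcome rule: P(abort) = logistic(slope * (third CV - center))
    abort_cv_center: float = 0.15
    abort_cv_slope: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_rounds <= len(self.round_mean_duration):
            raise ValueError("n_rounds out of range for round_mean_duration")
        if any(m <= 0 for m in self.round_mean_duration):
            raise ValueError("round mean durations must be strictly positive")
        if any(cv < 0 for cv in self.round_cv):
            raise ValueError("round CVs must be non-negative")
        if self.embryo_radius <= 0 or self.nucleus_radius <= 0:
            raise ValueError("radii must be strictly positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be strictly positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if self.motion_step_sd < 0 or self.noise_sd < 0 or self.z_attenuation < 0:
            raise ValueError("noise/motion/attenuation must be non-negative")

    @property
    def anisotropy(self) -> float:
        return self.voxel_spacing[2] / self.voxel_spacing[0]


@dataclass
class GroundTruth:
    """Everything the generator knows about one synthetic embryo."""

    embryo_id: str
    lineage: LineageTree
    observations: pd.DataFrame  # true centroids, isotropic units
    true_round_cvs: dict  # realized sample CV per round, from the lineage
    outcome: str  # "born" | "abort"


def _embryo_rng(config: SimulationConfig, embryo_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, embryo_index, stream])


def _lognormal_durations(
    mean: float, cv: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n durations from the log-normal with the given mean and CV."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def simulate_lineage(config: SimulationConfig, embryo_index: int = 0) -> LineageTree:
    """Draw one embryo's lineage tree down to 2**n_rounds terminal cells.

    Each blastomere's cell-cycle duration is log-normal with its round's
    mean and CV; daughters are born at the instant the parent divides.
    """
    rng = _embryo_rng(config, embryo_index, 0)
    tree = LineageTree(embryo_id=f"sim{embryo_index:03d}")
    next_id = 0
    tree.add(CellNode(next_id, None, 1, 0.0))
    frontier = [next_id]
    next_id += 1
    for r in range(1, config.n_rounds + 1):
        durations = _lognormal_durations(
            config.round_mean_duration[r - 1], config.round_cv[r - 1], len(frontier), rng
        )
        new_frontier = []
        for node_id, dur in zip(frontier, durations):
            node = tree.nodes[node_id]
            node.division_time = node.birth_time + float(dur)
            for _ in range(2):
                tree.add(CellNode(next_id, node_id, r + 1, node.division_time))
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return tree


def _reflect_into_sphere(p: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point back inside a sphere centred at the origin."""
    r = np.linalg.norm(p)
    if r <= radius:
        return p
    reflected = 2 * radius - r
    if reflected < 0:  # pathological jump: clamp just inside
        reflected = 0.9 * radius
    return p * (reflected / r)


def simulate_trajectories(
    tree: LineageTree,
    config: SimulationConfig,
    embryo_index: int = 0,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Confined random-walk trajectories for every living cell, per frame.

    Motion is an isotropic Gaussian step (``motion_step_sd`` µm per frame)
    reflected at the embryo-sphere boundary; at a division the parent
    position spawns two daughters separated by one nucleus diameter along a
    uniformly random axis.  Output coordinates are in isotropic units in the
    rendering grid frame.
    """
    rng = _embryo_rng(config, embryo_index, 1)
    if t_end is None:
        div_times = [n.division_time for n in tree.nodes.values() if n.division_time]
        t_end = (max(div_times) if div_times else 0.0) + 2 * config.frame_interval
    n_frames = int(np.floor(t_end / config.frame_interval)) + 1

    dx, dy, dz = config.voxel_spacing
    nz, ny, nx = config.grid_shape
    center = np.array([(nx - 1) / 2 * dx, (ny - 1) / 2 * dy, (nz - 1) / 2 * dz])
    sep = 2 * config.nucleus_radius
    confine_r = max(config.embryo_radius - config.nucleus_radius, config.nucleus_radius)

    roots = tree.roots()
    pos = {n.node_id: np.zeros(3) for n in roots}  # embryo-centred µm

    events = sorted(
        ((n.division_time, n.node_id) for n in tree.nodes.values() if n.division_time),
        key=lambda e: e[0],
    )
    ev = 0
    rows = []
    for k in range(n_frames):
        t = k * config.frame_interval
        # apply divisions that happened since the previous frame
        while ev < len(events) and events[ev][0] <= t:
            _, parent = events[ev]
            ev += 1
            if parent not in pos:
                continue
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            kids = tree.children_of(parent)
            offsets = (axis * sep / 2, -axis * sep / 2)
            for kid, off in zip(kids, offsets):
                pos[kid.node_id] = _reflect_into_sphere(pos[parent] + off, confine_r)
            del pos[parent]
        # random-walk step
        if k > 0 and config.motion_step_sd > 0:
            for nid in list(pos):
                step = rng.normal(scale=config.motion_step_sd, size=3)
                pos[nid] = _reflect_into_sphere(pos[nid] + step, confine_r)
        for nid in sorted(pos):
            p = pos[nid] + center  # grid-frame µm
            rows.append(
                (
                    tree.embryo_id,
                    k,
                    t,
                    p[0] / dx,
                    p[1] / dx,
                    p[2] / dz * config.anisotropy,  # = p_z/dx: pre-scaled z
                    0.0,
                    nid,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "frame", "time_h", "x", "y", "z", "volume_voxels", "label"],
    )


def render_frame(
    observations: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    frame_index: int = 0,
    time: float = 0.0,
) -> VoxelGrid:
    """Render one frame's observations into an anisotropic voxel grid.

    Each nucleus contributes an isotropic Gaussian blob (sigma = psf_sigma
    µm, unit peak) sampled on the voxel lattice, multiplied by exponential
    depth attenuation exp(-z_attenuation × depth µm); Gaussian noise is then
    added and the volume clipped at zero.
    """
    nz, ny, nx = config.grid_shape
    dx, dy, dz = config.voxel_spacing
    vol = np.zeros((nz, ny, nx))
    sig_x, sig_y, sig_z = config.psf_sigma / dx, config.psf_sigma / dy, config.psf_sigma / dz
    half = 4.0
    for row in observations.itertuples(index=False):
        cx, cy = float(row.x), float(row.y)
        cz = float(row.z) / config.anisotropy  # back to slice index
        zl, zh = max(0, int(cz - half * sig_z)), min(nz, int(cz + half * sig_z) + 2)
        yl, yh = max(0, int(cy - half * sig_y)), min(ny, int(cy + half * sig_y) + 2)
        xl, xh = max(0, int(cx - half * sig_x)), min(nx, int(cx + half * sig_x) + 2)
        if zl >= zh or yl >= yh or xl >= xh:
            continue
        zg, yg, xg = np.ogrid[zl:zh, yl:yh, xl:xh]
        blob = np.exp(
            -0.5 * (((zg - cz) / sig_z) ** 2 + ((yg - cy) / sig_y) ** 2 + ((xg - cx) / sig_x) ** 2)
        )
        vol[zl:zh, yl:yh, xl:xh] += blob
    if config.z_attenuation > 0:
        depth = np.arange(nz) * dz
        vol *= np.exp(-config.z_attenuation * depth)[:, None, None]
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        vol += rng.normal(scale=config.noise_sd, size=vol.shape)
    np.clip(vol, 0, None, out=vol)
    return VoxelGrid(vol, spacing=config.voxel_spacing, time=time, frame_index=frame_index)


def render_stack(
    observations: pd.DataFrame, config: SimulationConfig, embryo_index: int = 0
) -> list[VoxelGrid]:
    """Render every frame of a trajectory table; noise seeded per embryo."""
    rng = _embryo_rng(config, embryo_index, 2)
    out = []
    for fr in np.sort(observations["frame"].unique()):
        sub = observations[observations["frame"] == fr]
        t = float(sub["time_h"].iloc[0])
        out.append(render_frame(sub, config, rng=rng, frame_index=int(fr), time=t))
    return out


def true_round_cvs(tree: LineageTree, max_round: int = 4) -> dict:
    """Realized sample CV of each round's durations, recomputed from the tree."""
    cvs = {}
    for r in range(2, max_round + 1):
        try:
            cvs[r] = duration_cv(division_durations(tree, r))
        except Exception:
            break
    return cvs


def assign_outcome(
    third_cv: float, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """Draw a born/abort label: P(abort) logistic in the realized third CV."""
    p_abort = expit(config.abort_cv_slope * (third_cv - config.abort_cv_center))
    return "abort" if rng.random() < p_abort else "born"


def simulate_embryo(config: SimulationConfig, embryo_index: int) -> GroundTruth:
    """Lineage + trajectories + outcome label for one synthetic embryo."""
    tree = simulate_lineage(config, embryo_index)
    obs = simulate_trajectories(tree, config, embryo_index)
    cvs = true_round_cvs(tree, max_round=min(4, config.n_rounds))
    rng = _embryo_rng(config, embryo_index, 3)
    outcome = assign_outcome(cvs.get(3, 0.0), config, rng)
    return GroundTruth(
        embryo_id=tree.embryo_id,
        lineage=tree,
        observations=obs,
        true_round_cvs=cvs,
        outcome=outcome,
    )


def simulate_cohort(config: SimulationConfig) -> list[GroundTruth]:
    """Simulate the full synthetic cohort (deterministic under config.seed)."""
    return [simulate_embryo(config, i) for i in range(config.n_embryos)]


def config_for_cv(config: SimulationConfig, third_cv: float) -> SimulationConfig:
    """Copy of config with the third-round CV replaced (rounds are 1-based)."""
    cv = list(config.round_cv)
    cv[2] = third_cv
    return replace(config, round_cv=tuple(cv))
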