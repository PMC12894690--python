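"""Synthetic phantom cohorts for perfusion-deficit inference.

Real CT/CTA stroke cohorts are not redistributable, so every downstream
stage is exercised on phantoms that reproduce the statistical structure the
method assumes: a contrast-filled branching vascular tree rendered into an
aligned CT/CTA pair, occlusion of a branch removing contrast from its entire
downstream subtree (hypoperfusion), a planted spatial substrate, and ordinal
deficit scores generated as noisy dot products between the substrate and
each patient's perfusion map.

The generative model is deliberately simple — additive Gaussian noise,
tube-rasterised vessels, recursive branching with a fixed radius decay —
but it produces the correlated, tree-structured perfusion patterns that
make mass-univariate lesion-deficit mapping unreliable, which is the regime
the variational model is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .cpm import AlignedScanPair, CpmConfig, compute_cpm

__all__ = [
    "PhantomConfig",
    "VascularTree",
    "SyntheticPatient",
    "generate_vascular_tree",
    "generate_symmetric_tree",
    "render_scan_pair",
    "apply_occlusion",
    "plant_substrate",
    "raw_scores",
    "simulate_scores",
    "generate_cohort",
]

RADIUS_DECAY = 0.8        # per-generation vessel taper
LENGTH_DECAY = 0.75
TERRITORY_DILATION = 2    # voxels; hypoperfusion extends beyond the lumen


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_branches: int = 15
    branch_angle_spread: float = 0.6  # radians
    contrast_level: float = 1.0
    noise_sd: float = 0.02
    background_level: float = 0.3
    root_radius: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.contrast_level <= 0:
            raise ValueError("contrast_level must be > 0")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")


@dataclass
class VascularTree:
    """Branching centreline geometry with per-edge radii.

    ``nodes`` are continuous voxel coordinates; ``edges[i] = (parent_node,
    child_node)``; ``radii[i]`` is edge i's tube radius in voxels.  The tree
    is connected and acyclic with a single inflow root, and radii taper
    monotonically from parent to child.
    """

    nodes: np.ndarray
    edges: list[tuple[int, int]]
    radii: np.ndarray
    root: int
    grid_shape: tuple[int, int, int]
    edge_voxels: list[np.ndarray] = field(default_factory=list, repr=False)

    def children_of_edge(self, edge_id: int) -> list[int]:
        _, child_node = self.edges[edge_id]
        return [i for i, (p, _) in enumerate(self.edges) if p == child_node]

    def downstream_edges(self, edge_id: int) -> set[int]:
        """The edge itself plus every edge in its downstream subtree."""
        out = {edge_id}
        stack = [edge_id]
        while stack:
            for ch in self.children_of_edge(stack.pop()):
                if ch not in out:
                    out.add(ch)
                    stack.append(ch)
        return out

    def vessel_field(self, exclude_edges: set[int] | None = None) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        for i, vox in enumerate(self.edge_voxels):
            if exclude_edges and i in exclude_edges:
                continue
            if len(vox):
                mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        return mask


def _tube_voxels(p0: np.ndarray, p1: np.ndarray, radius: float, shape) -> np.ndarray:
    """Voxel centres within `radius` of the segment p0-p1 (point-to-segment)."""
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=np.intp)
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=1)
    else:
        t = np.clip((pts - p0) @ d / len2, 0.0, 1.0)
        dist = np.linalg.norm(pts - (p0 + t[:, None] * d), axis=1)
    return pts[dist <= radius].astype(np.intp)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate_towards(direction: np.ndarray, polar: float, azimuth: float) -> np.ndarray:
    """Tilt `direction` by angle `polar`, around it at angle `azimuth`."""
    d = _unit(direction)
    # build an orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, a))
    v = np.cross(d, u)
    return _unit(
        np.cos(polar) * d
        + np.sin(polar) * (np.cos(azimuth) * u + np.sin(azimuth) * v)
    )


def generate_vascular_tree(
    config: PhantomConfig,
) -> tuple[VascularTree, np.ndarray]:
    """Grow a branching tree by breadth-first bifurcation and rasterise it.

    The root enters from the centre of the bottom face; each branch spawns
    two children tilted by angles drawn within ``branch_angle_spread``, with
    radius tapered by ``RADIUS_DECAY`` per generation.  Breadth-first growth
    guarantees maximal generation depth for a given branch budget.
    Deterministic given ``config.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0]))
    shape = np.asarray(config.grid_shape)
    margin = 1.0
    if np.any(shape < 2 * config.root_radius + 4):
        raise ValueError(
            f"grid {tuple(shape)} too small for root radius {config.root_radius}"
        )
    root_pt = np.array([shape[0] / 2.0, shape[1] / 2.0, margin])
    root_dir = np.array([0.0, 0.0, 1.0])
    root_len = shape[2] / 4.0

    nodes = [root_pt]
    edges: list[tuple[int, int]] = []
    radii: list[float] = []
    # queue entries: (start node idx, direction, radius, length)
    queue: list[tuple[int, np.ndarray, float, float]] = [
        (0, root_dir, config.root_radius, root_len)
    ]
    while queue and len(edges) < config.n_branches:
        start, direction, radius, length = queue.pop(0)
        end = nodes[start] + direction * length
        end = np.clip(end, margin, shape - 1 - margin)
        nodes.append(end)
        child_idx = len(nodes) - 1
        edges.append((start, child_idx))
        radii.append(radius)
        for _ in range(2):
            polar = rng.uniform(0.3, 1.0) * config.branch_angle_spread
            azimuth = rng.uniform(0.0, 2.0 * np.pi)
            queue.append(
                (
                    child_idx,
                    _rotate_towards(direction, polar, azimuth),
                    radius * RADIUS_DECAY,
                    length * LENGTH_DECAY,
                )
            )
    tree = VascularTree(
        nodes=np.asarray(nodes),
        edges=edges,
        radii=np.asarray(radii),
        root=0,
        grid_shape=config.grid_shape,
    )
    tree.edge_voxels = [
        _tube_voxels(tree.nodes[p], tree.nodes[c], r, shape)
        for (p, c), r in zip(tree.edges, tree.radii)
    ]
    return tree, tree.vessel_field()


def generate_symmetric_tree(
    config: PhantomConfig,
) -> tuple[VascularTree, np.ndarray]:
    """A mirror-symmetric tree: a midplane root trunk plus two reflected halves.

    Grows one lateral half-tree hanging off the root trunk, then reflects it
    about the mid-sagittal plane of axis 0.  Used to test that the perfusion
    pipeline produces no left/right arrival-time asymmetry in the absence of
    an occlusion.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 7]))
    shape = np.asarray(config.grid_shape)
    cx = (shape[0] - 1) / 2.0
    margin = 1.0
    root_pt = np.array([cx, shape[1] / 2.0, margin])
    trunk_end = np.array([cx, shape[1] / 2.0, shape[2] / 3.0])

    nodes = [root_pt, trunk_end]
    edges: list[tuple[int, int]] = [(0, 1)]
    radii: list[float] = [config.root_radius]

    # grow one half-tree, biased towards +x, from the trunk end
    half_budget = max(1, (config.n_branches - 1) // 2)
    first_dir = _unit(np.array([0.8, 0.0, 0.6]))
    queue = [(1, first_dir, config.root_radius * RADIUS_DECAY, shape[2] / 4.0)]
    half_edges: list[int] = []
    while queue and len(half_edges) < half_budget:
        start, direction, radius, length = queue.pop(0)
        end = nodes[start] + direction * length
        end = np.clip(end, margin, shape - 1 - margin)
        end[0] = np.clip(end[0], cx + 1.0, shape[0] - 1 - margin)  # stay lateral
        nodes.append(end)
        child_idx = len(nodes) - 1
        edges.append((start, child_idx))
        radii.append(radius)
        half_edges.append(len(edges) - 1)
        for _ in range(2):
            polar = rng.uniform(0.3, 1.0) * config.branch_angle_spread
            azimuth = rng.uniform(0.0, 2.0 * np.pi)
            queue.append(
                (
                    child_idx,
                    _rotate_towards(direction, polar, azimuth),
                    radius * RADIUS_DECAY,
                    length * LENGTH_DECAY,
                )
            )
    # reflect the half-tree about x = cx
    node_map = {0: 0, 1: 1}
    for eid in half_edges:
        p, c = edges[eid]
        mirrored = nodes[c].copy()
        mirrored[0] = 2 * cx - mirrored[0]
        nodes.append(mirrored)
        node_map[c] = len(nodes) - 1
        edges.append((node_map[p], node_map[c]))
        radii.append(radii[eid])

    tree = VascularTree(
        nodes=np.asarray(nodes),
        edges=edges,
        radii=np.asarray(radii),
        root=0,
        grid_shape=config.grid_shape,
    )
    tree.edge_voxels = [
        _tube_voxels(tree.nodes[p], tree.nodes[c], r, shape)
        for (p, c), r in zip(tree.edges, tree.radii)
    ]
    return tree, tree.vessel_field()


def render_scan_pair(
    tree: VascularTree,
    config: PhantomConfig,
    occluded_edges: set[int] | None = None,
) -> AlignedScanPair:
    """Render the tree into an aligned CT/CTA pair.

    CT is background plus a smooth parenchymal texture plus Gaussian noise;
    CTA adds ``contrast_level`` inside every non-occluded vessel voxel plus
    independent acquisition noise.  Occluded branches carry no contrast —
    the imaging signature of a proximal occlusion.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    shape = config.grid_shape
    texture = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    texture *= 0.05 / max(texture.std(), 1e-12)
    ct = config.background_level + texture
    if config.noise_sd > 0:
        ct = ct + rng.normal(0.0, config.noise_sd, shape)
    vessels = tree.vessel_field(exclude_edges=occluded_edges)
    cta = ct + config.contrast_level * vessels
    if config.noise_sd > 0:
        cta = cta + rng.normal(0.0, config.noise_sd, shape)
    return AlignedScanPair(ct=ct, cta=cta)


def apply_occlusion(
    tree: VascularTree, edge_id: int
) -> tuple[set[int], np.ndarray]:
    """Occlude an edge and everything downstream of it.

    Returns the occluded edge set and the hypoperfused territory mask: the
    union of the subtree's tubes dilated by ``TERRITORY_DILATION`` voxels,
    since tissue at risk extends beyond the lumen itself.  Occluding the
    root marks the entire tree.
    """
    if not 0 <= edge_id < len(tree.edges):
        raise ValueError(f"edge_id {edge_id} out of range")
    occluded = tree.downstream_edges(edge_id)
    tubes = np.zeros(tree.grid_shape, dtype=bool)
    for eid in occluded:
        vox = tree.edge_voxels[eid]
        if len(vox):
            tubes[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    territory = binary_dilation(tubes, iterations=TERRITORY_DILATION)
    return occluded, territory


def plant_substrate(
    grid_shape: tuple[int, int, int],
    regions: list[tuple[tuple[float, float, float], float, float]],
) -> np.ndarray:
    """Ground-truth substrate: a sum of weighted balls.

    ``regions`` is a list of (center, radius, weight); overlapping balls sum.
    A radius-0 ball contributes a single voxel (its rounded centre).
    """
    sub = np.zeros(grid_shape, dtype=np.float64)
    if not regions:
        return sub
    idx = np.indices(grid_shape).reshape(3, -1).T.astype(np.float64)
    for center, radius, weight in regions:
        center = np.asarray(center, dtype=np.float64)
        if np.any(center < 0) or np.any(center >= np.asarray(grid_shape)):
            raise ValueError(f"substrate centre {tuple(center)} outside grid")
        dist = np.linalg.norm(idx - center, axis=1)
        inside = dist <= radius
        if not inside.any():  # radius-0: nearest single voxel
            inside = np.zeros(len(idx), dtype=bool)
            inside[np.argmin(dist)] = True
        sub.ravel()[inside] += weight
    return sub


def raw_scores(cpms: list[np.ndarray], substrate: np.ndarray) -> np.ndarray:
    """Noiseless raw deficit per patient: the substrate-CPM dot product."""
    for c in cpms:
        if c.shape != substrate.shape:
            raise ValueError("CPM and substrate grids differ")
    return np.array([float(np.sum(substrate * c)) for c in cpms])


def simulate_scores(
    cpms: list[np.ndarray],
    substrate: np.ndarray,
    noise_sd: float = 0.0,
    levels: int = 5,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinal deficit scores from noisy dot products, quantile-binned.

    Raw score = sum_v substrate_v * cpm_v + Gaussian noise; the cohort's raw
    scores are then discretised into ``levels`` ordinal bins {0..levels-1}
    by cohort quantiles, which guarantees a non-degenerate spread of labels.
    Constant raw scores collapse to level 0.  Returns (ordinal, raw).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    raw = raw_scores(cpms, substrate)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 2]))
        raw = raw + rng.normal(0.0, noise_sd, raw.shape)
    if np.ptp(raw) == 0:
        return np.zeros(len(raw), dtype=int), raw
    qs = np.quantile(raw, np.linspace(0, 1, levels + 1)[1:-1])
    ordinal = np.digitize(raw, qs)
    return ordinal.astype(int), raw


@dataclass
class SyntheticPatient:
    """One phantom patient: scans, ground truth, CPM and deficit scores."""

    patient_id: str
    scan_pair: AlignedScanPair
    occluded_edges: set[int]
    territory_mask: np.ndarray
    true_substrate: np.ndarray
    cpm: np.ndarray
    scores: dict[str, int]
    raw_score: float = 0.0

    def __post_init__(self) -> None:
        shape = self.scan_pair.ct.shape
        if self.territory_mask.shape != shape or self.true_substrate.shape != shape:
            raise ValueError("patient fields must share one grid")


def generate_cohort(
    n: int,
    config: PhantomConfig,
    rng_seed: int = 0,
    substrate_regions: list | None = None,
    score_noise_sd: float = 0.0,
    levels: int = 5,
    cpm_config: CpmConfig | None = None,
    subscore_name: str = "deficit",
) -> tuple[list[SyntheticPatient], np.ndarray]:
    """Generate a phantom cohort sharing one planted substrate.

    Each patient gets an independent vascular tree and one randomly occluded
    edge; CPMs are computed with the actual perfusion pipeline on the native
    grid, and scores follow the noisy dot-product generative model.

    Returns (patients, substrate).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    shape = config.grid_shape
    if substrate_regions is None:
        # place the eloquent region inside the vascular canopy (the tree
        # grows upward from the bottom face), so that random branch
        # occlusions hypoperfuse it in part of the cohort and the simulated
        # deficits actually carry a perfusion-deficit signal
        center = (shape[0] / 2.0, shape[1] / 2.0, 0.62 * shape[2])
        substrate_regions = [(center, min(shape) / 5.0, 1.0)]
    substrate = plant_substrate(shape, substrate_regions)
    if cpm_config is None:
        # native-grid CPM: phantom grids are already coarse
        cpm_config = CpmConfig(downsample_factor=1)
    master = np.random.default_rng(np.random.SeedSequence([rng_seed, 3]))
    patients: list[SyntheticPatient] = []
    cpms: list[np.ndarray] = []
    for i in range(n):
        pconf = PhantomConfig(
            grid_shape=config.grid_shape,
            n_branches=config.n_branches,
            branch_angle_spread=config.branch_angle_spread,
            contrast_level=config.contrast_level,
            noise_sd=config.noise_sd,
            background_level=config.background_level,
            root_radius=config.root_radius,
            rng_seed=int(master.integers(0, 2**31 - 1)),
        )
        tree, _ = generate_vascular_tree(pconf)
        # avoid occluding the root so some vasculature always enhances
        candidates = list(range(1, len(tree.edges))) or [0]
        edge_id = candidates[int(master.integers(0, len(candidates)))]
        occluded, territory = apply_occlusion(tree, edge_id)
        pair = render_scan_pair(tree, pconf, occluded_edges=occluded)
        result = compute_cpm(pair, cpm_config)
        patients.append(
            SyntheticPatient(
                patient_id=f"phantom{i:04d}",
                scan_pair=pair,
                occluded_edges=occluded,
                territory_mask=territory,
                true_substrate=substrate,
                cpm=result.cpm,
                scores={},
            )
        )
        cpms.append(result.cpm)
    ordinal, raw = simulate_scores(
        cpms, substrate, noise_sd=score_noise_sd, levels=levels, rng_seed=rng_seed
    )
    for p, o, r in zip(patients, ordinal, raw):
        p.scores[subscore_name] = int(o)
        p.raw_score = float(r)
    return patients, substrate
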