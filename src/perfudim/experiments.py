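"""Self-contained validation experiments at desk scale.

Each function runs one fixed protocol end-to-end — phantom generation,
pipeline execution, measurement — and returns plain numbers.  They are the
package's own evidence that the method behaves as designed: substrate
recovery on a synthetic cohort, eikonal-solver agreement with an
independent graph-search oracle, and occlusion-induced perfusion contrast
on a symmetric phantom.  The problem sizes (64 patients, 32-cube grids,
depth-5 schedule, 60 epochs) are chosen so a full run completes on a
single CPU core in minutes rather than GPU-days; docs/methods.md discusses
what these scaled runs do and do not demonstrate.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .cpm import CpmConfig, compute_cpm
from .dlm import (
    ModelConfig,
    calibrate_threshold,
    infer_substrate,
    split_cohort,
    train,
)
from .fastmarch import fast_march
from .phantom import (
    PhantomConfig,
    apply_occlusion,
    generate_cohort,
    generate_symmetric_tree,
    render_scan_pair,
)
from .reference import dijkstra_arrival

__all__ = [
    "run_recovery_experiment",
    "run_eikonal_benchmark",
    "run_phantom_contrast",
]


def run_recovery_experiment(
    seed: int = 11,
    n_patients: int = 64,
    grid: int = 32,
    epochs: int = 40,
    verbose: bool = False,
) -> dict:
    """Planted-substrate recovery on a synthetic cohort.

    Generates ``n_patients`` phantoms with independent vascular trees and
    random branch occlusions sharing one planted ball substrate; deficit
    scores are the exact (noiseless) substrate-CPM dot products, linearly
    mapped onto the ordinal scale [0, 4].  A depth-5 perfusion-deficit
    model is trained, the population substrate decoded, and the calibrated
    binary map compared with the planted support.

    Returns a dict with ``dice``, ``val_mse``, ``score_variance``,
    ``calibrated_percentile``, ``best_epoch`` and the raw artifacts.
    """
    cfg = PhantomConfig(
        grid_shape=(grid, grid, grid), n_branches=15, noise_sd=0.02, rng_seed=seed
    )
    patients, substrate = generate_cohort(
        n_patients, cfg, rng_seed=seed, score_noise_sd=0.0
    )
    cpms = {p.patient_id: p.cpm for p in patients}
    raw = {p.patient_id: p.raw_score for p in patients}
    rmax = max(raw.values())
    scores = {k: 4.0 * v / rmax for k, v in raw.items()}

    mcfg = ModelConfig(
        input_shape=(grid, grid, grid),
        channel_schedule=(8, 8, 16, 16, 16),
        latent_dim=50,
        substrate_latent=25,
        learning_rate=1e-3,
        batch_size=10,
        rng_seed=seed,
        score_scale=4.0,
    )
    split = split_cohort(sorted(cpms), rng_seed=seed)
    result = train(cpms, scores, split, mcfg, epochs=epochs, verbose=verbose)

    pop = infer_substrate(
        result, cpms, scores, split.train_ids, native_shape=(grid, grid, grid)
    )
    cal_cpms = [cpms[i] for i in split.calibration_ids]
    cal_scores = [scores[i] for i in split.calibration_ids]
    percentile, binary, _ = calibrate_threshold(pop, cal_cpms, cal_scores)

    truth = substrate > 0
    inter = np.logical_and(binary > 0, truth).sum()
    dice = 2.0 * inter / (binary.sum() + truth.sum())
    # supplementary recovery measures, independent of the percentile the
    # small-sample calibration step happens to select: Dice at the support
    # size matched to the planted ball, and the mean percentile rank of the
    # planted voxels within the inferred map.  Both are evaluated on the
    # final-epoch model: localisation keeps sharpening after the (small-
    # sample, prediction-optimal) validation checkpoint; methods.md
    # discusses the estimation-vs-selection divergence
    checkpoint_state = result.model.state()
    result.model.load_state(result.final_state)
    pop_final = infer_substrate(
        result, cpms, scores, split.train_ids, native_shape=(grid, grid, grid)
    )
    result.model.load_state(checkpoint_state)
    matched = pop_final > np.quantile(pop_final, 1.0 - truth.mean())
    dice_matched = 2.0 * (matched & truth).sum() / (matched.sum() + truth.sum())
    ranks = pop_final.ravel().argsort().argsort().reshape(pop_final.shape)
    truth_rank = float((ranks[truth] / pop_final.size).mean())
    val_mse = float(result.log.val_mse.min())
    scaled = np.array([scores[i] for i in sorted(scores)]) / 4.0

    # min-norm linear oracle on the same training data: the best any
    # dot-product readout can do, bounding attainable recovery
    X = np.array([cpms[i].ravel() for i in split.train_ids])
    s_tr = np.array([scores[i] for i in split.train_ids])
    gram = X @ X.T
    gram += 1e-9 * np.trace(gram) / len(s_tr) * np.eye(len(s_tr))
    w = (X.T @ np.linalg.solve(gram, s_tr)).reshape(truth.shape)
    w_matched = w > np.quantile(w, 1.0 - truth.mean())
    oracle_dice = (
        2.0 * (w_matched & truth).sum() / (w_matched.sum() + truth.sum())
    )
    oracle_ranks = w.ravel().argsort().argsort().reshape(w.shape)
    oracle_rank = float((oracle_ranks[truth] / w.size).mean())

    return {
        "dice": float(dice),
        "dice_matched_support": float(dice_matched),
        "truth_rank": truth_rank,
        "oracle_dice_matched_support": float(oracle_dice),
        "oracle_truth_rank": oracle_rank,
        "val_mse": val_mse,
        "score_variance": float(scaled.var()),
        "calibrated_percentile": float(percentile),
        "best_epoch": int(result.best_epoch),
        "population_substrate": pop,
        "binary_substrate": binary,
        "true_substrate": substrate,
        "log": result.log,
    }


def _smooth_speed(shape, seed, lo=0.2, hi=1.0):
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.random(shape), sigma=1.5)
    f = (f - f.min()) / max(np.ptp(f), 1e-12)
    return lo + (hi - lo) * f


def run_eikonal_benchmark(seed: int = 0, n_fields: int = 50) -> dict:
    """Fast marching vs dense-neighbourhood Dijkstra on small random fields.

    For each field (random shape up to 12 per axis, smooth speeds in
    [0.2, 1], one random seed voxel) the per-voxel relative deviation
    between the two arrival-time maps is recorded.  Returns the worst
    per-voxel deviation across all fields, the smallest per-field fraction
    of voxels within 10%, and the largest per-field median deviation.
    """
    worst = 0.0
    min_frac = 1.0
    max_median = 0.0
    for k in range(n_fields):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        shape = tuple(int(x) for x in rng.integers(6, 13, 3))
        speed = _smooth_speed(shape, int(rng.integers(0, 2**31 - 1)))
        sv = tuple(int(rng.integers(0, s)) for s in shape)
        T = fast_march(speed, [sv], speed_floor=None)
        D = dijkstra_arrival(speed, [sv], speed_floor=None)
        m = D > 1e-9
        rel = np.abs(T[m] - D[m]) / D[m]
        worst = max(worst, float(rel.max()))
        min_frac = min(min_frac, float((rel <= 0.10).mean()))
        max_median = max(max_median, float(np.median(rel)))
    return {
        "max_rel_error": worst,
        "min_frac_within_10pct": min_frac,
        "max_median_rel_error": max_median,
        "n_fields": n_fields,
    }


def run_phantom_contrast(seed: int = 5, grid: int = 48) -> dict:
    """Occlusion-induced arrival-time asymmetry on a symmetric-tree phantom.

    Builds a mirror-symmetric vascular tree, occludes one lateral branch,
    and compares the mean CPM inside the hypoperfused territory with the
    mirrored contralateral region; repeats without occlusion as control.
    Returns both territory/mirror mean ratios.
    """
    cfg = PhantomConfig(
        grid_shape=(grid, grid, grid), n_branches=21, noise_sd=0.0, rng_seed=seed
    )
    tree, _ = generate_symmetric_tree(cfg)
    cx = (grid - 1) / 2.0
    lateral = [
        i
        for i in range(1, len(tree.edges))
        if len(tree.edge_voxels[i]) and tree.edge_voxels[i][:, 0].mean() > cx + 2
    ]
    occluded, territory = apply_occlusion(tree, lateral[0])
    mirror = territory[::-1, :, :]
    cpm_cfg = CpmConfig(downsample_factor=1)

    pair_occ = render_scan_pair(tree, cfg, occluded_edges=occluded)
    cpm_occ = compute_cpm(pair_occ, cpm_cfg).cpm
    pair_open = render_scan_pair(tree, cfg)
    cpm_open = compute_cpm(pair_open, cpm_cfg).cpm

    return {
        "occluded_ratio": float(cpm_occ[territory].mean() / cpm_occ[mirror].mean()),
        "unoccluded_ratio": float(
            cpm_open[territory].mean() / cpm_open[mirror].mean()
        ),
        "territory_voxels": int(territory.sum()),
    }
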