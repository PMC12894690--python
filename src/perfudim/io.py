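"""Volume, streamline and cohort-roster I/O plus run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .tracts import StreamlineBundle

__all__ = [
    "read_volume",
    "write_volume",
    "read_scan_pair",
    "read_streamlines",
    "write_streamlines_text",
    "filter_cohort",
    "write_manifest",
]


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume; returns (data, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def write_volume(
    volume: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)
) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(path))


def read_scan_pair(ct_path, cta_path):
    """Load a co-registered CT/CTA pair, enforcing grid and spacing agreement."""
    from .cpm import AlignedScanPair

    ct, vs_ct = read_volume(ct_path)
    cta, vs_cta = read_volume(cta_path)
    if ct.shape != cta.shape:
        raise ValueError(
            f"CT/CTA misaligned: {ct.shape} vs {cta.shape}"
        )
    if not np.allclose(vs_ct, vs_cta, rtol=1e-4):
        raise ValueError(f"CT/CTA voxel sizes differ: {vs_ct} vs {vs_cta}")
    return AlignedScanPair(ct=ct, cta=cta, voxel_size_mm=vs_ct)


def read_streamlines(path) -> list[StreamlineBundle]:
    """Read a bundle atlas from a TRK file or plain-text bundle format.

    TRK files yield one bundle named after the file.  The text format holds
    one streamline per block of ``x y z`` rows, blocks separated by blank
    lines or ``#bundle <name>`` headers starting a named bundle.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".trk":
        trk = nib.streamlines.load(str(path))
        lines = [np.asarray(s, dtype=np.float64) for s in trk.streamlines]
        if not lines:
            raise ValueError(f"{path}: TRK file contains no streamlines")
        return [StreamlineBundle(path.stem, lines)]
    bundles: list[StreamlineBundle] = []
    name = path.stem
    current: list[np.ndarray] = []
    points: list[list[float]] = []

    def flush_line():
        if points:
            current.append(np.asarray(points, dtype=np.float64))
            points.clear()

    def flush_bundle(next_name: str | None):
        nonlocal name, current
        flush_line()
        if current:
            bundles.append(StreamlineBundle(name, current))
            current = []
        if next_name is not None:
            name = next_name

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#bundle"):
                flush_bundle(line.split(None, 1)[1].strip())
            elif not line or line.startswith("#"):
                flush_line()
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}: malformed point row {line!r}")
                points.append([float(p) for p in parts])
    flush_bundle(None)
    if not bundles:
        raise ValueError(f"{path}: no streamlines found")
    return bundles


def write_streamlines_text(bundles: list[StreamlineBundle], path) -> None:
    with open(path, "w") as fh:
        for bundle in bundles:
            fh.write(f"#bundle {bundle.name}\n")
            for s in bundle.streamlines:
                for x, y, z in s:
                    fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
                fh.write("\n")


@dataclass
class ExclusionTally:
    enrolled: int
    incomplete_subscores: int
    failed_coregistration: int
    mild_deficit: int
    retained: int


def filter_cohort(
    roster: pd.DataFrame, nihss_cutoff: int = 4
) -> tuple[list, ExclusionTally]:
    """Sequential cohort exclusion: incomplete sub-scores, then failed
    co-registration, then mild deficit (total NIHSS <= cutoff).

    Exclusions are applied in that fixed order, so each patient is counted
    in exactly one tally and the tallies plus the retained count always sum
    to the enrolled count.  ``roster`` needs columns ``patient_id``,
    ``has_complete_subscores``, ``coregistration_ok``, ``total_nihss``.
    """
    required = {
        "patient_id",
        "has_complete_subscores",
        "coregistration_ok",
        "total_nihss",
    }
    missing = required - set(roster.columns)
    if missing:
        raise ValueError(f"roster missing columns: {sorted(missing)}")
    if roster["patient_id"].duplicated().any():
        dupes = roster.loc[roster["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient ids: {sorted(set(dupes))[:5]}")
    if (roster["total_nihss"] < 0).any():
        raise ValueError("total_nihss must be >= 0")

    n0 = len(roster)
    step1 = roster[roster["has_complete_subscores"].astype(bool)]
    n_incomplete = n0 - len(step1)
    step2 = step1[step1["coregistration_ok"].astype(bool)]
    n_coreg = len(step1) - len(step2)
    step3 = step2[step2["total_nihss"] > nihss_cutoff]
    n_mild = len(step2) - len(step3)
    tally = ExclusionTally(
        enrolled=n0,
        incomplete_subscores=n_incomplete,
        failed_coregistration=n_coreg,
        mild_deficit=n_mild,
        retained=len(step3),
    )
    return list(step3["patient_id"]), tally


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    """Record the run configuration, a config hash, and library versions."""
    import scipy
    import skimage

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "perfudim": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "nibabel": nib.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
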