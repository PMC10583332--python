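"""Voxel-level ROI extraction on co-registered volumes.

Implements the tissue-fraction arithmetic used to take ROI-level NODDI means
from maps already aligned on one grid: GM fraction synthesised as
1 - WM - CSF (clamped to [0, 1]), a pseudo-T1 contrast built by weighting the
fraction maps with class values CSF=0, WM=1, GM=2, GM ROI means over voxels
whose GM fraction passes a threshold (default 0.7, inclusive), and WM tract
means weighted by tract-probability maps. Registration itself is out of
scope: a grid-equality check stands in for spatial alignment.

A deterministic phantom generator plants per-ROI metric means on a small
grid so extraction can be validated against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import GM_ROIS, METRICS, ROI_TISSUE, WM_ROIS

__all__ = [
    "VolumeSet",
    "ROISpec",
    "EmptyROIError",
    "compute_gm_fraction",
    "build_pseudo_t1",
    "gm_masked_roi_mean",
    "tract_weighted_mean",
    "extract_roi_table",
    "PhantomConfig",
    "generate_phantom_volumes",
    "save_volume_set",
    "load_volume_set",
]


class GridMismatchError(ValueError):
    """Volumes do not share a shape/affine grid."""


class EmptyROIError(ValueError):
    """No voxel passes the ROI mask (or tract support is empty)."""

    def __init__(self, roi_name: str, detail: str = ""):
        self.roi_name = roi_name
        super().__init__(f"ROI {roi_name!r} selects no voxels{': ' + detail if detail else ''}")


@dataclass
class VolumeSet:
    """Co-registered 3D volumes on one grid.

    metric_maps are keyed (metric, tissue_class) — separate GM- and
    WM-optimised NODDI fits are distinguished only by the tissue key.
    tract_probability maps are keyed by the names in the ROISpec.
    """

    affine: np.ndarray
    wm_fraction: np.ndarray
    csf_fraction: np.ndarray
    metric_maps: dict[tuple[str, str], np.ndarray]
    gm_labels: np.ndarray
    tract_probability: dict[str, np.ndarray]

    def validate(self) -> None:
        shape = self.wm_fraction.shape
        vols: list[np.ndarray] = [self.csf_fraction, self.gm_labels,
                                  *self.metric_maps.values(),
                                  *self.tract_probability.values()]
        for v in vols:
            if v.shape != shape:
                raise GridMismatchError(
                    f"volume shape {v.shape} != grid shape {shape}")
        for name, frac in (("wm_fraction", self.wm_fraction),
                           ("csf_fraction", self.csf_fraction)):
            if frac.min() < 0 or frac.max() > 1:
                raise ValueError(f"{name} outside [0, 1]")
        if self.gm_labels.min() < 0 or not np.issubdtype(
                self.gm_labels.dtype, np.integer):
            raise ValueError("gm_labels must be non-negative integers")
        for key, prob in self.tract_probability.items():
            if prob.min() < 0 or prob.max() > 1:
                raise ValueError(f"tract probability {key!r} outside [0, 1]")


@dataclass
class ROISpec:
    """Resolution of ROI names to label codes / probability-map keys.

    gm_rois: roi_name -> (left_label, right_label) in the gm_labels volume.
    wm_rois: roi_name -> tuple of tract_probability keys (one bilateral map,
    or a left/right pair whose extracted means are averaged).
    """

    gm_rois: dict[str, tuple[int, int]]
    wm_rois: dict[str, tuple[str, ...]]
    gm_threshold: float = 0.7

    def validate(self, volumes: VolumeSet) -> None:
        if not 0 < self.gm_threshold < 1:
            raise ValueError("gm_threshold must lie in (0, 1)")
        labels = set(np.unique(volumes.gm_labels).tolist())
        for roi, (left, right) in self.gm_rois.items():
            for code in (left, right):
                if code not in labels:
                    raise ValueError(
                        f"GM ROI {roi!r}: label {code} absent from gm_labels")
        for roi, keys in self.wm_rois.items():
            for key in keys:
                if key not in volumes.tract_probability:
                    raise ValueError(
                        f"WM ROI {roi!r}: probability map {key!r} missing")


def _check_grid(*volumes: np.ndarray) -> None:
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise GridMismatchError(f"volumes on different grids: {shapes}")


def compute_gm_fraction(wm_fraction: np.ndarray,
                        csf_fraction: np.ndarray) -> np.ndarray:
    """GM fraction = 1 - WM - CSF, clamped voxelwise to [0, 1]."""
    _check_grid(wm_fraction, csf_fraction)
    return np.clip(1.0 - wm_fraction - csf_fraction, 0.0, 1.0)


def build_pseudo_t1(gm_fraction: np.ndarray, wm_fraction: np.ndarray,
                    csf_fraction: np.ndarray) -> np.ndarray:
    """Pseudo-T1 contrast: class-weighted fraction sum (CSF=0, WM=1, GM=2)."""
    _check_grid(gm_fraction, wm_fraction, csf_fraction)
    return 0.0 * csf_fraction + 1.0 * wm_fraction + 2.0 * gm_fraction


def gm_masked_roi_mean(
    metric_map: np.ndarray,
    gm_fraction: np.ndarray,
    gm_labels: np.ndarray,
    label_codes: int | tuple[int, ...],
    threshold: float = 0.7,
    roi_name: str = "?",
) -> float:
    """Unweighted metric mean over voxels with a matching label AND
    GM fraction >= threshold (boundary inclusive)."""
    _check_grid(metric_map, gm_fraction, gm_labels)
    codes = (label_codes,) if np.isscalar(label_codes) else tuple(label_codes)
    mask = np.isin(gm_labels, codes) & (gm_fraction >= threshold)
    if not mask.any():
        raise EmptyROIError(roi_name, f"no voxel with GM fraction >= {threshold}")
    return float(metric_map[mask].mean())


def tract_weighted_mean(metric_map: np.ndarray,
                        probability_map: np.ndarray,
                        roi_name: str = "?") -> float:
    """Probability-weighted metric mean over the tract support (p > 0)."""
    _check_grid(metric_map, probability_map)
    support = probability_map > 0
    total = probability_map[support].sum()
    if total <= 0:
        raise EmptyROIError(roi_name, "all-zero probability map")
    return float((metric_map[support] * probability_map[support]).sum() / total)


def extract_roi_table(volumes: VolumeSet, spec: ROISpec) -> pd.DataFrame:
    """Extract the bilateral-mean ROI table from a VolumeSet.

    GM ROIs: per-hemisphere GM-masked means averaged left/right. WM ROIs:
    tract-probability-weighted means, averaged across the configured maps
    (so a left/right map pair is averaged after extraction).
    """
    volumes.validate()
    spec.validate(volumes)
    gm_fraction = compute_gm_fraction(volumes.wm_fraction, volumes.csf_fraction)
    rows = []
    for roi, (left, right) in spec.gm_rois.items():
        for metric in METRICS:
            mmap = volumes.metric_maps[(metric, "GM")]
            sides = [gm_masked_roi_mean(mmap, gm_fraction, volumes.gm_labels,
                                        code, spec.gm_threshold, roi_name=roi)
                     for code in (left, right)]
            rows.append({"participant_id": "", "roi_name": roi,
                         "metric": metric, "tissue_class": "GM",
                         "value": float(np.mean(sides))})
    for roi, keys in spec.wm_rois.items():
        for metric in METRICS:
            mmap = volumes.metric_maps[(metric, "WM")]
            sides = [tract_weighted_mean(mmap, volumes.tract_probability[k],
                                         roi_name=roi)
                     for k in keys]
            rows.append({"participant_id": "", "roi_name": roi,
                         "metric": metric, "tissue_class": "WM",
                         "value": float(np.mean(sides))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phantom generation

@dataclass
class PhantomConfig:
    """Synthetic phantom: labeled GM blobs, smooth WM tract blobs, planted
    per-ROI metric means. Default means mirror the cohort generator's
    baselines so phantom extraction feeds the tabular pipeline directly."""

    shape: tuple[int, int, int] = (32, 32, 32)
    gm_rois: tuple[str, ...] = GM_ROIS
    wm_rois: tuple[str, ...] = WM_ROIS
    planted_means: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    blob_size: int = 3
    background_metric: float = 0.3
    seed: int = 0

    def mean_for(self, roi: str, metric: str) -> float:
        if (roi, metric) in self.planted_means:
            return self.planted_means[(roi, metric)]
        from .cohort import _default_baselines
        return _default_baselines()[(roi, metric)]


def _blob_origins(n_blobs: int, shape_yz: tuple[int, int],
                  blob: int) -> list[tuple[int, int]]:
    """Raster-place n_blobs of side ``blob`` (1-voxel gaps) in a (ny, nz)
    plane; raises if they do not fit."""
    step = blob + 1
    ny, nz = shape_yz
    origins = []
    for zi in range(max((nz - 1) // step, 1)):
        for yi in range(max((ny - 1) // step, 1)):
            y0, z0 = 1 + yi * step, 1 + zi * step
            if y0 + blob <= ny and z0 + blob <= nz:
                origins.append((y0, z0))
    if len(origins) < n_blobs:
        raise ValueError(
            f"grid {shape_yz} too small to place {n_blobs} ROIs of size {blob}")
    return origins[:n_blobs]


def generate_phantom_volumes(
    config: PhantomConfig | None = None, seed: int | None = None
) -> tuple[VolumeSet, ROISpec]:
    """Build a deterministic phantom VolumeSet plus the matching ROISpec.

    GM ROIs are cubic blobs (per hemisphere, mirrored in x) where the tissue
    fractions give GM fraction 0.8 >= threshold; WM tracts are Gaussian
    probability blobs on a left/right pair of maps. Metric maps hold the
    planted per-ROI mean inside each blob plus optional Gaussian noise.
    """
    config = config or PhantomConfig()
    if seed is not None:
        config = PhantomConfig(**{**config.__dict__, "seed": seed})
    nx, ny, nz = config.shape
    if min(config.shape) < 8:
        raise ValueError("phantom grid must be at least 8 voxels per axis")
    blob = config.blob_size
    if nx < 2 * (blob + 2):
        raise ValueError("x extent too small for two hemispheres")
    rng = np.random.default_rng([int(config.seed), 37])

    # Background: mixed tissue, GM fraction 0.3 (below threshold).
    wm = np.full(config.shape, 0.4)
    csf = np.full(config.shape, 0.3)
    labels = np.zeros(config.shape, dtype=np.int32)
    metric_maps = {(m, t): np.full(config.shape, config.background_metric)
                   for m in METRICS for t in ("GM", "WM")}
    tract_probability: dict[str, np.ndarray] = {}

    half = nx // 2
    gm_origins = _blob_origins(len(config.gm_rois), (ny, nz), blob)
    gm_codes: dict[str, tuple[int, int]] = {}
    for i, roi in enumerate(config.gm_rois):
        y0, z0 = gm_origins[i]
        left_code, right_code = 2 * i + 1, 2 * i + 2
        gm_codes[roi] = (left_code, right_code)
        for code, x0 in ((left_code, 1), (right_code, half + 1)):
            sl = (slice(x0, x0 + blob), slice(y0, y0 + blob),
                  slice(z0, z0 + blob))
            labels[sl] = code
            wm[sl] = 0.1
            csf[sl] = 0.1   # GM fraction 0.8 inside the blob
            for metric in METRICS:
                metric_maps[(metric, "GM")][sl] = config.mean_for(roi, metric)

    # WM tracts: Gaussian probability blobs centred in each hemisphere, on a
    # y/z raster offset from the GM blobs.
    wm_origins = _blob_origins(len(config.gm_rois) + len(config.wm_rois),
                               (ny, nz), blob)[len(config.gm_rois):]
    yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    wm_keys: dict[str, tuple[str, ...]] = {}
    for j, roi in enumerate(config.wm_rois):
        y0, z0 = wm_origins[j]
        cy, cz = y0 + blob / 2, z0 + blob / 2
        keys = []
        for side, x0 in (("left", 1), ("right", half + 1)):
            prob = np.zeros(config.shape)
            plane = np.exp(-((yy - cy) ** 2 + (zz - cz) ** 2) / (2 * 1.0 ** 2))
            # Cut the tail so neighbouring blobs (and the GM cubes) never
            # share support; keeps planted means exactly recoverable.
            plane[plane < 0.2] = 0.0
            for dx in range(blob):
                prob[x0 + dx] = plane
            key = f"{roi}_{side}"
            tract_probability[key] = prob
            keys.append(key)
            sl = prob > 0
            wm[sl] = 0.9
            csf[sl] = 0.05
            for metric in METRICS:
                metric_maps[(metric, "WM")][sl] = config.mean_for(roi, metric)
        wm_keys[roi] = tuple(keys)

    if config.noise_sd > 0:
        for key in metric_maps:
            metric_maps[key] = metric_maps[key] + rng.normal(
                0.0, config.noise_sd, size=config.shape)

    volumes = VolumeSet(
        affine=np.diag([2.0, 2.0, 2.0, 1.0]),
        wm_fraction=wm, csf_fraction=csf, metric_maps=metric_maps,
        gm_labels=labels, tract_probability=tract_probability,
    )
    spec = ROISpec(gm_rois=gm_codes, wm_rois=wm_keys)
    volumes.validate()
    spec.validate(volumes)
    return volumes, spec


# ---------------------------------------------------------------------------
# NIfTI persistence (affine honored, no reorientation performed)

def save_volume_set(volumes: VolumeSet, spec: ROISpec,
                    outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _save(name: str, data: np.ndarray) -> None:
        nib.save(nib.Nifti1Image(np.asarray(data, np.float32), volumes.affine),
                 outdir / f"{name}.nii")

    _save("wm_fraction", volumes.wm_fraction)
    _save("csf_fraction", volumes.csf_fraction)
    nib.save(nib.Nifti1Image(volumes.gm_labels.astype(np.int32),
                             volumes.affine), outdir / "gm_labels.nii")
    for (metric, tissue), data in volumes.metric_maps.items():
        _save(f"metric_{metric}_{tissue}", data)
    for key, data in volumes.tract_probability.items():
        _save(f"tract_{key}", data)
    manifest = {
        "metric_maps": [[m, t] for (m, t) in volumes.metric_maps],
        "tracts": sorted(volumes.tract_probability),
        "gm_rois": {roi: list(codes) for roi, codes in spec.gm_rois.items()},
        "wm_rois": {roi: list(keys) for roi, keys in spec.wm_rois.items()},
        "gm_threshold": spec.gm_threshold,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_volume_set(indir: str | Path) -> tuple[VolumeSet, ROISpec]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())

    def _load(name: str) -> tuple[np.ndarray, np.ndarray]:
        img = nib.load(indir / f"{name}.nii")
        return np.asarray(img.dataobj), img.affine

    wm, affine = _load("wm_fraction")
    csf, _ = _load("csf_fraction")
    labels = np.asarray(nib.load(indir / "gm_labels.nii").dataobj).astype(np.int32)
    metric_maps = {(m, t): _load(f"metric_{m}_{t}")[0]
                   for m, t in (tuple(x) for x in manifest["metric_maps"])}
    tracts = {key: _load(f"tract_{key}")[0] for key in manifest["tracts"]}
    volumes = VolumeSet(affine=affine, wm_fraction=wm, csf_fraction=csf,
                        metric_maps=metric_maps, gm_labels=labels,
                        tract_probability=tracts)
    spec = ROISpec(
        gm_rois={roi: tuple(codes) for roi, codes in manifest["gm_rois"].items()},
        wm_rois={roi: tuple(keys) for roi, keys in manifest["wm_rois"].items()},
        gm_threshold=manifest["gm_threshold"],
    )
    volumes.validate()
    return volumes, spec
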