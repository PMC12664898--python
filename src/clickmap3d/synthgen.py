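"""Synthetic whole-brain scenes: toy atlases, simulated nuclei, rendered volumes,
and known ground-truth transforms.

The generator stands in for cleared-brain light-sheet acquisitions.  It
emulates the features the downstream pipeline must cope with: nucleus
densities that vary by region (with a ventricular-wall enrichment), clusters
of 1-4 touching S-phase nuclei, Poisson-Gaussian camera noise, single-voxel
speckle noise, a bright rim artifact at the tissue surface, a smooth
anatomy-correlated autofluorescence channel, and a known affine + smooth
nonlinear deformation between "sample" and "atlas" spaces.  Every operation
is a pure function of its inputs and an explicit integer seed.

Defaults encode the study conditions of the real acquisitions this package
targets: ~9 um nuclear diameter, imaging voxels down to 3.65 um, atlas
voxels of 10/25/50 um.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DEFAULT_CUSTOM_ID, OUTSIDE_ID, LabelAtlas, Ontology, Volume
from .normalization import AffineTransform, DeformationField, TransformChain

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticScene",
    "RenderParams",
    "DEFAULT_NUCLEUS_RADIUS_UM",
    "build_toy_atlas",
    "sample_nuclei",
    "render_channels",
    "inject_speckle",
    "make_ground_truth_transform",
]

#: nuclear radius used throughout the synthetic scenes (um); mouse-brain
#: nuclei are of order 9-10 um across.
DEFAULT_NUCLEUS_RADIUS_UM = 4.5

_ROOT_ID = 9997  # chosen away from the reserved custom ID


@dataclass
class SyntheticScene:
    """Ground truth for one simulated brain: nuclei, noise, and transforms."""

    nuclei: pd.DataFrame  # columns x_um, y_um, z_um, radius_um, cluster_id (atlas space)
    region_densities: dict[int, float]
    seed: int
    true_transform: TransformChain
    atlas: LabelAtlas
    speckle_voxels: list[tuple[int, int, int]] = dc_field(default_factory=list)

    def __post_init__(self):
        if len(self.nuclei):
            if (self.nuclei["radius_um"] <= 0).any():
                raise ValueError("nucleus radii must be positive")
            idx = self.atlas.point_to_index(self.centers_um())
            labels = np.full(len(idx), OUTSIDE_ID)
            ok = idx[:, 0] >= 0
            labels[ok] = self.atlas.labels[tuple(idx[ok].T)]
            if (labels == OUTSIDE_ID).any():
                raise ValueError("nucleus centers must lie inside nonzero-label voxels")

    def centers_um(self) -> np.ndarray:
        return self.nuclei[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    def centers_sample_um(self) -> np.ndarray:
        """Nucleus centres pushed into sample space by the true transform."""
        if not len(self.nuclei):
            return np.empty((0, 3))
        return self.true_transform.atlas_to_sample(self.centers_um())

    def cluster_sizes(self) -> pd.Series:
        return self.nuclei.groupby("cluster_id").size()

    def to_csv(self, path) -> None:
        df = self.nuclei.copy()
        df["kind"] = "nucleus"
        rows = [df]
        if self.speckle_voxels:
            sp = pd.DataFrame(self.speckle_voxels, columns=["x_um", "y_um", "z_um"], dtype=float)
            sp["radius_um"] = 0.0
            sp["cluster_id"] = -1
            sp["kind"] = "speckle"
            rows.append(sp)
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


@dataclass(frozen=True)
class RenderParams:
    """Optical/camera model for rendering a scene into intensity volumes.

    ``photon_scale`` is the mean photon count at the (unblurred) centre of a
    nucleus; shot noise is Poisson in those units and can be switched off to
    obtain analytically predictable volumes.
    """

    spacing_um: float = 3.65
    psf_sigma_um: float = 1.5
    photon_scale: float = 80.0
    read_noise_sd: float = 2.0
    surface_rim_amplitude: float = 0.0
    attenuation_per_mm: float = 0.0
    shot_noise: bool = True

    def __post_init__(self):
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        if self.psf_sigma_um < 0 or self.photon_scale < 0 or self.read_noise_sd < 0 \
                or self.surface_rim_amplitude < 0 or self.attenuation_per_mm < 0:
            raise ValueError("noise/optics amplitudes must be non-negative")


def _toy_ontology(n_regions: int, custom_id: int) -> tuple[Ontology, list[int], list[int]]:
    """Root -> n top-level regions -> one leaf each (the grid labels)."""
    names = ["ventricle", "caudoputamen-like"] + [f"region-{k}" for k in range(3, n_regions + 1)]
    onto = Ontology()
    onto.add(_ROOT_ID, "root", "root", None)
    top_ids, leaf_ids = [], []
    for k, nm in enumerate(names):
        top = 10 * (k + 1)
        leaf = top + 1
        if custom_id in (top, leaf, _ROOT_ID):
            raise ValueError(f"reserved custom ID {custom_id} collides with generated IDs")
        onto.add(top, nm.upper()[:4] + str(k), nm, _ROOT_ID)
        onto.add(leaf, nm[:3] + f"-leaf{k}", nm + " leaf", top)
        top_ids.append(top)
        leaf_ids.append(leaf)
    return onto, top_ids, leaf_ids


def build_toy_atlas(spacing_um: float, shape: tuple[int, int, int], n_regions: int,
                    seed: int, midline_axis: int = 2,
                    custom_id: int = DEFAULT_CUSTOM_ID) -> LabelAtlas:
    """A bilaterally symmetric toy label atlas with a hierarchy-bearing ontology.

    The brain mask is an ellipsoid; each hemisphere contains a small
    "ventricle" region wrapped by an adjacent "caudoputamen-like" shell (so
    ventricular-wall annotation is exercisable), and the remaining tissue is
    split into ``n_regions - 2`` Voronoi territories mirrored across the
    midline of ``midline_axis``.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 20 for s in shape):
        raise ValueError("toy atlas shape must be at least (20, 20, 20)")
    if n_regions < 3:
        raise ValueError("need at least 3 regions (ventricle, shell, other)")
    rng = np.random.default_rng(seed)
    onto, _top_ids, leaf_ids = _toy_ontology(n_regions, custom_id)

    idx = np.indices(shape, dtype=float) + 0.5
    centre = np.asarray(shape, dtype=float) / 2
    semi = np.asarray(shape, dtype=float) / 2 - 1.5
    r2 = sum(((idx[d] - centre[d]) / semi[d]) ** 2 for d in range(3))
    mask = r2 <= 1.0

    # mirror coordinate: work in one half, reflect across the midline
    m = midline_axis
    half = idx[m] < centre[m]
    labels = np.zeros(shape, dtype=np.int64)

    # ventricle: small ellipsoid per hemisphere, centred partway to the midline
    vent_c = centre.copy()
    vent_c[m] = centre[m] * 0.55
    vent_semi = np.maximum(np.asarray(shape) / 10.0, 1.5)
    v2 = sum(((idx[d] - vent_c[d]) / vent_semi[d]) ** 2 for d in range(3))
    vent = (v2 <= 1.0) & mask
    shell = (v2 <= 2.2 ** 2) & mask & ~vent

    # remaining regions: Voronoi over seed points in one half of the mask
    rest = mask & ~vent & ~shell & half
    rest_pts = np.argwhere(rest)
    n_other = n_regions - 2
    if len(rest_pts) < n_other:
        raise ValueError("atlas too small for requested region count")
    seeds = rest_pts[rng.choice(len(rest_pts), size=n_other, replace=False)]
    d2 = np.stack([((np.argwhere(mask & half) - s) ** 2).sum(axis=1) for s in seeds])
    assign = np.argmin(d2, axis=0)
    half_mask_pts = np.argwhere(mask & half)
    for k in range(n_other):
        pts = half_mask_pts[assign == k]
        labels[tuple(pts.T)] = leaf_ids[2 + k]
    labels[vent & half] = leaf_ids[0]
    labels[shell & half] = leaf_ids[1]

    # reflect onto the other hemisphere (midline of even axes falls between voxels)
    flip = np.flip(labels, axis=m)
    other = ~half
    labels[other] = flip[other]
    return LabelAtlas(labels, spacing_um, onto, custom_id=custom_id)


def sample_nuclei(atlas: LabelAtlas, region_densities: dict[int, float],
                  cluster_mix: dict[int, float] | None = None, seed: int = 0,
                  radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM,
                  transform: TransformChain | None = None) -> SyntheticScene:
    """Place nuclei in atlas space at region-dependent densities.

    Per-region nucleus counts are Poisson with mean ``density x region
    volume``.  Nuclei arrive in clusters whose sizes are drawn from
    ``cluster_mix`` (a distribution over 1-4); members of one cluster sit at
    centre-to-centre distances of 1.0-1.5 nuclear diameters, emulating
    freshly divided, still-touching cells.
    """
    if cluster_mix is None:
        cluster_mix = {1: 1.0}
    sizes = np.array(sorted(cluster_mix))
    probs = np.array([cluster_mix[s] for s in sizes], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("cluster_mix must be a non-negative distribution")
    probs = probs / probs.sum()
    if sizes.min() < 1 or sizes.max() > 4:
        raise ValueError("cluster sizes must be between 1 and 4")
    if any(d < 0 for d in region_densities.values()):
        raise ValueError("densities must be non-negative")

    rng = np.random.default_rng(seed)
    brain = atlas.brain_mask()
    sp = np.asarray(atlas.spacing)
    diameter = 2.0 * radius_um
    rows = []
    cluster_id = 0
    for region_id, density in sorted(region_densities.items()):
        region_vox = np.argwhere(atlas.labels == region_id)
        if len(region_vox) == 0:
            raise ValueError(f"region {region_id} has no voxels in the atlas")
        vol_mm3 = len(region_vox) * atlas.voxel_volume_mm3
        n_target = rng.poisson(density * vol_mm3)
        placed = 0
        while placed < n_target:
            size = int(rng.choice(sizes, p=probs))
            size = min(size, n_target - placed)
            anchor_vox = region_vox[rng.integers(len(region_vox))]
            anchor = (anchor_vox + rng.random(3)) * sp
            members = [anchor]
            attempts = 0
            while len(members) < size:
                attempts += 1
                if attempts > 200:
                    raise ValueError(
                        f"rejection sampling failed in region {region_id}: "
                        "density or clustering too high for the region geometry")
                base = members[rng.integers(len(members))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                dist = diameter * rng.uniform(1.0, 1.5)
                cand = base + direction * dist
                ci = np.floor(cand / sp).astype(int)
                if np.any(ci < 0) or np.any(ci >= np.asarray(atlas.shape)):
                    continue
                if not brain[tuple(ci)]:
                    continue
                members.append(cand)
            for c in members:
                rows.append((c[0], c[1], c[2], radius_um, cluster_id))
            cluster_id += 1
            placed += size
    nuclei = pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "radius_um", "cluster_id"])
    chain = transform if transform is not None else TransformChain()
    return SyntheticScene(nuclei=nuclei, region_densities=dict(region_densities),
                          seed=seed, true_transform=chain, atlas=atlas)


def _rasterize_spheres(centers_um: np.ndarray, radii_um: np.ndarray,
                       shape: tuple[int, int, int], spacing: float) -> np.ndarray:
    """Unit-amplitude sphere indicator sampled at voxel centres."""
    img = np.zeros(shape, dtype=float)
    for c, r in zip(centers_um, radii_um):
        lo = np.maximum(np.floor((c - r) / spacing - 1).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / spacing + 1).astype(int), np.asarray(shape))
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        ix = np.indices([h - l for l, h in zip(lo, hi)], dtype=float)
        d2 = sum(((ix[d] + lo[d] + 0.5) * spacing - c[d]) ** 2 for d in range(3))
        img[sl] = np.maximum(img[sl], (d2 <= r * r).astype(float))
    return img


def render_channels(scene: SyntheticScene, params: RenderParams,
                    channels=("edu", "autofluorescence"), seed: int = 0,
                    space: str = "sample") -> dict[str, Volume]:
    """Render a scene into per-channel intensity volumes.

    ``space="sample"`` pushes nuclei and anatomy through the scene's true
    transform first, producing the deformed stacks a microscope would have
    acquired; ``space="atlas"`` renders in atlas coordinates directly.
    The marker channel re-renders the same nuclei with a small random
    chromatic offset (different excitation wavelengths travel differently
    through cleared tissue), so colocalization at a few micrometres is the
    expected signal.
    """
    spacing = params.spacing_um
    if len(scene.nuclei) and 2 * scene.nuclei["radius_um"].min() < spacing:
        warnings.warn("nucleus diameter below one voxel at the requested spacing; "
                      "rendering anyway")
    rng = np.random.default_rng(seed)

    if space == "sample":
        centers = scene.centers_sample_um()
        # brain mask in sample space: map voxel centres back to atlas labels
        extent = np.asarray(scene.atlas.shape) * np.asarray(scene.atlas.spacing)
        shape = tuple(int(np.ceil(e / spacing)) for e in extent)
        vox_centers = (np.indices(shape).reshape(3, -1).T + 0.5) * spacing
        atlas_pts, _ = scene.true_transform.sample_to_atlas(vox_centers)
        idx = scene.atlas.point_to_index(atlas_pts)
        inside = idx[:, 0] >= 0
        lab = np.zeros(len(idx), dtype=np.int64)
        lab[inside] = scene.atlas.labels[tuple(idx[inside].T)]
        brain = (lab != OUTSIDE_ID).reshape(shape)
    elif space == "atlas":
        centers = scene.centers_um()
        extent = np.asarray(scene.atlas.shape) * np.asarray(scene.atlas.spacing)
        shape = tuple(int(np.ceil(e / spacing)) for e in extent)
        # nearest-neighbour lookup of the atlas label under each render voxel centre
        axes = [np.minimum(((np.arange(n) + 0.5) * spacing / scene.atlas.spacing[d])
                           .astype(int), scene.atlas.shape[d] - 1)
                for d, n in enumerate(shape)]
        brain = scene.atlas.brain_mask()[np.ix_(*axes)]
    else:
        raise ValueError(f"space must be 'sample' or 'atlas', got {space!r}")

    radii = scene.nuclei["radius_um"].to_numpy() if len(scene.nuclei) else np.empty(0)
    sigma_vox = params.psf_sigma_um / spacing

    def _camera(photons: np.ndarray) -> np.ndarray:
        out = photons
        if params.shot_noise and params.photon_scale > 0:
            out = rng.poisson(np.clip(photons, 0, None)).astype(float)
        if params.read_noise_sd > 0:
            out = out + rng.normal(0, params.read_noise_sd, photons.shape)
        return out

    out: dict[str, Volume] = {}
    for channel in channels:
        if channel in ("edu", "marker"):
            cen = centers
            if channel == "marker" and len(cen):
                offset = rng.normal(0, 1.0, cen.shape)  # ~2 um chromatic shift rms
                cen = cen + offset
            ideal = _rasterize_spheres(cen, radii, shape, spacing) if len(cen) else \
                np.zeros(shape)
            if sigma_vox > 0:
                ideal = ndimage.gaussian_filter(ideal, sigma_vox)
            photons = ideal * params.photon_scale
        elif channel == "autofluorescence":
            base = ndimage.gaussian_filter(brain.astype(float), 2.0) * 50.0
            photons = base
            if params.surface_rim_amplitude > 0:
                rim = brain & ~ndimage.binary_erosion(brain, iterations=2)
                photons = photons + rim * params.surface_rim_amplitude
        else:
            raise ValueError(f"unknown channel {channel!r}")
        if params.attenuation_per_mm > 0:
            depth_mm = (np.arange(shape[0], dtype=float)[:, None, None] + 0.5) \
                * spacing * 1e-3
            photons = photons * np.exp(-params.attenuation_per_mm * depth_mm)
        data = _camera(photons)
        out[channel] = Volume(np.clip(data, 0, None), spacing)
    return out


def inject_speckle(volume: Volume, n_speckles: int, amplitude: float, seed: int,
                   exclude_mask: np.ndarray | None = None
                   ) -> tuple[Volume, list[tuple[int, int, int]]]:
    """Add single-voxel speckle spikes at positions away from true nuclei.

    Returns the speckled volume and the ground-truth voxel indices, so
    detection can be cross-checked: a correct pipeline never reports a
    nucleus at a speckle position (single voxels fail the three-voxel rule).
    """
    if n_speckles < 0:
        raise ValueError("n_speckles must be non-negative")
    if n_speckles == 0:
        return volume, []
    free = np.ones(volume.shape, dtype=bool)
    if exclude_mask is not None:
        if exclude_mask.shape != volume.shape:
            raise ValueError("exclude_mask shape mismatch")
        # keep speckles clear of nuclei so they cannot merge into a component
        free &= ~ndimage.binary_dilation(exclude_mask, iterations=2)
    free_idx = np.argwhere(free)
    if len(free_idx) < n_speckles:
        raise ValueError("not enough free voxels for the requested speckle count")
    rng = np.random.default_rng(seed)
    chosen = free_idx[rng.choice(len(free_idx), size=n_speckles, replace=False)]
    data = np.asarray(volume.data, dtype=float).copy()
    data[tuple(chosen.T)] += amplitude
    return volume.with_data(data), [tuple(int(i) for i in c) for c in chosen]


def make_ground_truth_transform(rotation_deg=(0.0, 0.0, 0.0), scale=(1.0, 1.0, 1.0),
                                translation_um=(0.0, 0.0, 0.0),
                                warp_amplitude_um: float = 0.0,
                                warp_smoothness_um: float = 100.0, seed: int = 0,
                                grid_shape=(40, 40, 40), grid_spacing_um: float = 10.0
                                ) -> TransformChain:
    """A known affine + smooth random deformation between atlas and sample spaces.

    The affine is the forward (atlas->sample) map; the displacement field is
    smooth Gaussian-filtered noise on the atlas grid, rescaled so its largest
    vector has length ``warp_amplitude_um``.  Parameter bounds keep the
    composite map invertible in practice.
    """
    rot = np.asarray(rotation_deg, dtype=float)
    sc = np.asarray(scale, dtype=float)
    if np.any(np.abs(rot) > 20):
        raise ValueError("|rotation| must be <= 20 degrees")
    if np.any(sc < 0.8) or np.any(sc > 1.25):
        raise ValueError("scale must lie in [0.8, 1.25]")
    if warp_amplitude_um > 5 * grid_spacing_um:
        raise ValueError("warp amplitude above 5 voxels breaks invertibility")
    r = np.deg2rad(rot)
    cx, sx = np.cos(r[0]), np.sin(r[0])
    cy, sy = np.cos(r[1]), np.sin(r[1])
    cz, sz = np.cos(r[2]), np.sin(r[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    lin = Rx @ Ry @ Rz @ np.diag(sc)
    affine = AffineTransform(lin, np.asarray(translation_um, dtype=float), "atlas->sample")

    field = None
    if warp_amplitude_um > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=tuple(grid_shape) + (3,))
        sigma_vox = warp_smoothness_um / grid_spacing_um
        for c in range(3):
            noise[..., c] = ndimage.gaussian_filter(noise[..., c], sigma_vox)
        mags = np.linalg.norm(noise, axis=-1)
        peak = mags.max()
        if peak > 0:
            noise *= warp_amplitude_um / peak
        field = DeformationField(noise, grid_spacing_um)
    return TransformChain(affine=affine, field=field)
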