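"""Synthetic brightfield scenes with paired ground truth.

Generates scenes that emulate dried *Bacillus* spores (small,
near-circular, phase-dense) and outgrowing vegetative cells (larger,
elongated rods) on a noisy, unevenly illuminated background, together
with the exact polygon annotations and binary masks a real annotated
dataset would provide.  Every other stage of the pipeline (annotation
rasterization, preprocessing, training, evaluation, particle counting)
can therefore be exercised offline with known truth.

Morphometry defaults match the germination assay this package targets,
at 16.5 px/um:

* dormant spores: area median 1.11 um^2 (5-95%: 0.6-1.97),
  circularity median 0.86 (5-95%: 0.71-0.93);
* outgrown cells: area median 3.73 um^2 (5-95%: 0.33-10.06),
  circularity median 0.58 (5-95%: 0.30-0.90).

Areas are drawn from a lognormal parametrized to hit the stated median
and 5-95% range (a truncated-normal option is available for the
near-normal spore-area distribution); circularities from a logit-normal
fitted the same way, which keeps draws inside (0, 1).

Scenes also contain debris - irregular low-circularity blobs rendered
into the image but EXCLUDED from the ground-truth mask - so
false-positive behaviour of downstream filters can be measured.  What
the generator does not emulate: physical optics (point-spread function,
defocus), frame-to-frame continuity of a timelapse.  A
``contrast_polarity`` switch flips objects from dark-on-light to
bright-on-light, mimicking the contrast inversion seen under focus
drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io_annotation import (
    BinaryMask,
    GrayImage,
    PolygonAnnotation,
    polygons_to_mask,
    write_annotations,
    write_image,
    write_mask,
)
from .particle_analysis import Particle, label_particles

__all__ = [
    "SceneSpec",
    "Scene",
    "t0_spec",
    "t120_spec",
    "sample_spore_shape",
    "sample_cell_shape",
    "render_scene",
    "make_dataset",
    "make_training_arrays",
]

_Z95 = 1.6448536269514722  # standard-normal 95th percentile


def _lognormal_params(median: float, p5: float, p95: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal matching the median and the 5-95% span
    (the range ratio sets sigma; the median sets mu)."""
    return np.log(median), np.log(p95 / p5) / (2.0 * _Z95)


def _logitnormal_params(median: float, p5: float, p95: float) -> tuple[float, float]:
    return logit(median), (logit(p95) - logit(p5)) / (2.0 * _Z95)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Distribution fields are ``(median, p5, p95)`` triples in um^2 (areas)
    or dimensionless (circularities).  ``noise_sd`` is the additive
    Gaussian noise sigma in 8-bit intensity units;
    ``illumination_gradient`` the peak-to-centre amplitude of the smooth
    background ramp; ``debris_rate`` the Poisson mean count of debris
    blobs per scene.  ``max_overlap`` is the largest fraction of a new
    object's pixels allowed to land on already-occupied pixels.
    """

    image_size: tuple[int, int] = (512, 512)
    px_per_um: float = 16.5
    n_spores: int = 40
    n_cells: int = 0
    spore_area_um2: tuple[float, float, float] = (1.11, 0.6, 1.97)
    spore_circularity: tuple[float, float, float] = (0.86, 0.71, 0.93)
    cell_area_um2: tuple[float, float, float] = (3.73, 0.33, 10.06)
    cell_circularity: tuple[float, float, float] = (0.58, 0.30, 0.90)
    spore_area_family: str = "lognormal"  # or "truncnorm"
    noise_sd: float = 6.0
    illumination_gradient: float = 15.0
    debris_rate: float = 3.0
    contrast_polarity: int = 1  # +1: dark objects (in focus); -1: bright
    max_overlap: float = 0.0
    min_separation_px: int = 0  # >0 forbids contact merges between objects
    background_level: float = 170.0
    seed: int = 0

    def __post_init__(self):
        self.image_size = tuple(self.image_size)
        if self.n_spores < 0 or self.n_cells < 0 or self.debris_rate < 0:
            raise ValueError("object counts must be non-negative")
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")
        for name in ("spore_area_um2", "spore_circularity",
                     "cell_area_um2", "cell_circularity"):
            med, p5, p95 = getattr(self, name)
            if not (0 < p5 <= med <= p95):
                raise ValueError(f"{name} must satisfy 0 < p5 <= median <= p95")


def t0_spec(**overrides) -> SceneSpec:
    """Pre-incubation scene: dormant spores only."""
    return SceneSpec(**{"n_spores": 40, "n_cells": 0, **overrides})


def t120_spec(**overrides) -> SceneSpec:
    """Post-incubation scene: a mix of remaining spores and outgrown cells."""
    return SceneSpec(**{"n_spores": 8, "n_cells": 32, **overrides})


@dataclass
class Scene:
    """A rendered frame with its complete ground truth."""

    image: GrayImage
    mask: BinaryMask
    annotations: list[PolygonAnnotation]
    truth_particles: list[Particle]
    n_placed: int
    n_merged: int  # placed objects fused into one mask component by contact
    spec: SceneSpec = field(repr=False, default=None)


# -- shape sampling ---------------------------------------------------

def _ellipse_circularity(q: float) -> float:
    """Circularity of an ellipse with axis ratio q = b/a (Ramanujan
    perimeter approximation)."""
    a, b = 1.0, q
    p = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    return 4 * np.pi * (np.pi * a * b) / p**2

def _capsule_circularity(t: float) -> float:
    """Circularity of a capsule (rectangle + semicircular caps) with
    elongation t = straight length / width."""
    area = t + np.pi / 4.0
    perim = 2.0 * t + np.pi
    return 4 * np.pi * area / perim**2


def _draw_area_px(spec: SceneSpec, params: tuple[float, float, float],
                  family: str, rng: np.random.Generator) -> float:
    med, p5, p95 = params
    if family == "truncnorm":
        sd = (p95 - p5) / (2.0 * _Z95)
        while True:
            a = rng.normal(med, sd)
            if a > 0.05:
                return a * spec.px_per_um**2
    mu, sigma = _lognormal_params(med, p5, p95)
    return float(np.exp(rng.normal(mu, sigma))) * spec.px_per_um**2


def _draw_circularity(params: tuple[float, float, float],
                      rng: np.random.Generator) -> float:
    mu, sigma = _logitnormal_params(*params)
    return float(expit(rng.normal(mu, sigma)))


def _rotate(verts: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return verts @ np.array([[c, -s], [s, c]]).T


def sample_spore_shape(spec: SceneSpec, rng: np.random.Generator,
                       n_vertices: int = 48) -> np.ndarray:
    """Sample one dormant-spore outline: an ellipse polygon, centred at
    the origin, whose area and circularity are draws from the spore
    distributions (axis ratio solved from the circularity target)."""
    area_px = _draw_area_px(spec, spec.spore_area_um2, spec.spore_area_family, rng)
    circ = _draw_circularity(spec.spore_circularity, rng)
    if circ >= _ellipse_circularity(1.0 - 1e-9):
        q = 1.0
    else:
        q = brentq(lambda qq: _ellipse_circularity(qq) - circ, 1e-3, 1.0)
    a = np.sqrt(area_px / (np.pi * q))
    b = q * a
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    return _rotate(verts, rng.uniform(0, np.pi))


def sample_cell_shape(spec: SceneSpec, rng: np.random.Generator,
                      n_arc: int = 24) -> np.ndarray:
    """Sample one outgrown-cell outline: a rod/capsule polygon (straight
    section with semicircular caps), centred at the origin, with area
    and circularity drawn from the cell distributions."""
    area_px = _draw_area_px(spec, spec.cell_area_um2, "lognormal", rng)
    circ = _draw_circularity(spec.cell_circularity, rng)
    if circ >= 1.0 - 1e-9:
        t = 0.0
    else:
        t = brentq(lambda tt: _capsule_circularity(tt) - circ, 0.0, 500.0)
    w = np.sqrt(area_px / (t + np.pi / 4.0))
    half_l, r = t * w / 2.0, w / 2.0
    th_right = np.linspace(-np.pi / 2, np.pi / 2, n_arc)
    th_left = np.linspace(np.pi / 2, 3 * np.pi / 2, n_arc)
    right = np.column_stack([half_l + r * np.cos(th_right), r * np.sin(th_right)])
    left = np.column_stack([-half_l + r * np.cos(th_left), r * np.sin(th_left)])
    return _rotate(np.vstack([right, left]), rng.uniform(0, np.pi))


# -- scene rendering --------------------------------------------------

def _place_objects(spec: SceneSpec, rng: np.random.Generator):
    """Place spore and cell polygons without exceeding the overlap limit.

    Returns (annotations, per-object masks).  Raises RuntimeError when an
    object cannot be placed within the retry budget.
    """
    h, w = spec.image_size
    occupied = np.zeros((h, w), dtype=bool)
    annotations: list[PolygonAnnotation] = []
    obj_masks: list[np.ndarray] = []
    kinds = ["spore"] * spec.n_spores + ["cell"] * spec.n_cells
    for kind in kinds:
        for _ in range(300):
            verts = (
                sample_spore_shape(spec, rng)
                if kind == "spore"
                else sample_cell_shape(spec, rng)
            )
            ext_x = verts[:, 0].max() - verts[:, 0].min()
            ext_y = verts[:, 1].max() - verts[:, 1].min()
            if ext_x > w - 4 or ext_y > h - 4:
                continue
            cx = rng.uniform(1 - verts[:, 0].min(), w - 2 - verts[:, 0].max())
            cy = rng.uniform(1 - verts[:, 1].min(), h - 2 - verts[:, 1].max())
            shifted = verts + np.array([cx, cy])
            ann = PolygonAnnotation(label=kind, vertices=shifted)
            obj = polygons_to_mask([ann], (h, w)).pixels
            n_obj = obj.sum()
            if n_obj == 0:
                continue
            footprint = obj
            if spec.min_separation_px > 0:
                footprint = ndimage.binary_dilation(
                    obj, structure=np.ones((3, 3), dtype=bool),
                    iterations=spec.min_separation_px,
                )
            if (footprint & occupied).sum() > spec.max_overlap * n_obj:
                continue
            occupied |= obj
            annotations.append(ann)
            obj_masks.append(obj)
            break
        else:
            raise RuntimeError(
                f"could not place {kind} within retry budget at "
                f"max_overlap={spec.max_overlap}"
            )
    return annotations, obj_masks


def _debris_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Irregular low-circularity blobs: short random walks of small disks."""
    h, w = spec.image_size
    out = np.zeros((h, w), dtype=bool)
    n = rng.poisson(spec.debris_rate)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n):
        x, y = rng.uniform(5, w - 5), rng.uniform(5, h - 5)
        for _ in range(rng.integers(3, 9)):
            r = rng.uniform(1.0, 2.5)
            out |= (xx - x) ** 2 + (yy - y) ** 2 <= r**2
            step = rng.normal(0, 2.5, size=2)
            x = np.clip(x + step[0], 2, w - 3)
            y = np.clip(y + step[1], 2, h - 3)
    return out


def render_scene(spec: SceneSpec) -> Scene:
    """Render one brightfield-like scene, fully determined by the seed.

    Background sits at mid-gray with a smooth illumination ramp; objects
    are rendered darker than background with a brighter rim
    (``contrast_polarity=-1`` inverts them); debris is drawn into the
    image but excluded from the mask; additive Gaussian noise last.
    The returned mask is exactly the union of the rasterized
    annotations.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    annotations, obj_masks = _place_objects(spec, rng)
    mask = np.zeros((h, w), dtype=bool)
    for m in obj_masks:
        mask |= m

    # background with a smooth illumination ramp of random direction
    yy, xx = np.mgrid[0:h, 0:w]
    phi = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(phi) * (xx / max(w - 1, 1) - 0.5)
            + np.sin(phi) * (yy / max(h - 1, 1) - 0.5))
    img = spec.background_level + spec.illumination_gradient * 2 * ramp

    pol = float(spec.contrast_polarity)
    for m in obj_masks:
        interior = ndimage.binary_erosion(m)
        rim = m & ~interior
        depth = rng.normal(55.0, 6.0)
        img[interior] -= pol * depth
        img[rim] += pol * 18.0

    debris = _debris_mask(spec, rng) & ~mask
    img[debris] -= pol * rng.normal(28.0, 4.0)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    bmask = BinaryMask(mask)
    particles = label_particles(bmask, px_per_um=spec.px_per_um)
    return Scene(
        image=GrayImage(img, px_per_um=spec.px_per_um),
        mask=bmask,
        annotations=annotations,
        truth_particles=particles,
        n_placed=len(annotations),
        n_merged=len(annotations) - len(particles),
        spec=spec,
    )


def make_dataset(
    spec_t0: SceneSpec,
    spec_t120: SceneSpec,
    n_scenes: int,
    out: str | Path,
) -> dict:
    """Write paired image/mask/annotation files for the two assay time
    points plus a manifest of seeds and truth statistics.

    Scene i of a time point uses seed ``spec.seed + i``; regenerating
    from the manifest seeds reproduces the files exactly.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"n_scenes": n_scenes, "timepoints": {}}
    for name, spec in (("t0", spec_t0), ("t120", spec_t120)):
        # normalize tuples to lists so the manifest round-trips through JSON
        spec_dict = json.loads(json.dumps(asdict(spec)))
        entries = []
        for i in range(n_scenes):
            scene_spec = SceneSpec(**{**asdict(spec), "seed": spec.seed + i})
            scene = render_scene(scene_spec)
            stem = f"{name}_{i:03d}"
            write_image(scene.image, out / f"{stem}_image.png")
            write_mask(scene.mask, out / f"{stem}_mask.png")
            write_annotations(scene.annotations, out / f"{stem}_annotations.json")
            entries.append(
                {
                    "stem": stem,
                    "seed": scene_spec.seed,
                    "n_placed": scene.n_placed,
                    "n_merged": scene.n_merged,
                    "n_truth_particles": len(scene.truth_particles),
                    "foreground_px": int(scene.mask.pixels.sum()),
                }
            )
        manifest["timepoints"][name] = {"spec": spec_dict, "scenes": entries}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def make_training_arrays(
    n_scenes: int,
    spec: SceneSpec,
    patch_size: int = 64,
    min_occupancy: float = 0.05,
    seed: int = 0,
    equalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render scenes, preprocess and cut occupancy-filtered patches.

    Returns float32 arrays ``(X, Y)`` of shape (n, patch, patch): network
    inputs in [-1, 1] and binary targets.
    """
    from .preprocessing import extract_patches, preprocess_frame

    xs, ys = [], []
    for i in range(n_scenes):
        scene = render_scene(SceneSpec(**{**asdict(spec), "seed": seed + i}))
        prepped = preprocess_frame(scene.image, equalize=equalize)
        for patch in extract_patches(prepped, scene.mask, size=patch_size,
                                     min_occupancy=min_occupancy):
            xs.append(patch.image.pixels.astype(np.float32))
            ys.append(patch.mask.pixels.astype(np.float32))
    if not xs:
        raise RuntimeError("no patches passed the occupancy filter")
    return np.stack(xs), np.stack(ys)
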