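"""Synthetic phantoms of hepatocyte lumina with complete ground truth.

No imaging data accompany the biological study this package operationalises,
so validation rests on phantoms: multi-channel images that emulate the two
lumen shapes at stake —

* **tubes**: bile-canaliculi-like lumina of ~1 µm radius, rendered as
  capsules (a centerline segment dilated by the tube radius, with
  hemispherical caps), optionally branched, carrying bright transverse
  *bulkhead* stripes at quasi-periodic spacing on the order of the lumen
  diameter, alternating the side of the tube they project from;
* **cysts**: spherical lumina of several µm radius, without stripes.

Capsule caps are a deliberate geometric choice: every interior point of a
capsule lies within ``tube_radius`` of the centerline, so the largest
inscribed circle through any interior point has exactly radius
``tube_radius`` — the ground-truth radius field is uniform and exact, not
approximate.  The same holds trivially for cysts.

Images are rendered as the mid-plane section of the 3D geometry when 2D
(the in vitro analysis of this pipeline is per-2D-image); full 3D rasters
are produced when ``image_size`` has three axes.  The actin channel is::

    background  everywhere
    interior    inside the lumen mask
    wall        on the 1-px inner boundary shell of the mask
    stripe      on transverse bulkhead planes, restricted to the outer
                ``bulkhead_depth`` fraction of the cross-section

Bulkhead stripes live in the intensity channel only; they never remove
pixels from the ground-truth mask, mirroring the biology (bulkheads cross
the lumen but never seal it into chambers).

Noise is Poisson–Gaussian (shot noise at ``noise_poisson_scale`` photons
per intensity unit, then additive Gaussian read noise), the standard
fluorescence-camera model; it is applied only by :func:`add_noise`.

Everything is a pure function of (parameters, seed): identical spec and
seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .raster import RasterImage

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "DatasetDesign",
    "ImageRecord",
    "PhantomDataset",
    "make_phantom",
    "add_noise",
    "make_gfp_channel",
    "make_dataset",
    "SizingError",
    "ConfigurationError",
]

_AXIS_NAMES = {2: ("y", "x"), 3: ("z", "y", "x")}


class SizingError(ValueError):
    """The requested object does not fit into image_size."""


class ConfigurationError(ValueError):
    """A dataset design is empty or inconsistent."""


@dataclass
class PhantomSpec:
    """Generative parameters for one phantom object.

    All lengths in µm; intensities in arbitrary fluorescence units.
    ``bulkhead_spacing = 0`` disables bulkheads; ``bulkhead_depth`` is the
    fraction of the lumen cross-section each bulkhead occludes and must stay
    below 1 (a bulkhead never separates the lumen into chambers).
    """

    shape_kind: str = "tube"  # tube | branched_tube | cyst
    image_size: Optional[Tuple[int, ...]] = None  # None = minimal auto fit
    spacing: Tuple[float, ...] = (0.1, 0.1)
    tube_radius: float = 1.0
    tube_length: float = 20.0
    branch_count: int = 0
    cyst_radius: float = 8.0
    bulkhead_spacing: float = 2.0
    bulkhead_jitter: float = 0.0
    bulkhead_depth: float = 0.7
    bulkhead_thickness: float = 0.3  # µm; plate thickness of the ridge
    wall_thickness: float = 0.2  # µm; cortical-actin shell (>= 1 px)
    wall_intensity: float = 100.0
    stripe_intensity: float = 100.0
    interior_intensity: float = 40.0
    background_intensity: float = 10.0
    noise_gaussian_sd: float = 0.0
    noise_poisson_scale: float = 0.0
    gfp_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_kind not in ("tube", "branched_tube", "cyst"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if not (0 <= self.bulkhead_depth < 1):
            raise ValueError("bulkhead_depth must lie in [0, 1)")
        if self.tube_radius <= 0 or self.cyst_radius <= 0:
            raise ValueError("radii must be strictly positive")
        if self.bulkhead_spacing < 0 or self.bulkhead_jitter < 0:
            raise ValueError("bulkhead spacing/jitter must be non-negative")
        if self.noise_gaussian_sd < 0 or self.noise_poisson_scale < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (0 <= self.gfp_fraction <= 1):
            raise ValueError("gfp_fraction must lie in [0, 1]")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.branch_count < 0:
            raise ValueError("branch_count must be >= 0")


@dataclass
class PhantomTruth:
    """Exact ground truth for one generated object."""

    mask: np.ndarray  # bool, lumen interior (incl. wall shell)
    radius_field: np.ndarray  # µm, true inscribed-circle radius per pixel
    bulkhead_positions: np.ndarray  # arclength µm along the main centerline
    centerline: np.ndarray  # ordered (n, ndim) pixel coordinates (float)
    object_id: int = 1


# ---------------------------------------------------------------------------
# geometry helpers (physical coordinates = pixel index * spacing)

def _segments(spec: PhantomSpec, ndim: int):
    """Centerline segments [(a, b), ...] in µm; first one is the main axis.

    The main tube runs along the last (x) axis; branches leave it at ±45° in
    the y–x plane, alternating sides.
    """
    if spec.shape_kind == "cyst":
        return []
    L = spec.tube_length
    main = (np.zeros(ndim), np.zeros(ndim))
    main[1][-1] = L
    segs = [main]
    if spec.shape_kind == "branched_tube" and spec.branch_count > 0:
        bl = L / 2.0
        d = 1.0 / np.sqrt(2.0)
        for i in range(spec.branch_count):
            t = (i + 1) / (spec.branch_count + 1)
            a = np.zeros(ndim)
            a[-1] = t * L
            direction = np.zeros(ndim)
            direction[-1] = d
            direction[-2] = d if i % 2 == 0 else -d
            segs.append((a, a + bl * direction))
    return segs


def _dist_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a[None, :] + t[:, None] * ab[None, :]
    return np.linalg.norm(points - proj, axis=-1)


def _geometry_extent(spec: PhantomSpec, ndim: int):
    """(lo, hi) physical bounding box of the object, in µm, origin at main-axis start."""
    if spec.shape_kind == "cyst":
        r = spec.cyst_radius
        return -r * np.ones(ndim), r * np.ones(ndim)
    segs = _segments(spec, ndim)
    pts = np.array([p for seg in segs for p in seg])
    return pts.min(axis=0) - spec.tube_radius, pts.max(axis=0) + spec.tube_radius


def _minimal_size(spec: PhantomSpec, ndim: int, margin_px: int = 3) -> Tuple[int, ...]:
    lo, hi = _geometry_extent(spec, ndim)
    sp = np.asarray(spec.spacing, dtype=float)
    return tuple(int(np.ceil((hi[k] - lo[k]) / sp[k])) + 2 * margin_px + 1
                 for k in range(ndim))


def _bulkhead_positions(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Arclength positions (µm) of bulkheads along the main centerline.

    Nominal positions are multiples of ``bulkhead_spacing`` strictly inside
    (0, tube_length); jitter adds Gaussian displacement with standard
    deviation ``bulkhead_jitter · bulkhead_spacing``.
    """
    if spec.shape_kind == "cyst" or spec.bulkhead_spacing <= 0:
        return np.empty(0)
    d = spec.bulkhead_spacing
    n = int(np.ceil(spec.tube_length / d - 1e-9)) - 1
    if n <= 0:
        return np.empty(0)
    pos = d * np.arange(1, n + 1, dtype=float)
    if spec.bulkhead_jitter > 0:
        pos = pos + rng.normal(0.0, spec.bulkhead_jitter * d, size=n)
        pos = np.sort(np.clip(pos, 0.25 * d, spec.tube_length - 0.25 * d))
    return pos


def make_phantom(
    spec: PhantomSpec, object_id: int = 1
) -> Tuple[RasterImage, PhantomTruth]:
    """Render one phantom object and its exact ground truth.

    Returns a noise-free image with a single ``actin`` channel (noise is
    applied separately by :func:`add_noise`) and the :class:`PhantomTruth`.
    Raises :class:`SizingError`, naming the offending axis, if the object
    plus a 2-pixel background margin does not fit into ``image_size``.
    """
    ndim = len(spec.spacing)
    if ndim not in (2, 3):
        raise ValueError("spacing must have 2 or 3 axes")
    size = spec.image_size if spec.image_size is not None else _minimal_size(spec, ndim)
    size = tuple(int(n) for n in size)
    if len(size) != ndim:
        raise ValueError("image_size and spacing must have the same length")
    sp = np.asarray(spec.spacing, dtype=float)
    extent = (np.asarray(size) - 1) * sp

    lo, hi = _geometry_extent(spec, ndim)
    span = hi - lo
    for k in range(ndim):
        if span[k] + 4 * sp[k] > extent[k]:
            name = _AXIS_NAMES[ndim][k]
            raise SizingError(
                f"object extent {span[k]:.2f} µm plus margin exceeds image "
                f"axis {k} ({name}: {extent[k]:.2f} µm)"
            )
    # place the object's bounding box centred in the canvas
    origin = (extent - span) / 2.0 - lo  # physical coord of geometry origin

    idx = np.indices(size).reshape(ndim, -1).T
    coords = idx * sp - origin  # physical µm in geometry frame

    rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 11)))

    if spec.shape_kind == "cyst":
        dist = np.linalg.norm(coords, axis=-1)
        mask = (dist <= spec.cyst_radius).reshape(size)
        true_r = spec.cyst_radius
        centerline = np.empty((0, ndim))
        bulkheads = np.empty(0)
    else:
        segs = _segments(spec, ndim)
        dist = np.min(
            np.stack([_dist_to_segment(coords, a, b) for a, b in segs]), axis=0
        )
        mask = (dist <= spec.tube_radius).reshape(size)
        true_r = spec.tube_radius
        step = float(sp[-1])
        n_pts = int(np.floor(spec.tube_length / step)) + 1
        arc = np.arange(n_pts) * step
        centerline = np.tile(origin / sp, (n_pts, 1))
        centerline[:, -1] = (origin[-1] + arc) / sp[-1]
        bulkheads = _bulkhead_positions(spec, rng)

    radius_field = np.where(mask, true_r, 0.0)

    actin = np.full(size, spec.background_intensity, dtype=float)
    actin[mask] = spec.interior_intensity
    n_erode = max(1, int(round(spec.wall_thickness / float(sp.min()))))
    shell = mask & ~ndimage.binary_erosion(mask, iterations=n_erode)
    actin[shell] = spec.wall_intensity

    if bulkheads.size and spec.bulkhead_depth > 0:
        x_phys = idx[:, -1].reshape(size) * sp[-1] - origin[-1]
        u = idx[:, -2].reshape(size) * sp[-2] - origin[-2]  # transverse coord
        R = spec.tube_radius
        half = max(spec.bulkhead_thickness / 2.0, float(sp[-1]) / 2.0)
        for k, s in enumerate(bulkheads):
            plane = np.abs(x_phys - s) <= half
            if k % 2 == 0:  # from the top (small y)
                side = u <= -R + 2.0 * R * spec.bulkhead_depth
            else:  # from the bottom
                side = u >= R - 2.0 * R * spec.bulkhead_depth
            actin[plane & side & mask] = spec.stripe_intensity

    image = RasterImage(
        data=actin[None],
        channels={"actin": 0},
        spacing=tuple(sp.tolist()),
        provenance=[f"phantom {spec.shape_kind} seed={spec.seed}"],
    )
    truth = PhantomTruth(
        mask=mask,
        radius_field=radius_field,
        bulkhead_positions=bulkheads,
        centerline=centerline,
        object_id=object_id,
    )
    return image, truth


def add_noise(image: RasterImage, spec: PhantomSpec) -> RasterImage:
    """Apply the Poisson–Gaussian camera model to every channel.

    With ``noise_poisson_scale > 0`` intensities are resampled as
    ``Poisson(I·scale)/scale`` (shot noise), then Gaussian read noise of
    standard deviation ``noise_gaussian_sd`` is added.  Both off → the data
    pass through unchanged.  Deterministic under ``spec.seed``.
    """
    if spec.noise_gaussian_sd < 0 or spec.noise_poisson_scale < 0:
        raise ValueError("noise parameters must be non-negative")
    if spec.noise_gaussian_sd == 0 and spec.noise_poisson_scale == 0:
        return image
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 13)))
    data = np.asarray(image.data, dtype=float)
    if data.min() < 0:
        raise ValueError("add_noise requires non-negative intensities")
    out = data
    if spec.noise_poisson_scale > 0:
        out = rng.poisson(out * spec.noise_poisson_scale) / spec.noise_poisson_scale
    if spec.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.noise_gaussian_sd, size=out.shape)
    return replace(
        image,
        data=out,
        channels=dict(image.channels),
        provenance=[*image.provenance,
                    f"noise poisson_scale={spec.noise_poisson_scale} "
                    f"gaussian_sd={spec.noise_gaussian_sd} seed={spec.seed}"],
    )


def make_gfp_channel(
    truth_list: Sequence[PhantomTruth],
    gfp_fraction: float,
    seed: int,
    shape: Optional[Tuple[int, ...]] = None,
) -> Tuple[np.ndarray, List[bool]]:
    """Binary rescue-marker channel covering a random subset of objects.

    Exactly ``round(n · gfp_fraction)`` objects are marked positive; each
    positive object's mask, dilated by one pixel, is set in the channel.
    Returns the channel and the per-object positivity flags (in input order).
    """
    if not (0 <= gfp_fraction <= 1):
        raise ValueError("gfp_fraction must lie in [0, 1]")
    if shape is None:
        if not truth_list:
            raise ValueError("need shape when truth_list is empty")
        shape = truth_list[0].mask.shape
    channel = np.zeros(shape, dtype=bool)
    n = len(truth_list)
    n_pos = int(round(n * gfp_fraction))
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 17)))
    positive = set(rng.choice(n, size=n_pos, replace=False).tolist()) if n else set()
    flags = []
    for i, truth in enumerate(truth_list):
        flag = i in positive
        flags.append(flag)
        if flag:
            channel |= ndimage.binary_dilation(truth.mask)
    return channel, flags


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class DatasetDesign:
    """Replicate structure and object mixtures of a phantom study.

    The default layout mirrors the biological study this pipeline targets:
    ``n_experiments = 3`` independent experiments with
    ``images_per_condition = 4`` images each, a control condition of pure
    ~1 µm tubes and a knockdown condition where a fraction of objects are
    large cysts (7–9 µm).  ``snr`` is the wall-to-background contrast over
    the Gaussian noise sd.
    """

    conditions: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "control": {"tube": 1.0},
            "knockdown": {"tube": 0.8, "cyst": 0.2},
        }
    )
    n_experiments: int = 3
    images_per_condition: int = 4
    objects_per_image: int = 5
    image_size: Tuple[int, ...] = (384, 384)
    spacing: Tuple[float, ...] = (0.2, 0.2)
    tube_radius: float = 1.0
    tube_length: float = 20.0
    bulkhead_spacing: float = 2.0
    bulkhead_jitter: float = 0.1
    bulkhead_depth: float = 0.7
    cyst_radius_range: Tuple[float, float] = (7.0, 9.0)
    wall_intensity: float = 100.0
    stripe_intensity: float = 100.0
    interior_intensity: float = 40.0
    background_intensity: float = 10.0
    snr: float = 10.0
    noise_poisson_scale: float = 0.0
    gfp_fraction: Dict[str, float] = field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigurationError("design lists no conditions")
        for name, mix in self.conditions.items():
            if not mix or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"condition {name!r}: object mixture must sum to 1"
                )
            unknown = set(mix) - {"tube", "cyst"}
            if unknown:
                raise ConfigurationError(f"unknown object kinds {unknown}")
        if self.n_experiments < 1 or self.images_per_condition < 1:
            raise ConfigurationError("need >= 1 experiment and image")

    @property
    def noise_gaussian_sd(self) -> float:
        contrast = self.wall_intensity - self.background_intensity
        return 0.0 if self.snr <= 0 else contrast / self.snr


@dataclass
class ImageRecord:
    """One generated image with its ground truth and bookkeeping."""

    image: RasterImage
    truth_labels: np.ndarray  # int canvas, object ids
    truth_radius: np.ndarray  # µm canvas
    objects: List[Dict]  # id, kind, true_radius, n_bulkheads, gfp, truth
    condition: str
    experiment: int
    index: int
    seed: int


@dataclass
class PhantomDataset:
    design: DatasetDesign
    images: List[ImageRecord]

    def manifest(self):
        """Tidy per-object table (one row per generated object)."""
        import pandas as pd

        rows = []
        for rec in self.images:
            for obj in rec.objects:
                rows.append({
                    "condition": rec.condition,
                    "experiment": rec.experiment,
                    "image": rec.index,
                    "seed": rec.seed,
                    "object_id": obj["id"],
                    "kind": obj["kind"],
                    "true_radius_um": obj["true_radius"],
                    "bulkhead_spacing_um": obj["bulkhead_spacing"],
                    "n_bulkheads": obj["n_bulkheads"],
                    "gfp": obj["gfp"],
                })
        return pd.DataFrame(rows)


def _image_seed(master: int, cond_idx: int, exp: int, img: int) -> int:
    ss = np.random.SeedSequence((int(master), cond_idx, exp, img))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _object_counts(mix: Dict[str, float], k: int) -> Dict[str, int]:
    """Largest-remainder rounding of mixture proportions to k objects."""
    kinds = sorted(mix)
    raw = {m: mix[m] * k for m in kinds}
    counts = {m: int(np.floor(raw[m])) for m in kinds}
    rem = k - sum(counts.values())
    for m in sorted(kinds, key=lambda m: raw[m] - counts[m], reverse=True)[:rem]:
        counts[m] += 1
    return counts


def _pack(sizes: List[Tuple[int, int]], canvas: Tuple[int, int], gap: int,
          rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Shelf-pack local grids into the canvas; returns top-left corners."""
    order = rng.permutation(len(sizes))
    corners: List[Optional[Tuple[int, int]]] = [None] * len(sizes)
    y = gap
    x = gap
    row_h = 0
    for i in order:
        h, w = sizes[i]
        if x + w + gap > canvas[1]:
            y += row_h + gap
            x = gap
            row_h = 0
        if y + h + gap > canvas[0] or x + w + gap > canvas[1]:
            raise SizingError(
                f"objects do not fit into canvas {canvas} (axis y overflow)"
            )
        slack = canvas[1] - gap - (x + w)
        jitter = int(rng.integers(0, min(slack, 2 * gap) + 1)) if slack > 0 else 0
        corners[i] = (y, x + jitter)
        x += w + gap + jitter
        row_h = max(row_h, h)
    return corners  # type: ignore[return-value]


def make_dataset(design: DatasetDesign) -> PhantomDataset:
    """Generate the full replicate-structured phantom dataset.

    A pure function of (design, master_seed): per-image seeds are derived
    from ``(master_seed, condition index, experiment, image)``, so the whole
    dataset — manifest and pixel data — is reproducible bit for bit.
    """
    if len(design.image_size) != 2:
        raise ConfigurationError("dataset assembly renders 2D images")
    images: List[ImageRecord] = []
    cond_names = sorted(design.conditions)
    for cond_idx, cond in enumerate(cond_names):
        mix = design.conditions[cond]
        for exp in range(design.n_experiments):
            for img_idx in range(design.images_per_condition):
                seed = _image_seed(design.master_seed, cond_idx, exp, img_idx)
                images.append(
                    _render_image(design, cond, mix, exp, img_idx, seed)
                )
    return PhantomDataset(design=design, images=images)


def _render_image(design: DatasetDesign, cond: str, mix: Dict[str, float],
                  exp: int, img_idx: int, seed: int) -> ImageRecord:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 19)))
    counts = _object_counts(mix, design.objects_per_image)
    kinds = [k for k in sorted(counts) for _ in range(counts[k])]
    rng.shuffle(kinds)

    sp = np.asarray(design.spacing, dtype=float)
    specs: List[PhantomSpec] = []
    sizes: List[Tuple[int, int]] = []
    for i, kind in enumerate(kinds):
        if kind == "cyst":
            r = float(rng.uniform(*design.cyst_radius_range))
            spec = PhantomSpec(
                shape_kind="cyst", spacing=design.spacing, cyst_radius=r,
                bulkhead_spacing=0.0,
                wall_intensity=design.wall_intensity,
                stripe_intensity=design.stripe_intensity,
                interior_intensity=design.interior_intensity,
                background_intensity=design.background_intensity,
                seed=seed * 31 + i,
            )
        else:
            spec = PhantomSpec(
                shape_kind="tube", spacing=design.spacing,
                tube_radius=design.tube_radius,
                tube_length=design.tube_length,
                bulkhead_spacing=design.bulkhead_spacing,
                bulkhead_jitter=design.bulkhead_jitter,
                bulkhead_depth=design.bulkhead_depth,
                wall_intensity=design.wall_intensity,
                stripe_intensity=design.stripe_intensity,
                interior_intensity=design.interior_intensity,
                background_intensity=design.background_intensity,
                seed=seed * 31 + i,
            )
        specs.append(spec)
        sizes.append(tuple(_minimal_size(spec, 2)))  # type: ignore[arg-type]

    corners = _pack(sizes, tuple(design.image_size), gap=3, rng=rng)

    canvas = np.full(design.image_size, design.background_intensity, dtype=float)
    labels = np.zeros(design.image_size, dtype=np.int32)
    radius = np.zeros(design.image_size, dtype=float)
    objects: List[Dict] = []
    truths: List[PhantomTruth] = []
    for i, (spec, size, corner) in enumerate(zip(specs, sizes, corners)):
        local_img, local_truth = make_phantom(
            replace(spec, image_size=size), object_id=i + 1
        )
        sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
        np.maximum(canvas[sl], local_img.channel("actin"), out=canvas[sl])
        labels[sl][local_truth.mask] = i + 1
        radius[sl][local_truth.mask] = local_truth.radius_field[local_truth.mask]
        full_mask = np.zeros(design.image_size, dtype=bool)
        full_mask[sl] = local_truth.mask
        truths.append(replace(local_truth, mask=full_mask))
        objects.append({
            "id": i + 1,
            "kind": spec.shape_kind,
            "true_radius": spec.cyst_radius if spec.shape_kind == "cyst"
            else spec.tube_radius,
            "bulkhead_spacing": spec.bulkhead_spacing
            if spec.shape_kind != "cyst" else 0.0,
            "n_bulkheads": int(local_truth.bulkhead_positions.size),
            "gfp": False,
            "truth": truths[-1],
        })

    channels = {"actin": 0}
    data = [canvas]
    gfrac = design.gfp_fraction.get(cond, 0.0) if isinstance(
        design.gfp_fraction, dict) else float(design.gfp_fraction)
    if gfrac > 0:
        gfp, flags = make_gfp_channel(truths, gfrac, seed)
        for obj, flag in zip(objects, flags):
            obj["gfp"] = bool(flag)
        channels["gfp"] = 1
        data.append(gfp.astype(float))

    image = RasterImage(
        data=np.stack(data),
        channels=channels,
        spacing=tuple(sp.tolist()),
        provenance=[f"phantom dataset cond={cond} exp={exp} img={img_idx} seed={seed}"],
    )
    noise_spec = PhantomSpec(
        spacing=design.spacing,
        noise_gaussian_sd=design.noise_gaussian_sd,
        noise_poisson_scale=design.noise_poisson_scale,
        seed=seed,
    )
    noisy = add_noise(image, noise_spec)
    if "gfp" in channels:  # the marker channel stays binary
        noisy = noisy.with_channel_data("gfp", data[1], "gfp kept noise-free")
    return ImageRecord(
        image=noisy, truth_labels=labels, truth_radius=radius,
        objects=objects, condition=cond, experiment=exp, index=img_idx,
        seed=seed,
    )
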