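"""Seeded synthetic micrographs of phage-infected rod-shaped bacteria.

Renders 2-D multi-channel fields of view that emulate widefield images of
*Pseudomonas* cells during jumbo-phage infection: each cell is a
spherocylinder (a rectangle capped by two semicircles) of fluorophore
density, and an infected cell additionally carries a circular "phage
nucleus" placed along the cell axis.  Channels follow the fixed order
``(GFP, DAPI, membrane)``:

* GFP — a cytoplasmic reporter whose in-nucleus density is
  ``gfp_contrast`` times the cytoplasmic density (>1 imported, <1
  excluded, =1 uniform);
* DAPI — dim cytoplasmic DNA plus, in infected cells, a bright circular
  nucleus focus;
* membrane — a one-pixel cell outline, standing in for a lipophilic stain
  such as FM4-64.

The optical train is an isotropic Gaussian PSF followed by a standard
camera model (Poisson shot noise, constant offset, Gaussian read noise).
Every scene is generated from an explicit :class:`SceneSpec`, so identical
specs (including the seed) produce bit-identical images, and the renderer
returns pixel-level :class:`GroundTruth` against which every downstream
stage can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage as ndi

from .errors import ConfigError, GeometryError, OverlapError

CHANNELS = ("gfp", "dapi", "membrane")
PHENOTYPES = ("imported", "excluded", "uniform")

#: default in-nucleus / cytoplasm GFP density ratios per phenotype
PHENOTYPE_CONTRAST = {"imported": 3.0, "excluded": 0.2, "uniform": 1.0}


@dataclass
class OpticsModel:
    """Imaging and camera parameters.

    ``pixel_size_nm`` and ``psf_sigma_nm`` set the spatial scale (defaults
    emulate a 100x widefield system sampled at 65 nm/px with a ~130 nm
    Gaussian PSF).  ``photon_scale`` converts emitter density to expected
    camera counts; ``camera_offset`` and ``read_noise_sd`` are the usual
    sCMOS/CCD offset and Gaussian read noise.  With ``noise=False`` the
    renderer returns the expected counts (offset included) as floats — the
    infinite-photon limit used by the noiseless tests.
    """

    pixel_size_nm: float = 65.0
    psf_sigma_nm: float = 130.0
    camera_offset: float = 100.0
    read_noise_sd: float = 10.0
    photon_scale: float = 200.0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ConfigError("pixel_size_nm must be > 0")
        if self.psf_sigma_nm < 0 or self.read_noise_sd < 0:
            raise ConfigError("psf_sigma_nm and read_noise_sd must be >= 0")
        if self.photon_scale <= 0:
            raise ConfigError("photon_scale must be > 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm


@dataclass
class CellSpec:
    """One synthetic cell.

    ``center`` is (row, col) in pixels; ``orientation`` is the angle of the
    long axis in radians (0 = horizontal).  ``nucleus_radius_frac`` is the
    nucleus radius as a fraction of the cell half-width and
    ``nucleus_axial_pos`` the nucleus centre as a fraction of the cell
    length from the first pole (0.5 = midcell, where the phage spindle
    positions it).  Emitter densities are in arbitrary units; the optics
    ``photon_scale`` maps them to counts.
    """

    center: tuple[float, float]
    length_um: float = 3.0
    width_um: float = 1.0
    orientation: float = 0.0
    infected: bool = True
    nucleus_radius_frac: float = 0.8
    nucleus_axial_pos: float = 0.5
    phenotype: str = "uniform"
    gfp_contrast: float = 1.0
    gfp_cyto_level: float = 5.0
    dapi_nucleus_level: float = 48.0
    dapi_background_level: float = 5.0
    membrane_level: float = 6.0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ConfigError(f"unknown phenotype {self.phenotype!r}")
        if not 0.0 < self.nucleus_radius_frac <= 1.0:
            raise ConfigError("nucleus_radius_frac must be in (0, 1]")
        if not 0.0 <= self.nucleus_axial_pos <= 1.0:
            raise ConfigError("nucleus_axial_pos must be in [0, 1]")
        if self.length_um < self.width_um:
            raise ConfigError("rod geometry requires length >= width")
        if self.gfp_contrast < 0:
            raise ConfigError("gfp_contrast must be >= 0")


@dataclass
class SceneSpec:
    """Full parametrization of one synthetic field of view."""

    image_shape: tuple[int, int]
    cells: list[CellSpec]
    optics: OpticsModel = field(default_factory=OpticsModel)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        for c in d["cells"]:
            c["center"] = list(c["center"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        cells = [CellSpec(**{**c, "center": tuple(c["center"])}) for c in d["cells"]]
        return cls(
            image_shape=tuple(d["image_shape"]),
            cells=cells,
            optics=OpticsModel(**d.get("optics", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class CellTruth:
    """Ground truth for one rendered cell (masks live in the label images)."""

    cell_id: int
    phenotype: str
    infected: bool
    axis_p0: tuple[float, float]
    axis_p1: tuple[float, float]
    length_px: float
    mean_density: dict[str, float]


@dataclass
class GroundTruth:
    """Pixel-exact truth for a rendered scene.

    ``label_image`` assigns every cell pixel to exactly one cell id (>0);
    ``nucleus_label`` does the same for nucleus disks.
    """

    label_image: np.ndarray
    nucleus_label: np.ndarray
    cells: list[CellTruth]

    def mask(self, cell_id: int) -> np.ndarray:
        return self.label_image == cell_id

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        return self.nucleus_label == cell_id

    @property
    def phenotype_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.cells:
            out[c.phenotype] = out.get(c.phenotype, 0) + 1
        return out


# ---------------------------------------------------------------------------
# geometry helpers


def _axis_unit(orientation: float) -> np.ndarray:
    # (row, col) unit vector; orientation measured from the column axis
    return np.array([np.sin(orientation), np.cos(orientation)])


def _capsule_distance(
    shape: tuple[int, int], a: np.ndarray, b: np.ndarray, pad: float
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Distance of pixel centres to the segment a-b, inside a padded bbox."""
    lo = np.floor(np.minimum(a, b) - pad).astype(int)
    hi = np.ceil(np.maximum(a, b) + pad).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(shape))
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]))
    rr, cc = np.meshgrid(
        np.arange(lo[0], hi[0], dtype=float),
        np.arange(lo[1], hi[1], dtype=float),
        indexing="ij",
    )
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        t = np.zeros_like(rr)
    else:
        t = ((rr - a[0]) * ab[0] + (cc - a[1]) * ab[1]) / denom
        t = np.clip(t, 0.0, 1.0)
    dr = rr - (a[0] + t * ab[0])
    dc = cc - (a[1] + t * ab[1])
    return np.hypot(dr, dc), sl


def cell_geometry(cell: CellSpec, pixel_size_nm: float) -> dict:
    """Pixel-space geometry of a cell: poles, cap centres, radii."""
    length_px = cell.length_um * 1000.0 / pixel_size_nm
    width_px = cell.width_um * 1000.0 / pixel_size_nm
    u = _axis_unit(cell.orientation)
    center = np.asarray(cell.center, dtype=float)
    half = length_px / 2.0
    radius = width_px / 2.0
    pole0 = center - half * u
    pole1 = center + half * u
    cap0 = center - (half - radius) * u
    cap1 = center + (half - radius) * u
    nucleus_center = pole0 + cell.nucleus_axial_pos * length_px * u
    return {
        "length_px": length_px,
        "width_px": width_px,
        "radius_px": radius,
        "unit": u,
        "pole0": pole0,
        "pole1": pole1,
        "cap0": cap0,
        "cap1": cap1,
        "nucleus_center": nucleus_center,
        "nucleus_radius_px": cell.nucleus_radius_frac * radius,
    }


# ---------------------------------------------------------------------------
# rendering


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to a ``(3, rows, cols)`` image plus ground truth.

    Pipeline: paint per-channel emitter density (spherocylinder body,
    nucleus disk, one-pixel membrane outline), blur with the Gaussian PSF,
    scale by ``photon_scale``, draw Poisson counts, add camera offset and
    Gaussian read noise, clip at zero and round to 16-bit integers.  With
    ``optics.noise=False`` the expected counts (offset included) are
    returned unrounded as float64.

    Raises
    ------
    GeometryError
        if a cell footprint extends outside the image.
    OverlapError
        if two cell footprints share a pixel.
    """
    shape = tuple(spec.image_shape)
    optics = spec.optics
    density = {ch: np.zeros(shape, dtype=float) for ch in CHANNELS}
    label = np.zeros(shape, dtype=np.int32)
    nucleus_label = np.zeros(shape, dtype=np.int32)
    truths: list[CellTruth] = []

    for idx, cell in enumerate(spec.cells, start=1):
        g = cell_geometry(cell, optics.pixel_size_nm)
        bb_lo = np.minimum(g["cap0"], g["cap1"]) - g["radius_px"]
        bb_hi = np.maximum(g["cap0"], g["cap1"]) + g["radius_px"]
        if (bb_lo < -0.5).any() or (bb_hi > np.array(shape) - 0.5).any():
            raise GeometryError(f"cell {idx} footprint outside image")
        dist, sl = _capsule_distance(shape, g["cap0"], g["cap1"], g["radius_px"] + 2)
        body = dist <= g["radius_px"]
        if (label[sl][body] != 0).any():
            raise OverlapError(f"cell {idx} overlaps a previously placed cell")
        label[sl][body] = idx

        gfp_cell = np.where(body, cell.gfp_cyto_level, 0.0)
        dapi_cell = np.where(body, cell.dapi_background_level, 0.0)
        if cell.infected:
            nr, nc = g["nucleus_center"]
            rr, cc = np.meshgrid(
                np.arange(sl[0].start, sl[0].stop, dtype=float),
                np.arange(sl[1].start, sl[1].stop, dtype=float),
                indexing="ij",
            )
            disk = (np.hypot(rr - nr, cc - nc) <= g["nucleus_radius_px"]) & body
            gfp_cell[disk] = cell.gfp_contrast * cell.gfp_cyto_level
            dapi_cell[disk] = cell.dapi_nucleus_level
            nucleus_label[sl][disk] = idx
        outline = body & ~ndi.binary_erosion(body)
        density["gfp"][sl] += gfp_cell
        density["dapi"][sl] += dapi_cell
        density["membrane"][sl][outline] = cell.membrane_level

        p0, p1 = g["pole0"], g["pole1"]
        if tuple(p1) < tuple(p0):
            p0, p1 = p1, p0
        truths.append(
            CellTruth(
                cell_id=idx,
                phenotype=cell.phenotype,
                infected=cell.infected,
                axis_p0=(float(p0[0]), float(p0[1])),
                axis_p1=(float(p1[0]), float(p1[1])),
                length_px=float(g["length_px"]),
                mean_density={
                    ch: float(density[ch][sl][body].mean()) for ch in CHANNELS
                },
            )
        )

    sigma = optics.psf_sigma_px
    rng = np.random.default_rng(spec.seed)
    planes = []
    for ch in CHANNELS:
        expected = density[ch]
        if sigma > 0:
            expected = ndi.gaussian_filter(expected, sigma=sigma)
        expected = expected * optics.photon_scale
        if optics.noise:
            counts = rng.poisson(expected).astype(float)
            counts += optics.camera_offset
            if optics.read_noise_sd > 0:
                counts += rng.normal(0.0, optics.read_noise_sd, size=shape)
            planes.append(
                np.clip(np.rint(counts), 0, np.iinfo(np.uint16).max).astype(np.uint16)
            )
        else:
            planes.append(expected + optics.camera_offset)
    image = np.stack(planes, axis=0)
    return image, GroundTruth(label_image=label, nucleus_label=nucleus_label, cells=truths)


# ---------------------------------------------------------------------------
# population generator


def make_population(
    n: int,
    phenotype_mix: dict[str, float],
    base_cell: CellSpec | None = None,
    jitter: float = 0.1,
    seed: int = 0,
    optics: OpticsModel | None = None,
    infected_fraction: float = 1.0,
    contrasts: dict[str, float] | None = None,
    image_shape: tuple[int, int] | None = None,
    margin_px: float = 6.0,
    max_attempts: int = 100,
) -> SceneSpec:
    """Build a scene of ``n`` non-overlapping cells with a given phenotype mix.

    Phenotype counts are allocated by largest remainder, so the realized
    mix matches ``phenotype_mix`` exactly in expectation, and the labels
    are then shuffled.  Cell length and width receive relative Gaussian
    jitter; orientations are drawn uniformly on [0, pi).  Placement is
    rejection sampling with ``max_attempts`` repositions per cell against
    an occupancy map dilated by ``margin_px`` (so footprints stay separated
    even after PSF blur).  Fully deterministic given ``seed``.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if any(f < 0 for f in phenotype_mix.values()):
        raise ConfigError("phenotype fractions must be >= 0")
    unknown = set(phenotype_mix) - set(PHENOTYPES)
    if unknown:
        raise ConfigError(f"unknown phenotypes {sorted(unknown)}")
    total = sum(phenotype_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"phenotype fractions sum to {total}, expected 1")

    rng = np.random.default_rng(seed)
    base = base_cell if base_cell is not None else CellSpec(center=(0.0, 0.0))
    optics = optics if optics is not None else OpticsModel()
    contrasts = {**PHENOTYPE_CONTRAST, **(contrasts or {})}

    # largest-remainder allocation of phenotype counts
    items = sorted(phenotype_mix.items())
    quotas = {ph: n * f for ph, f in items}
    counts = {ph: int(np.floor(q)) for ph, q in quotas.items()}
    short = n - sum(counts.values())
    for ph, _ in sorted(items, key=lambda kv: quotas[kv[0]] - np.floor(quotas[kv[0]]), reverse=True)[:short]:
        counts[ph] += 1
    labels = [ph for ph, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)

    px = optics.pixel_size_nm
    base_len_px = base.length_um * 1000.0 / px
    base_wid_px = base.width_um * 1000.0 / px
    if image_shape is None:
        fp = (base_len_px + 2 * margin_px + 4) * (base_wid_px + 2 * margin_px + 4)
        side = int(np.ceil(np.sqrt(n * fp * 3.0)))
        side = max(side, int(np.ceil(2.5 * base_len_px)))
        image_shape = (side, side)
    shape = tuple(image_shape)

    occupied = np.zeros(shape, dtype=bool)
    cells: list[CellSpec] = []
    for i, phenotype in enumerate(labels):
        length = base.length_um * max(0.4, 1.0 + jitter * rng.normal())
        width = base.width_um * max(0.4, 1.0 + jitter * rng.normal())
        length = max(length, width)
        infected = bool(rng.random() < infected_fraction)
        placed = False
        for _ in range(max_attempts):
            orientation = float(rng.uniform(0.0, np.pi))
            half_px = length * 1000.0 / px / 2.0
            rad_px = width * 1000.0 / px / 2.0
            # keep footprints clear of the border so PSF bleed cannot make
            # a segmented component touch the image edge (border discard)
            lo = half_px + max(4.0, margin_px)
            center = np.array(
                [
                    rng.uniform(lo, shape[0] - 1 - lo),
                    rng.uniform(lo, shape[1] - 1 - lo),
                ]
            )
            u = _axis_unit(orientation)
            cap0 = center - (half_px - rad_px) * u
            cap1 = center + (half_px - rad_px) * u
            dist, sl = _capsule_distance(shape, cap0, cap1, rad_px + margin_px + 1)
            dilated = dist <= rad_px + margin_px / 2.0
            if not (occupied[sl] & dilated).any():
                occupied[sl] |= dilated
                cells.append(
                    dataclasses.replace(
                        base,
                        center=(float(center[0]), float(center[1])),
                        length_um=float(length),
                        width_um=float(width),
                        orientation=orientation,
                        infected=infected,
                        phenotype=phenotype,
                        gfp_contrast=contrasts[phenotype],
                    )
                )
                placed = True
                break
        if not placed:
            raise OverlapError(
                f"could not place cell {i + 1}/{n} after {max_attempts} attempts"
            )
    return SceneSpec(
        image_shape=shape,
        cells=cells,
        optics=optics,
        seed=int(rng.integers(2**31)),
    )


# ---------------------------------------------------------------------------
# run-length encoding and scene I/O


def rle_encode(mask: np.ndarray) -> list[int]:
    """Row-major run-length encoding; runs alternate 0s/1s, starting with 0s."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate(([0], changes, [flat.size]))).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    val = False
    for r in runs:
        if val:
            out[pos : pos + r] = True
        pos += r
        val = not val
    return out.reshape(shape)


def write_scene(
    out_dir: str | Path, name: str, image: np.ndarray, truth: GroundTruth
) -> tuple[Path, Path]:
    """Write a multi-page TIFF (one page per channel) plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{name}.tif"
    tifffile.imwrite(tiff_path, image, photometric="minisblack")
    shape = truth.label_image.shape
    sidecar = {
        "image_shape": list(shape),
        "channels": list(CHANNELS),
        "cells": [
            {
                "id": c.cell_id,
                "phenotype": c.phenotype,
                "infected": c.infected,
                "axis_p0": list(c.axis_p0),
                "axis_p1": list(c.axis_p1),
                "length_px": c.length_px,
                "mean_density": c.mean_density,
                "mask_rle": rle_encode(truth.mask(c.cell_id)),
                "nucleus_rle": rle_encode(truth.nucleus_mask(c.cell_id)),
            }
            for c in truth.cells
        ],
    }
    json_path = out_dir / f"{name}.truth.json"
    json_path.write_text(json.dumps(sidecar))
    return tiff_path, json_path


def read_scene(tiff_path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF back as a ``(channels, rows, cols)`` array."""
    img = tifffile.imread(tiff_path)
    if img.ndim == 2:
        img = img[None]
    return img


def read_truth(json_path: str | Path) -> GroundTruth:
    d = json.loads(Path(json_path).read_text())
    shape = tuple(d["image_shape"])
    label = np.zeros(shape, dtype=np.int32)
    nucleus = np.zeros(shape, dtype=np.int32)
    cells = []
    for c in d["cells"]:
        label[rle_decode(c["mask_rle"], shape)] = c["id"]
        nucleus[rle_decode(c["nucleus_rle"], shape)] = c["id"]
        cells.append(
            CellTruth(
                cell_id=c["id"],
                phenotype=c["phenotype"],
                infected=c["infected"],
                axis_p0=tuple(c["axis_p0"]),
                axis_p1=tuple(c["axis_p1"]),
                length_px=c["length_px"],
                mean_density=c["mean_density"],
            )
        )
    return GroundTruth(label_image=label, nucleus_label=nucleus, cells=cells)
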