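"""Synthetic mitochondrial fluorescence fields along a fission-fusion continuum.

Real training data for the scoring pipeline are live-cell fields of
MitoTracker-stained cells whose mitochondria range from fragmented puncta and
rings (hyperfission, CCCP-like), through mixed curved tubules (normal), to long
interconnected filaments (hyperfusion, FL3-like).  This module emulates those
three phenotypes — and the continuum between them — with a stochastic-geometry
model: each field contains a few disc-shaped cell footprints with faint
cytoplasmic background, inside which mitochondria are rendered as antialiased
discs (puncta), annuli (rings) and smoothed random-walk curves (tubules),
convolved with a Gaussian PSF and corrupted by Poisson shot noise plus Gaussian
read noise.

The single control parameter ``phi`` in [0, 1] moves the field along the
continuum: 0 is extreme hyperfission (all puncta), 0.5 is normal (mixed), 1 is
extreme hyperfusion (all tubules, partially interconnected).  Expected puncta
count decreases linearly in ``phi`` and expected tubule count and arc length
increase, so classical morphometry and learned scores can both be validated
against the generating coordinate.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

# Rendering amplitudes, in 16-bit camera counts before noise.
STRUCTURE_AMP = 600.0
CELL_BG_AMP = 40.0
MAX_COUNTS = 65535.0

#: class labels derived from phi (fission-like, normal, fusion-like);
#: named after the canonical inducing treatments so downstream tasks
#: (CCCP-NC, FL3-NC, CCCP-FL3-NC) apply unchanged to synthetic data.
FISSION_LABEL = "CCCP"
NORMAL_LABEL = "NC"
FUSION_LABEL = "FL3"


def truth_label_for_phi(phi: float) -> str:
    """Class label as a deterministic function of the continuum coordinate.

    Thirds of [0, 1]: phi < 1/3 is fission-like, 1/3 <= phi < 2/3 normal,
    phi >= 2/3 fusion-like.
    """
    if phi < 1.0 / 3.0:
        return FISSION_LABEL
    if phi < 2.0 / 3.0:
        return NORMAL_LABEL
    return FUSION_LABEL


@dataclass(frozen=True)
class MorphologySpec:
    """Parameters of one synthetic field.

    Parameters
    ----------
    phi : float
        Fission-fusion coordinate in [0, 1]; 0 = extreme hyperfission,
        0.5 = normal, 1 = extreme hyperfusion.
    n_cells : int
        Cells per field.
    cell_radius_px : float
        Mean cell footprint radius in pixels.
    fragment_rate : float
        Expected puncta per cell at phi = 0 (decays quadratically to 0 at
        phi = 1).
    tubule_rate : float
        Expected tubules per cell at phi = 1 (grows linearly from 0 at phi = 0).
    tubule_length_px : float
        Mean tubule arc length at phi = 1, in pixels.
    ring_fraction : float
        Fraction of puncta rendered as annuli (ring-shaped mitochondria,
        characteristic of strong uncoupler treatment).
    psf_sigma_px : float
        Gaussian point-spread-function width.
    noise_level : float
        Scales both Poisson shot noise and Gaussian read noise; 0 disables
        noise entirely.
    field_size_px : int
        Output side length in pixels.
    seed : int
        RNG seed; a fixed seed yields a byte-identical field.
    """

    phi: float
    n_cells: int = 6
    cell_radius_px: float = 60.0
    fragment_rate: float = 40.0
    tubule_rate: float = 8.0
    tubule_length_px: float = 80.0
    ring_fraction: float = 0.25
    psf_sigma_px: float = 1.2
    noise_level: float = 0.05
    field_size_px: int = 512
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.cell_radius_px <= 2:
            raise ValueError(f"cell_radius_px must exceed 2 px, got {self.cell_radius_px}")
        if self.fragment_rate < 0:
            raise ValueError(f"fragment_rate must be >= 0, got {self.fragment_rate}")
        if self.tubule_rate < 0:
            raise ValueError(f"tubule_rate must be >= 0, got {self.tubule_rate}")
        if self.tubule_length_px <= 0:
            raise ValueError(f"tubule_length_px must be > 0, got {self.tubule_length_px}")
        if not (0.0 <= self.ring_fraction <= 1.0):
            raise ValueError(f"ring_fraction must be in [0, 1], got {self.ring_fraction}")
        if self.psf_sigma_px < 0:
            raise ValueError(f"psf_sigma_px must be >= 0, got {self.psf_sigma_px}")
        if self.noise_level < 0:
            raise ValueError(f"noise_level must be >= 0, got {self.noise_level}")
        if self.field_size_px < 2 * self.cell_radius_px + 4:
            raise ValueError(
                f"field_size_px={self.field_size_px} too small to contain a cell of "
                f"radius {self.cell_radius_px}"
            )


def expected_primitive_rates(spec: MorphologySpec) -> tuple[float, float]:
    """Expected (puncta, tubule) counts per cell — the generator's own oracle.

    Puncta are Poisson with mean ``fragment_rate * (1 - phi)^2`` (quadratic,
    so the normal state is already tubule-dominant with a minority of
    puncta); tubules are Poisson with mean ``tubule_rate * phi``.  With the
    default rates the total expected primitive count is strictly decreasing
    over the canonical grid phi in {0, 0.25, 0.5, 0.75, 1}: fragmentation
    trades many small objects for few long ones.
    """
    return spec.fragment_rate * (1.0 - spec.phi) ** 2, spec.tubule_rate * spec.phi


def expected_tubule_length(spec: MorphologySpec) -> float:
    """Mean tubule arc length in px: grows affinely from 20% to 100% of
    ``tubule_length_px`` as phi goes 0 -> 1."""
    return spec.tubule_length_px * (0.2 + 0.8 * spec.phi)


@dataclass(frozen=True)
class Punctum:
    center: tuple[float, float]  # (row, col), sub-pixel
    radius: float
    is_ring: bool = False
    ring_width: float = 1.2


@dataclass(frozen=True)
class Tubule:
    points: np.ndarray  # (n, 2) polyline vertices, sub-pixel (row, col)


@dataclass(frozen=True)
class CellGeometry:
    center: tuple[float, float]
    radius: float
    puncta: tuple[Punctum, ...]
    tubules: tuple[Tubule, ...]

    @property
    def n_primitives(self) -> int:
        return len(self.puncta) + len(self.tubules)


def _sample_cell_centers(spec: MorphologySpec, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping cell discs fully inside the field."""
    cells: list[tuple[float, float, float]] = []
    size = spec.field_size_px
    for _ in range(spec.n_cells):
        for _attempt in range(200):
            radius = spec.cell_radius_px * rng.uniform(0.85, 1.15)
            margin = radius + 1.0
            r = rng.uniform(margin, size - margin)
            c = rng.uniform(margin, size - margin)
            if all(np.hypot(r - r0, c - c0) > 0.95 * (radius + rad0) for r0, c0, rad0 in cells):
                cells.append((r, c, radius))
                break
        else:
            # dense field: accept an overlapping placement rather than fail
            radius = spec.cell_radius_px
            cells.append((rng.uniform(radius, size - radius), rng.uniform(radius, size - radius), radius))
    return cells


def _sample_tubule(
    start: np.ndarray,
    length: float,
    cell_center: np.ndarray,
    cell_radius: float,
    rng: np.random.Generator,
) -> Tubule:
    """Smoothed random walk of given arc length, confined to the cell disc."""
    step = 1.5
    n_steps = max(2, int(round(length / step)))
    heading = rng.uniform(0.0, 2.0 * np.pi)
    pts = [start.astype(float)]
    pos = start.astype(float)
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.22)
        nxt = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if np.hypot(*(nxt - cell_center)) > 0.92 * cell_radius:
            # steer back toward the cell interior
            to_center = cell_center - pos
            heading = np.arctan2(to_center[0], to_center[1]) + rng.normal(0.0, 0.4)
            nxt = pos + step * np.array([np.sin(heading), np.cos(heading)])
        pos = nxt
        pts.append(pos.copy())
    return Tubule(points=np.asarray(pts))


def sample_mito_geometry(spec: MorphologySpec, rng: np.random.Generator | None = None) -> list[CellGeometry]:
    """Draw the stochastic geometry (cells, puncta, tubules) for one field.

    Per cell, puncta count ~ Poisson(fragment_rate * (1-phi)) and tubule count
    ~ Poisson(tubule_rate * phi); tubule arc length is Gamma-distributed around
    :func:`expected_tubule_length`.  For phi >= 2/3 a growing fraction of
    tubules starts at the endpoint of an earlier tubule in the same cell
    (network interconnection).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([0x5EED, spec.seed & 0x7FFFFFFF]))
    lam_puncta, lam_tubules = expected_primitive_rates(spec)
    mean_len = expected_tubule_length(spec)
    share_prob = 0.0
    if spec.phi >= 2.0 / 3.0:
        share_prob = 0.6 * (spec.phi - 2.0 / 3.0) * 3.0

    cells: list[CellGeometry] = []
    for r0, c0, radius in _sample_cell_centers(spec, rng):
        center = np.array([r0, c0])
        n_puncta = rng.poisson(lam_puncta)
        n_tubules = rng.poisson(lam_tubules)
        puncta: list[Punctum] = []
        for _ in range(n_puncta):
            ang = rng.uniform(0, 2 * np.pi)
            rad = radius * 0.88 * np.sqrt(rng.uniform())
            pr, pc = r0 + rad * np.sin(ang), c0 + rad * np.cos(ang)
            if rng.uniform() < spec.ring_fraction:
                puncta.append(Punctum(center=(pr, pc), radius=rng.uniform(3.5, 6.0), is_ring=True))
            else:
                puncta.append(Punctum(center=(pr, pc), radius=rng.uniform(1.5, 3.0)))
        tubules: list[Tubule] = []
        for _ in range(n_tubules):
            if tubules and rng.uniform() < share_prob:
                prev = tubules[rng.integers(len(tubules))]
                start = prev.points[-1 if rng.uniform() < 0.5 else 0]
            else:
                ang = rng.uniform(0, 2 * np.pi)
                rad = radius * 0.8 * np.sqrt(rng.uniform())
                start = center + rad * np.array([np.sin(ang), np.cos(ang)])
            length = rng.gamma(shape=4.0, scale=mean_len / 4.0)
            length = float(np.clip(length, 6.0, 4.0 * mean_len))
            tubules.append(_sample_tubule(np.asarray(start, dtype=float), length, center, radius, rng))
        cells.append(CellGeometry(center=(r0, c0), radius=radius, puncta=tuple(puncta), tubules=tuple(tubules)))
    return cells


@dataclass(frozen=True)
class SimulatedField:
    """A rendered synthetic field with its generating ground truth."""

    image: np.ndarray  # float64, 16-bit count scale, clipped to [0, 65535]
    truth_mask: np.ndarray  # bool, union of cell footprints
    truth_label: str
    phi: float
    seed: int
    n_puncta: int = 0
    n_tubules: int = 0


def _splat_disc(canvas: np.ndarray, center: tuple[float, float], radius: float, amp: float) -> None:
    """Antialiased solid disc: coverage ~ clip(radius + 0.5 - dist, 0, 1)."""
    r0, c0 = center
    size = canvas.shape[0]
    lo_r = max(0, int(np.floor(r0 - radius - 2)))
    hi_r = min(size, int(np.ceil(r0 + radius + 3)))
    lo_c = max(0, int(np.floor(c0 - radius - 2)))
    hi_c = min(size, int(np.ceil(c0 + radius + 3)))
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dist = np.hypot(rr - r0, cc - c0)
    canvas[lo_r:hi_r, lo_c:hi_c] += amp * np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _splat_annulus(canvas: np.ndarray, center: tuple[float, float], radius: float, width: float, amp: float) -> None:
    r0, c0 = center
    size = canvas.shape[0]
    outer = radius + width
    lo_r = max(0, int(np.floor(r0 - outer - 2)))
    hi_r = min(size, int(np.ceil(r0 + outer + 3)))
    lo_c = max(0, int(np.floor(c0 - outer - 2)))
    hi_c = min(size, int(np.ceil(c0 + outer + 3)))
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dist = np.hypot(rr - r0, cc - c0)
    canvas[lo_r:hi_r, lo_c:hi_c] += amp * np.clip(width / 2.0 + 0.5 - np.abs(dist - radius), 0.0, 1.0)


def _splat_polyline(canvas: np.ndarray, points: np.ndarray, amp: float) -> None:
    """Bilinear splatting of a densely resampled polyline; the deposited mass
    per unit arc length is 1, giving a ~1-px-wide line of intensity ~amp."""
    size = canvas.shape[0]
    diffs = np.diff(points, axis=0)
    seg_len = np.hypot(diffs[:, 0], diffs[:, 1])
    total = float(seg_len.sum())
    if total <= 0:
        return
    n_samples = max(2, int(np.ceil(total / 0.25)))
    t = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    rows = np.interp(t, cum, points[:, 0])
    cols = np.interp(t, cum, points[:, 1])
    w = total / n_samples  # mass per sample

    fr = np.floor(rows).astype(int)
    fc = np.floor(cols).astype(int)
    dr = rows - fr
    dc = cols - fc
    for off_r, off_c, weight in (
        (0, 0, (1 - dr) * (1 - dc)),
        (0, 1, (1 - dr) * dc),
        (1, 0, dr * (1 - dc)),
        (1, 1, dr * dc),
    ):
        rr = fr + off_r
        cc = fc + off_c
        ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        np.add.at(canvas, (rr[ok], cc[ok]), amp * w * weight[ok])


def rasterize(geometry: Sequence[CellGeometry], spec: MorphologySpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise- and PSF-free raster of the geometry plus the truth mask."""
    size = spec.field_size_px
    canvas = np.zeros((size, size), dtype=np.float64)
    mask = np.zeros((size, size), dtype=bool)
    for cell in geometry:
        # faint cytoplasmic background marks the cell footprint
        _splat_disc(canvas, cell.center, cell.radius, CELL_BG_AMP)
        # truth mask is exact (not antialiased); computed on the bounding box
        r0, c0 = cell.center
        lo_r = max(0, int(np.floor(r0 - cell.radius - 1)))
        hi_r = min(size, int(np.ceil(r0 + cell.radius + 2)))
        lo_c = max(0, int(np.floor(c0 - cell.radius - 1)))
        hi_c = min(size, int(np.ceil(c0 + cell.radius + 2)))
        sub_rr, sub_cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        mask[lo_r:hi_r, lo_c:hi_c] |= np.hypot(sub_rr - r0, sub_cc - c0) <= cell.radius + 0.5
        for p in cell.puncta:
            if p.is_ring:
                _splat_annulus(canvas, p.center, p.radius, p.ring_width, STRUCTURE_AMP)
            else:
                _splat_disc(canvas, p.center, p.radius, STRUCTURE_AMP)
        for t in cell.tubules:
            _splat_polyline(canvas, t.points, STRUCTURE_AMP)
    return canvas, mask


def render_field(geometry: Sequence[CellGeometry], spec: MorphologySpec) -> SimulatedField:
    """Rasterize geometry, apply the Gaussian PSF, add shot + read noise.

    With ``noise_level = 0`` and ``psf_sigma_px = 0`` the image equals the
    raw raster exactly.  Noise model: counts are re-drawn as
    ``Poisson(image / g) * g`` with gain ``g = 8 * noise_level`` and Gaussian
    read noise of SD ``300 * noise_level`` counts is added; the result is
    clipped to the 16-bit range.
    """
    spec.validate()
    raster, mask = rasterize(geometry, spec)
    image = raster
    if spec.psf_sigma_px > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.psf_sigma_px)
    if spec.noise_level > 0:
        rng = np.random.default_rng(np.random.SeedSequence([0x401E, spec.seed & 0x7FFFFFFF]))
        gain = 8.0 * spec.noise_level
        image = rng.poisson(np.clip(image, 0, None) / gain).astype(np.float64) * gain
        image = image + rng.normal(0.0, 300.0 * spec.noise_level, size=image.shape)
    image = np.clip(image, 0.0, MAX_COUNTS)
    n_puncta = sum(len(c.puncta) for c in geometry)
    n_tubules = sum(len(c.tubules) for c in geometry)
    return SimulatedField(
        image=image,
        truth_mask=mask,
        truth_label=truth_label_for_phi(spec.phi),
        phi=spec.phi,
        seed=spec.seed,
        n_puncta=n_puncta,
        n_tubules=n_tubules,
    )


def simulate_field(spec: MorphologySpec) -> SimulatedField:
    """Convenience: geometry sampling + rendering in one call."""
    return render_field(sample_mito_geometry(spec), spec)


def default_class_specs(field_size_px: int = 512, noise_level: float = 0.05) -> dict[str, MorphologySpec]:
    """The three canonical phenotype conditions used throughout the package:
    fission-like (phi=0.15), normal (phi=0.5), fusion-like (phi=0.85)."""
    return {
        FISSION_LABEL: MorphologySpec(phi=0.15, field_size_px=field_size_px, noise_level=noise_level),
        NORMAL_LABEL: MorphologySpec(phi=0.50, field_size_px=field_size_px, noise_level=noise_level),
        FUSION_LABEL: MorphologySpec(phi=0.85, field_size_px=field_size_px, noise_level=noise_level),
    }


_CLASS_BANDS = {
    FISSION_LABEL: (0.0, 1.0 / 3.0 - 1e-9),
    NORMAL_LABEL: (1.0 / 3.0, 2.0 / 3.0 - 1e-9),
    FUSION_LABEL: (2.0 / 3.0, 1.0),
}


def _child_seed(root: int, *key: int) -> int:
    h = hashlib.sha256(np.array([root, *key], dtype=np.int64).tobytes()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def generate_dataset(
    class_specs: dict[str, MorphologySpec],
    n_fields_per_class: int,
    out_dir: str | Path,
    seed: int,
    n_experiments: int = 5,
    phi_jitter: float = 0.08,
) -> pd.DataFrame:
    """Render and write a labelled synthetic dataset plus its manifest.

    Each field's phi is jittered uniformly within its class band so that the
    manifest label always equals the truth label.  Acquisition-batch
    ("experiment") ids are assigned round-robin so that grouped
    cross-validation is exercised downstream.  Deterministic given ``seed``.

    Returns the manifest DataFrame; also writes ``manifest.csv``, 16-bit field
    TIFFs under ``fields/`` and 8-bit 0/255 truth masks under ``masks/``.
    """
    from mitoscore import imaging_io

    out_dir = Path(out_dir)
    (out_dir / "fields").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for class_idx, (label, spec) in enumerate(sorted(class_specs.items())):
        if truth_label_for_phi(spec.phi) != label:
            raise ValueError(
                f"class spec for {label!r} has phi={spec.phi}, which maps to "
                f"label {truth_label_for_phi(spec.phi)!r}"
            )
        lo, hi = _CLASS_BANDS[label]
        for i in range(n_fields_per_class):
            child = _child_seed(seed, class_idx, i)
            jrng = np.random.default_rng(child)
            phi_i = float(np.clip(spec.phi + jrng.uniform(-phi_jitter, phi_jitter), lo, hi))
            spec_i = dataclasses.replace(spec, phi=phi_i, seed=child)
            sim = simulate_field(spec_i)
            field_id = f"{label}_{i:04d}"
            rel_path = f"fields/{field_id}.tif"
            rel_mask = f"masks/{field_id}.tif"
            imaging_io.write_field(np.round(sim.image).astype(np.uint16), out_dir / rel_path)
            imaging_io.write_field((sim.truth_mask.astype(np.uint8) * 255), out_dir / rel_mask)
            rows.append(
                {
                    "field_id": field_id,
                    "path": rel_path,
                    "mask_path": rel_mask,
                    "label": sim.truth_label,
                    "phi": phi_i,
                    "experiment_id": f"E{i % n_experiments}",
                    "participant_id": "",
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
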