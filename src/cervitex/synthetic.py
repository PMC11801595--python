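"""Seeded three-class synthetic micrograph and height-map generator.

The clinical cervical micrographs behind the classification protocol are not
publicly deposited, so this module synthesizes stand-in data with the same
protocol shape (45 source images of 512x512 per class per modality) and the
same class-distinguishing physical contrasts: surface roughness increasing
from normal through benign to malign, and particle volume smallest for the
malign class.

Each image is a self-affine Gaussian random field (white noise shaped by a
radial spectral filter f^(-beta/2)) plus soft-edged particle mesas at
class-dependent density, radius and relative amplitude.  In AFM mode the
plane-detrended map is rescaled so its RMS roughness equals the class target
(defaults are the reported class roughnesses 50.23 / 244.654 / 456.145 nm);
in SEM mode the same field family is mapped affinely to 8-bit with a
class-dependent contrast gain.

A ``separation`` knob in [0, 1] linearly shrinks every class parameter
toward the cross-class mean: at 1 the classes are fully distinct, at 0 they
are identically distributed and classification can only be at chance.  Every
image's RNG stream is derived from a stable hash of
(seed, modality, class, index), so datasets are reproducible file by file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cervitex.afm import HeightMap, detrend_plane, save_height_map
from cervitex.image_io import (GrayImage, LABELS, new_manifest, save_image,
                               write_manifest)

__all__ = ["ClassParams", "SyntheticConfig", "generate_field",
           "generate_class_image", "generate_dataset", "height_to_gray"]


@dataclass(frozen=True)
class ClassParams:
    """Per-class generator parameters.

    beta: spectral exponent of the background field (larger = smoother).
    target_rq_nm: RMS roughness the AFM-mode map is scaled to.
    n_particles: particle mesas per 512x512 image.
    particle_radius_px: mesa plateau radius.
    particle_amplitude: mesa height relative to the background RMS.
    sem_gain: 8-bit contrast gain of the SEM-mode mapping.
    sem_noise_sd: additive SEM read noise, gray levels (1 sd).
    """

    beta: float
    target_rq_nm: float
    n_particles: int
    particle_radius_px: float
    particle_amplitude: float
    sem_gain: float
    sem_noise_sd: float


#: Defaults encode the study's class contrasts: roughness 50.23/244.654/
#: 456.145 nm for normal/benign/malign, particle content chosen so the
#: integrated above-threshold particle volume is smallest for malign with
#: normal and benign of the same order, and additive SEM noise increasing
#: with grade.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "normal": ClassParams(beta=3.4, target_rq_nm=50.23, n_particles=52,
                          particle_radius_px=20.0, particle_amplitude=8.0,
                          sem_gain=28.0, sem_noise_sd=0.8),
    "benign": ClassParams(beta=2.4, target_rq_nm=244.654, n_particles=36,
                          particle_radius_px=9.0, particle_amplitude=8.0,
                          sem_gain=44.0, sem_noise_sd=4.0),
    "malign": ClassParams(beta=1.5, target_rq_nm=456.145, n_particles=10,
                          particle_radius_px=5.0, particle_amplitude=24.0,
                          sem_gain=60.0, sem_noise_sd=9.0),
}

#: Default lateral pixel size of AFM-mode maps, um per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.02


@dataclass(frozen=True)
class SyntheticConfig:
    """Dataset-level generator configuration."""

    n_images_per_class: int = 45
    image_size: int = 512
    seed: int = 0
    separation: float = 1.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    class_params: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must be in [0, 1]")
        if self.n_images_per_class < 1 or self.image_size < 8:
            raise ValueError("invalid dataset dimensions")

    def effective_params(self, label: str) -> ClassParams:
        """Class parameters shrunk toward the cross-class mean by separation.

        value = mean + separation * (class value - mean), per field; at
        separation 0 every class collapses onto the same parameter vector.
        """
        params = [self.class_params[c] for c in LABELS]
        base = self.class_params[label]
        s = self.separation
        def mix(attr):
            mean = float(np.mean([getattr(p, attr) for p in params]))
            return mean + s * (getattr(base, attr) - mean)
        return ClassParams(
            beta=mix("beta"),
            target_rq_nm=mix("target_rq_nm"),
            n_particles=int(round(mix("n_particles"))),
            particle_radius_px=mix("particle_radius_px"),
            particle_amplitude=mix("particle_amplitude"),
            sem_gain=mix("sem_gain"),
            sem_noise_sd=mix("sem_noise_sd"),
        )


def _subseed(seed: int, modality: str, label: str, index: int) -> int:
    """Stable per-image sub-seed below 2**31."""
    key = f"{seed}|{modality}|{label}|{index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


def generate_field(size: int, beta: float,
                   seed: int | np.random.Generator) -> np.ndarray:
    """Zero-mean self-affine Gaussian random field by spectral synthesis.

    White Gaussian noise is shaped in the frequency domain by the radial
    filter f^(-beta/2) (DC term zeroed) and transformed back to real space.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    fx = np.fft.fftfreq(size)
    f = np.sqrt(fx[:, None] ** 2 + fx[None, :] ** 2)
    filt = np.zeros_like(f)
    nzero = f > 0
    filt[nzero] = f[nzero] ** (-beta / 2.0)
    shaped = np.real(np.fft.ifft2(np.fft.fft2(white) * filt))
    shaped -= shaped.mean()
    return shaped


def _add_particles(canvas: np.ndarray, params: ClassParams, amplitude: float,
                   rng: np.random.Generator) -> None:
    """Stamp soft-edged particle mesas (tanh profile) onto the canvas."""
    size = canvas.shape[0]
    r0 = params.particle_radius_px
    edge = max(r0 / 4.0, 1.0)
    half = int(np.ceil(r0 + 4 * edge))
    for _ in range(params.n_particles):
        cy, cx = rng.uniform(0, size, 2)
        y0, y1 = max(0, int(cy) - half), min(size, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(size, int(cx) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        canvas[y0:y1, x0:x1] += amplitude * 0.5 * (1 + np.tanh((r0 - d) / edge))


def _compose_surface(cfg: SyntheticConfig, label: str,
                     rng: np.random.Generator) -> np.ndarray:
    """Background field plus particle mesas, unit-free relative heights."""
    p = cfg.effective_params(label)
    fieldmap = generate_field(cfg.image_size, p.beta, rng)
    rms = fieldmap.std()
    if rms > 0:
        fieldmap /= rms
    _add_particles(fieldmap, p, p.particle_amplitude, rng)
    return fieldmap


def generate_class_image(cfg: SyntheticConfig, label: str, modality: str,
                         index: int) -> GrayImage | HeightMap:
    """One synthetic image: a GrayImage (SEM mode) or HeightMap (AFM mode)."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    p = cfg.effective_params(label)
    rng = np.random.default_rng(_subseed(cfg.seed, modality, label, index))
    surface = _compose_surface(cfg, label, rng)
    if modality == "AFM":
        # scale so the plane-detrended RMS roughness equals the class target
        rq = np.sqrt(np.mean(detrend_plane(surface) ** 2))
        heights = surface * (p.target_rq_nm / rq)
        return HeightMap(heights=heights, pixel_size=cfg.pixel_size_um)
    if modality == "SEM":
        z = surface / surface.std()
        pixels = 128.0 + p.sem_gain * z + p.sem_noise_sd * rng.standard_normal(
            surface.shape)
        pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
        return GrayImage(pixels=pixels, modality="SEM", label=label,
                         source_id=f"syn_SEM_{label}_{index:03d}")
    raise ValueError(f"unknown modality {modality!r}")


def height_to_gray(hmap: HeightMap, label: str,
                   source_id: str) -> GrayImage:
    """Min-max 8-bit rendering of a height map for the texture pipeline."""
    h = hmap.heights
    span = h.max() - h.min()
    if span == 0:
        pixels = np.zeros(h.shape, dtype=np.uint8)
    else:
        pixels = np.rint((h - h.min()) / span * 255).astype(np.uint8)
    return GrayImage(pixels=pixels, modality="AFM", label=label,
                     source_id=source_id)


def generate_images(cfg: SyntheticConfig, modality: str) -> list:
    """All n_images_per_class x 3 images of one modality, in memory.

    AFM mode yields (HeightMap, label, source_id) tuples; SEM mode yields
    GrayImage objects.
    """
    out = []
    for label in LABELS:
        for i in range(cfg.n_images_per_class):
            img = generate_class_image(cfg, label, modality, i)
            if modality == "AFM":
                out.append((img, label, f"syn_AFM_{label}_{i:03d}"))
            else:
                out.append(img)
    return out


def generate_gray_images(cfg: SyntheticConfig, modality: str) -> list[GrayImage]:
    """Like :func:`generate_images` but AFM maps rendered to 8-bit gray."""
    if modality == "SEM":
        return generate_images(cfg, "SEM")
    return [height_to_gray(hm, label, sid)
            for hm, label, sid in generate_images(cfg, "AFM")]


def generate_dataset(cfg: SyntheticConfig, modality: str,
                     out_dir: str | Path) -> pd.DataFrame:
    """Write one modality's synthetic dataset to disk and return its manifest.

    SEM images are 8-bit PNG; AFM height maps are 32-bit float TIFF.  The
    manifest describes source images (tile_index empty); downstream tiling
    of the default 45x3 protocol yields 540 tiles.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for label in LABELS:
        for i in range(cfg.n_images_per_class):
            img = generate_class_image(cfg, label, modality, i)
            if modality == "AFM":
                sid = f"syn_AFM_{label}_{i:03d}"
                path = out_dir / f"{sid}.tif"
                save_height_map(img, path)
            else:
                sid = img.source_id
                path = out_dir / f"{sid}.png"
                save_image(img, path)
            records.append({"path": str(path), "modality": modality,
                            "label": label, "source_id": sid,
                            "tile_index": None, "split": "unassigned"})
    manifest = new_manifest(records)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
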