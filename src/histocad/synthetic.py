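"""Synthetic H&E-like image generator with case structure.

The generator exists to make the full pipeline testable without any real
histology: it emulates the *statistical* structure of a slide-level dataset
— images nested within cases, one diagnosis per case, a class-dependent
texture (nucleus density and size), and a case-level appearance shift
(stain variation) — not tissue morphology.

Images are a pink "eosin" background plus purple "hematoxylin" elliptical
nuclei.  The class effect is carried by the Poisson rate of nuclei per
image (and mildly by nucleus size); the per-case stain shift is a single
RGB tint added to the background of every image of that case, which makes
images from one case mutually similar.  That confound is what makes
patient-grouped cross-validation consequential, and it is the lever the
leakage tests pull.

Determinism: a single integer seed fans out through ``numpy``
``SeedSequence`` spawning to one stream per case and per image, so the
dataset is bit-reproducible file by file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse

from .manifest import DatasetManifest, scan_cmtd_layout, write_manifest

#: standard deviation of the additive per-pixel Gaussian noise (8-bit scale)
PIXEL_NOISE_SD = 3.0


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions for one synthetic dataset.

    Defaults are the package's reference conditions: 20 cases per class of
    8 images each at 96×96 px, a strong nucleus-density effect
    (λ_benign=20 vs λ_malignant=120) and a moderate per-case stain shift
    (sd 8 on the 8-bit scale).  ``image_size`` is (width, height); the
    generator scales to 1024×768 to mimic bench-microscope captures.
    """

    n_cases_per_class: int = 20
    images_per_case: int = 8
    image_size: tuple[int, int] = (96, 96)
    nucleus_rate: dict[str, float] = field(
        default_factory=lambda: {"benign": 20.0, "malignant": 120.0}
    )
    nucleus_radius: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"benign": (4.0, 1.0), "malignant": (5.0, 1.0)}
    )
    stain_shift_sd: float = 8.0
    background_rgb: tuple[int, int, int] = (230, 180, 200)
    nucleus_rgb: tuple[int, int, int] = (90, 60, 140)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases_per_class < 1 or self.images_per_case < 1:
            raise ValueError("n_cases_per_class and images_per_case must be >= 1")
        w, h = self.image_size
        if w < 64 or h < 64:
            raise ValueError(f"image_size must be at least 64x64, got {w}x{h}")
        for lab in ("benign", "malignant"):
            if self.nucleus_rate[lab] < 0:
                raise ValueError(f"nucleus_rate[{lab!r}] must be >= 0")
            mean, sd = self.nucleus_radius[lab]
            if mean <= 0 or sd < 0:
                raise ValueError(f"nucleus_radius[{lab!r}] must have mean>0, sd>=0")
        if self.stain_shift_sd < 0:
            raise ValueError("stain_shift_sd must be >= 0")


def generate_image(
    label: str,
    case_tint: np.ndarray,
    params: SyntheticParams,
    rng: np.random.Generator,
    *,
    return_count: bool = False,
) -> np.ndarray | tuple[np.ndarray, int]:
    """Draw one labelled image.

    Background = ``background_rgb + case_tint`` plus i.i.d. Gaussian pixel
    noise (sd 3, clipped to [0, 255]); then N ~ Poisson(λ_label) ellipses at
    uniform positions, axis radii ~ Normal(mean, sd) truncated at 1 px,
    filled with the exact ``nucleus_rgb`` colour.  Nuclei may overlap; the
    goal is statistical structure, not visual realism.

    With ``return_count=True`` also returns the number of nuclei drawn
    (the direct count the Poisson-rate tests check against).
    """
    w, h = params.image_size
    tint = np.asarray(case_tint, dtype=float)
    base = np.asarray(params.background_rgb, dtype=float) + tint
    img = base[None, None, :] + rng.normal(0.0, PIXEL_NOISE_SD, size=(h, w, 3))
    img = np.clip(img, 0, 255)

    n_nuclei = int(rng.poisson(params.nucleus_rate[label]))
    mean_r, sd_r = params.nucleus_radius[label]
    colour = np.asarray(params.nucleus_rgb, dtype=float)
    for _ in range(n_nuclei):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = max(1.0, rng.normal(mean_r, sd_r))
        rx = max(1.0, rng.normal(mean_r, sd_r))
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
        img[rr, cc] = colour

    out = img.round().astype(np.uint8)
    return (out, n_nuclei) if return_count else out


def generate_dataset(params: SyntheticParams, out_dir: str | Path) -> DatasetManifest:
    """Write a full cmtd-layout dataset and return its scanned manifest.

    One case directory per case (``<label>_s<NN>/``), one RGB tint per case
    drawn N(0, stain_shift_sd) per channel, ``images_per_case`` PNGs per
    case, plus a ``manifest.csv``.  Byte-identical on regeneration with the
    same params.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".histocad_write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory is not writable: {out_dir}") from exc

    root_seq = np.random.SeedSequence(params.seed)
    n_cases = 2 * params.n_cases_per_class
    case_seqs = root_seq.spawn(n_cases)
    labels = ["benign"] * params.n_cases_per_class + [
        "malignant"
    ] * params.n_cases_per_class
    for idx, (label, seq) in enumerate(zip(labels, case_seqs)):
        within = idx % params.n_cases_per_class
        case_dir = out_dir / f"{label}_{label[0]}{within:02d}"
        case_dir.mkdir(exist_ok=True)
        tint_rng = np.random.default_rng(seq)
        tint = tint_rng.normal(0.0, params.stain_shift_sd, size=3)
        for j, img_seq in enumerate(seq.spawn(params.images_per_case)):
            img = generate_image(
                label, tint, params, np.random.default_rng(img_seq)
            )
            Image.fromarray(img, mode="RGB").save(case_dir / f"img_{j:03d}.png")

    manifest = scan_cmtd_layout(out_dir)
    manifest = replace(manifest, layout="synthetic")
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def nucleus_pixel_fraction(
    image: np.ndarray, nucleus_rgb: tuple[int, int, int] = (90, 60, 140)
) -> float:
    """Fraction of pixels exactly matching the nucleus colour.

    A deliberately naive texture statistic: thresholding it at the midpoint
    between the class means is the baseline classifier the effect-size
    tests compare the full pipeline against.
    """
    match = np.all(image == np.asarray(nucleus_rgb, dtype=image.dtype), axis=-1)
    return float(match.mean())
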