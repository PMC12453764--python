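"""Synthetic skin-image cohorts with ground-truth lesion masks and clinical records.

Each cohort emulates the inputs the pipeline consumes in practice: RGB skin
photographs in which diseased cases carry a single textured elliptical lesion
that differs from the surrounding skin in mean intensity and in texture
roughness, a pixel-level lesion mask, and a per-patient clinical record
(age, symptom duration, gender, Fitzpatrick skin type, a medical-history
flag) whose association with the diagnosis has a configurable effect size.

The generator is fully deterministic given ``(config, seed)``: the same
configuration always produces bit-identical images and tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

# Mean RGB of the healthy-skin background, a mid-tone skin colour.
_SKIN_RGB = np.array([0.76, 0.57, 0.45])

GENDERS = ("F", "M")
SKIN_TYPES = ("I", "II", "III", "IV", "V", "VI")

# Fitzpatrick phototype frequencies, roughly mirroring a mixed cohort.
_SKIN_TYPE_P = (0.08, 0.18, 0.28, 0.24, 0.14, 0.08)

_DURATION_MEAN_HEALTHY = 30.0  # days; exponential mean for the healthy class


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_images:
        Number of samples to generate.
    image_size:
        (rows, cols) of every image, pixels.
    prevalence:
        Fraction of diseased samples in [0, 1]; assignment is deterministic
        and stratified, so the realised fraction is within 1/n_images of it.
    lesion_axes_range:
        (min, max) of the ellipse semi-axes, pixels. Must fit in the image.
    lesion_intensity_shift:
        Mean RGB offset of lesion pixels relative to the background
        (lesions are rendered darker by this amount).
    lesion_noise_sd:
        Gaussian texture roughness inside the lesion.
    background_noise_sd:
        Gaussian noise of healthy skin.
    clinical_effect_beta:
        Effect size of the informative continuous covariate
        (symptom_duration): the Bayes log-odds difference between the two
        label-conditional means. 0 makes the covariate uninformative.
    seed:
        Base seed; the full cohort is a pure function of (config, seed).
    """

    n_images: int = 200
    image_size: tuple[int, int] = (64, 64)
    prevalence: float = 0.5
    lesion_axes_range: tuple[float, float] = (8.0, 16.0)
    lesion_intensity_shift: float = 0.2
    lesion_noise_sd: float = 0.08
    background_noise_sd: float = 0.05
    clinical_effect_beta: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_images <= 0:
            raise ValueError(f"n_images must be positive, got {self.n_images}")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.lesion_noise_sd < 0 or self.background_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        lo, hi = self.lesion_axes_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad lesion_axes_range {self.lesion_axes_range}")
        h, w = self.image_size
        if 2 * hi > min(h, w):
            raise ValueError(
                f"lesion semi-axis {hi} px cannot fit inside a {h}x{w} image"
            )


@dataclasses.dataclass
class SynthSample:
    """One synthetic case: image, lesion mask, clinical record and label."""

    image: np.ndarray        # rows x cols x 3, float in [0, 1]
    lesion_mask: np.ndarray  # rows x cols, uint8 in {0, 1}; all-zero iff healthy
    clinical: dict           # age, symptom_duration, gender, skin_type, history_flag
    label: int               # 0 healthy, 1 diseased


def _duration_rates(beta: float) -> tuple[float, float]:
    """Label-conditional exponential rates for symptom_duration.

    The log-likelihood-ratio of two exponentials is linear in x with slope
    (lambda0 - lambda1); evaluating the Bayes log-odds at the two class means
    (1/lambda0 and 1/lambda1) and differencing gives (r-1)^2/r with
    r = lambda0/lambda1. Solving (r-1)^2/r = beta fixes the rate ratio.
    """
    if beta < 0:
        raise ValueError("clinical_effect_beta must be >= 0")
    r = (beta + 2.0 + np.sqrt(beta * beta + 4.0 * beta)) / 2.0
    lam0 = 1.0 / _DURATION_MEAN_HEALTHY
    return lam0, lam0 / r


def _render_image(
    rng: np.random.Generator, config: SynthConfig, diseased: bool
) -> tuple[np.ndarray, np.ndarray]:
    h, w = config.image_size
    image = _SKIN_RGB[None, None, :] + rng.normal(
        0.0, config.background_noise_sd, size=(h, w, 3)
    )
    mask = np.zeros((h, w), dtype=np.uint8)
    if diseased:
        lo, hi = config.lesion_axes_range
        a = rng.uniform(lo, hi)  # semi-axis along rows
        b = rng.uniform(lo, hi)  # semi-axis along cols
        cy = rng.uniform(a, h - a)
        cx = rng.uniform(b, w - b)
        yy, xx = np.mgrid[0:h, 0:w]
        inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        mask[inside] = 1
        lesion = (
            _SKIN_RGB[None, :]
            - config.lesion_intensity_shift
            + rng.normal(0.0, config.lesion_noise_sd, size=(int(inside.sum()), 3))
        )
        image[inside] = lesion
    return np.clip(image, 0.0, 1.0), mask


def _draw_clinical(rng: np.random.Generator, label: int, beta: float) -> dict:
    age = float(np.clip(rng.normal(50.0, 15.0), 18.0, 90.0))
    lam0, lam1 = _duration_rates(beta)
    lam = lam1 if label == 1 else lam0
    duration = float(rng.exponential(1.0 / lam))
    gender = GENDERS[int(rng.integers(len(GENDERS)))]
    skin_type = str(rng.choice(SKIN_TYPES, p=_SKIN_TYPE_P))
    history = int(rng.random() < 0.3)
    return {
        "age": round(age, 1),
        "symptom_duration": round(duration, 2),
        "gender": gender,
        "skin_type": skin_type,
        "history_flag": history,
    }


def generate_cohort(config: SynthConfig) -> list[SynthSample]:
    """Generate a deterministic cohort of ``config.n_images`` samples.

    Label assignment is stratified: exactly ``round(n * prevalence)`` samples
    are diseased, then the label order is shuffled by the seeded generator,
    so the realised prevalence is always within 1/n of the requested one.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_images
    n_dis = int(round(n * config.prevalence))
    labels = np.zeros(n, dtype=int)
    labels[:n_dis] = 1
    rng.shuffle(labels)

    samples = []
    for i in range(n):
        label = int(labels[i])
        image, mask = _render_image(rng, config, diseased=bool(label))
        clinical = _draw_clinical(rng, label, config.clinical_effect_beta)
        samples.append(SynthSample(image=image, lesion_mask=mask, clinical=clinical, label=label))
    return samples


def write_cohort(samples: list[SynthSample], directory: str | Path) -> dict:
    """Write a cohort to disk; returns a manifest of everything written.

    Layout: ``img_<k>.png`` (8-bit RGB), ``mask_<k>.png`` (8-bit grayscale,
    0/255), ``clinical.csv`` keyed by image filename, ``manifest.json``.
    Reading the directory back reproduces the samples to within the 8-bit
    quantization of PNG (1/255 per channel).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc

    rows = []
    image_paths, mask_paths = [], []
    for k, s in enumerate(samples):
        img_name, mask_name = f"img_{k:05d}.png", f"mask_{k:05d}.png"
        img8 = np.round(np.clip(s.image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(img8, mode="RGB").save(directory / img_name)
        Image.fromarray((s.lesion_mask * 255).astype(np.uint8), mode="L").save(
            directory / mask_name
        )
        rows.append({"image": img_name, **s.clinical, "label": s.label})
        image_paths.append(img_name)
        mask_paths.append(mask_name)

    columns = ["image", "age", "symptom_duration", "gender", "skin_type",
               "history_flag", "label"]
    table = pd.DataFrame(rows, columns=columns)
    table.to_csv(directory / "clinical.csv", index=False)

    manifest = {
        "n_images": len(samples),
        "images": image_paths,
        "masks": mask_paths,
        "clinical_table": "clinical.csv",
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory: str | Path) -> list[SynthSample]:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    table = pd.read_csv(directory / "clinical.csv")
    table = table.set_index("image")
    samples = []
    for img_name, mask_name in zip(manifest["images"], manifest["masks"]):
        image = np.asarray(Image.open(directory / img_name), dtype=np.float64) / 255.0
        mask = (np.asarray(Image.open(directory / mask_name)) > 127).astype(np.uint8)
        row = table.loc[img_name]
        clinical = {
            "age": float(row["age"]),
            "symptom_duration": float(row["symptom_duration"]),
            "gender": str(row["gender"]),
            "skin_type": str(row["skin_type"]),
            "history_flag": int(row["history_flag"]),
        }
        samples.append(
            SynthSample(image=image, lesion_mask=mask, clinical=clinical,
                        label=int(row["label"]))
        )
    return samples
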