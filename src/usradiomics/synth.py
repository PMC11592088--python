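"""Synthetic B-mode ultrasound nodule cohorts.

Real thyroid-nodule ultrasound with cytology labels is rarely shareable, so
this module emulates the statistical structure such a study rests on: a
training/internal cohort dominated by benign nodules (default 102 benign +
40 malignant) plus a small external cohort (default 15 benign + 6
malignant). Each case is a single elliptical nodule ROI on a smooth
echogenic background carrying multiplicative gamma speckle. Malignant
nodules differ from benign ones in two ways that sonographers describe on
real images: a Poisson number of small dark (hypoechoic) foci scattered
inside the nodule, and a higher speckle dispersion — together producing the
higher intensity variability over a homogeneous echogenic background that
characterizes the malignant class.

Images are pure texture: no burned-in markers, calipers or annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .prep import GrayImage, ROIMask, write_image, write_mask, write_labels

BENIGN = "benign"
MALIGNANT = "malignant"
TRAIN_INTERNAL = "train_internal"
EXTERNAL = "external"


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the training-cohort conditions.

    ``speckle_shape`` is the gamma shape parameter of the multiplicative
    speckle (unit mean, coefficient of variation ``1/sqrt(shape)``);
    malignant nodules divide it by ``malignant_speckle_contrast**2``, i.e.
    multiply the speckle CV by ``malignant_speckle_contrast``. Dark foci are
    discs whose intensity is multiplied by ``focus_intensity_factor`` (< 1:
    hypoechoic). All effects act only inside the nodule ROI.
    """

    n_benign: int = 102
    n_malignant: int = 40
    image_height: int = 256
    image_width: int = 256
    pixel_spacing_mm: float | tuple[float, float] = 0.1
    bit_depth: int = 8
    speckle_shape: float = 30.0
    roi_axes_range: tuple[int, int] = (30, 60)
    malignant_focus_rate: float = 10.0
    focus_radius_range: tuple[float, float] = (2.0, 5.0)
    focus_intensity_factor: float = 0.2
    malignant_speckle_contrast: float = 1.3
    split: str = TRAIN_INTERNAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("class counts must be >= 0")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not (0 < self.focus_intensity_factor < 1):
            raise ValueError("focus_intensity_factor must be in (0,1): foci are darker")
        if self.malignant_speckle_contrast < 1:
            raise ValueError("malignant_speckle_contrast must be >= 1")
        lo, hi = self.roi_axes_range
        if hi >= min(self.image_height, self.image_width) // 2:
            raise ValueError("roi_axes_range exceeds image bounds")
        if lo <= 0:
            raise ValueError("degenerate ROI axes")

    @property
    def spacing(self) -> tuple[float, float]:
        s = self.pixel_spacing_mm
        if isinstance(s, (int, float)):
            return (float(s), float(s))
        return (float(s[0]), float(s[1]))


def external_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default external cohort: 21 cases, 15 benign / 6 malignant (~71%/29%)."""
    kw = dict(n_benign=15, n_malignant=6, split=EXTERNAL, seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


@dataclass
class SyntheticCase:
    case_id: str
    label: str
    split: str
    image: GrayImage
    mask: ROIMask


def _base_field(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth echogenic background: gentle radial falloff plus large-scale
    smooth variation, on the 8-bit-equivalent scale [0, 1]."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) / h) ** 2 + ((xx - cx) / w) ** 2
    base = 0.62 - 0.18 * r2  # mid-grey centre, mildly darker margins
    lowfreq = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=min(h, w) / 6.0
    )
    lowfreq /= max(lowfreq.std(), 1e-12)
    return base * (1.0 + 0.05 * lowfreq)


def render_case(
    label: str,
    config: CohortConfig,
    rng: np.random.Generator,
    case_id: str = "case",
) -> SyntheticCase:
    """Render one synthetic nodule image + ROI mask.

    Benign: elliptical ROI with homogeneous multiplicative speckle over a
    smooth base. Malignant: same base, speckle CV inflated by
    ``malignant_speckle_contrast``, plus a Poisson(``malignant_focus_rate``)
    number of dark circular foci fully inside the ROI.
    """
    if label not in (BENIGN, MALIGNANT):
        raise ValueError(f"unknown label {label!r}")
    h, w = config.image_height, config.image_width
    base = _base_field(h, w, rng)

    lo, hi = config.roi_axes_range
    a = rng.uniform(lo, hi)  # semi-axes, mild random eccentricity
    b = a * rng.uniform(0.7, 1.0)
    if rng.random() < 0.5:
        a, b = b, a
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2 <= 1.0
    if mask.sum() < 64:
        raise ValueError("degenerate ROI: fewer than 64 pixels")

    shape = config.speckle_shape
    if label == MALIGNANT:
        shape = shape / config.malignant_speckle_contrast**2
    speckle = rng.gamma(shape, 1.0 / shape, size=(h, w))
    # benign-style speckle outside the ROI on malignant images too
    if label == MALIGNANT:
        bg_speckle = rng.gamma(
            config.speckle_shape, 1.0 / config.speckle_shape, size=(h, w)
        )
        speckle = np.where(mask, speckle, bg_speckle)

    img = base * speckle

    if label == MALIGNANT:
        n_foci = rng.poisson(config.malignant_focus_rate)
        r_lo, r_hi = config.focus_radius_range
        attn = np.ones((h, w))
        for _ in range(n_foci):
            r = rng.uniform(r_lo, r_hi)
            # centre such that the disc stays fully inside the ellipse
            for _try in range(50):
                t = rng.uniform(0, 2 * np.pi)
                u = np.sqrt(rng.random())
                fy = cy + u * (b - r) * np.sin(t)
                fx = cx + u * (a - r) * np.cos(t)
                if ((fy - cy) / max(b - r, 1e-9)) ** 2 + (
                    (fx - cx) / max(a - r, 1e-9)
                ) ** 2 <= 1.0:
                    break
            disc = (yy - fy) ** 2 + (xx - fx) ** 2 <= r**2
            attn[disc] *= config.focus_intensity_factor
        img = img * attn

    vmax = 2**config.bit_depth - 1
    img = np.clip(np.rint(img * vmax), 0, vmax)
    return SyntheticCase(
        case_id=case_id,
        label=label,
        split=config.split,
        image=GrayImage(img, config.spacing, config.bit_depth),
        mask=ROIMask(mask),
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticCase]:
    """Generate the full cohort: exactly ``n_benign + n_malignant`` cases,
    deterministic given ``config.seed``.

    Labels are interleaved deterministically (shuffled once with the cohort
    seed) so case ordering carries no class information.
    """
    rng = np.random.default_rng(config.seed)
    labels = [BENIGN] * config.n_benign + [MALIGNANT] * config.n_malignant
    labels = [labels[i] for i in rng.permutation(len(labels))]
    cases = []
    for i, label in enumerate(labels):
        cid = f"{config.split}_{i:04d}"
        cases.append(render_case(label, config, rng, case_id=cid))
    return cases


def write_cohort(
    cases: list[SyntheticCase],
    out_dir: str | Path,
    config: CohortConfig | None = None,
    use_tiff: bool = False,
) -> Path:
    """Write a cohort to disk: images (PNG, or 16-bit TIFF via flag), 0/255
    PNG masks, a labels CSV and a manifest JSON recording config and seed."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        ext = "tiff" if use_tiff else "png"
        write_image(case.image, out / "images" / f"{case.case_id}.{ext}")
        write_mask(case.mask, out / "masks" / f"{case.case_id}.png")
        rows.append(
            {"case_id": case.case_id, "label": case.label, "split": case.split}
        )
    write_labels(rows, out / "labels.csv")
    if config is not None:
        manifest = {"config": asdict(config), "n_cases": len(cases)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
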