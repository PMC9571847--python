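"""Synthetic specimen photographs with known ground-truth chromaticity.

The generator emulates the photographic setup of the staining assay: a
near-uniform coloured patch (the stained specimen under fixed illumination)
with per-pixel Gaussian sensor noise, 8-bit quantization, and optional
radial vignetting.  Because the base colour is constructed by exactly
inverting the forward RGB→XYZ→xy path, every pipeline stage can be tested
against known truth without real photographs.

Seeding: a master seed expands to per-image seeds by the fixed arithmetic
``(master + 10007 · image_index) mod 2³¹``, so any subset of images is
reproducible from the master seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from cvchroma.colorspace import (
    ConversionOptions,
    RGB_TO_XYZ_MATRIX,
    encode_channel,
)
from cvchroma.imaging import ImageRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "SyntheticExperiment",
    "xy_to_encoded_rgb",
    "generate_specimen_image",
    "generate_experiment",
]

_SEED_STRIDE = 10007
_SEED_MOD = 2**31


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic specimen photograph.

    Parameters
    ----------
    target_xy
        Ground-truth chromaticity of the patch; must be reachable by the
        RGB matrix gamut at the given luminance.
    luminance_Y
        Relative luminance in (0, 1].
    noise_sd
        Per-channel Gaussian noise SD in 8-bit units (camera sensor noise).
    size
        (H, W) in pixels, at least 4×4.
    seed
        RNG seed for the noise field.
    vignette_strength
        Radial darkening toward corners, in [0, 1); 0 disables it.
    """

    target_xy: tuple[float, float]
    luminance_Y: float = 0.35
    noise_sd: float = 5.0
    size: tuple[int, int] = (64, 64)
    seed: int = 0
    vignette_strength: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.luminance_Y <= 1):
            raise ValueError(f"luminance_Y must be in (0, 1], got {self.luminance_Y}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.size[0] < 4 or self.size[1] < 4:
            raise ValueError(f"size must be at least 4×4, got {self.size}")
        if not (0 <= self.vignette_strength < 1):
            raise ValueError("vignette_strength must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticExperiment:
    """A multi-condition replicate design for the synthetic generator.

    ``conditions`` is a list of (name, SyntheticSpec, replicate_count).
    ``drift`` optionally records the per-day chromaticity displacement the
    condition series was built with (increasing stain moves chromaticity
    toward the lower left of the xy diagram); it is metadata only.
    """

    conditions: tuple = ()
    drift: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("experiment needs at least one condition")
        for name, spec, n in self.conditions:
            if n < 1:
                raise ValueError(f"condition {name!r}: replicate count must be ≥ 1")

    @staticmethod
    def staining_series(
        base_xy: tuple[float, float],
        days: tuple[int, ...] = (0, 1, 3),
        drift_per_day: tuple[float, float] = (-0.0022, -0.0030),
        replicates: int = 3,
        luminance_Y: float = 0.35,
        noise_sd: float = 5.0,
        size: tuple[int, int] = (64, 64),
        substrate: str = "Ti",
    ) -> "SyntheticExperiment":
        """Immersion-time series: chromaticity drifts from ``base_xy`` by
        ``drift_per_day`` per day of immersion, emulating the lower-left
        shift of increasing crystal-violet stain."""
        conds = []
        for day in days:
            xy = (
                base_xy[0] + day * drift_per_day[0],
                base_xy[1] + day * drift_per_day[1],
            )
            name = f"{substrate} only" if day == 0 else f"{substrate} day {day}"
            spec = SyntheticSpec(
                target_xy=xy, luminance_Y=luminance_Y, noise_sd=noise_sd, size=size
            )
            conds.append((name, spec, replicates))
        return SyntheticExperiment(conditions=tuple(conds), drift=drift_per_day)


def xy_to_encoded_rgb(
    xy: tuple[float, float],
    Y: float,
    options: ConversionOptions = ConversionOptions(),
) -> np.ndarray:
    """Invert the forward path: chromaticity + luminance → encoded RGB.

    Reconstructs XYZ from (x, y, Y), applies the inverse of the RGB→XYZ
    matrix, and gamma-encodes (if ``options.linearize``).  The forward
    conversion of the result reproduces (x, y, Y) to ≤ 1e−9 before 8-bit
    quantization.

    Raises
    ------
    ValueError
        If the implied linear RGB leaves [0, 1] — the target is outside the
        matrix gamut at this luminance; the message names the channel.
    """
    x, yc = float(xy[0]), float(xy[1])
    if yc <= 0:
        raise ValueError(f"chromaticity y must be > 0 to reconstruct XYZ, got {yc}")
    if not (0 < Y <= 1):
        raise ValueError(f"luminance Y must be in (0, 1], got {Y}")
    X = x * Y / yc
    Z = (1.0 - x - yc) * Y / yc
    xyz = np.array([X, Y, Z])
    linear = np.linalg.solve(RGB_TO_XYZ_MATRIX, xyz)
    tol = 1e-9
    for name, v in zip("RGB", linear):
        if v < -tol or v > 1 + tol:
            raise ValueError(
                f"target xy={xy} at Y={Y} is out of gamut: linear {name} = {v:.6f} "
                "outside [0, 1]"
            )
    linear = np.clip(linear, 0.0, 1.0)
    return np.asarray(encode_channel(linear, options))


def _per_image_seed(master_seed: int, index: int) -> int:
    return (int(master_seed) + _SEED_STRIDE * int(index)) % _SEED_MOD


def generate_specimen_image(
    spec: SyntheticSpec, options: ConversionOptions = ConversionOptions()
) -> tuple[ImageRecord, dict]:
    """Render one synthetic specimen photo and its ground-truth record.

    The base colour comes from :func:`xy_to_encoded_rgb`; vignetting (if
    any) darkens linear light radially by ``1 − strength·(r/r_max)²``;
    i.i.d. Gaussian noise (``noise_sd`` 8-bit units, seeded) is added per
    pixel per channel; values are rounded half-to-even and clipped to
    [0, 255].  Identical specs give byte-identical images.
    """
    h, w = spec.size
    base_encoded = xy_to_encoded_rgb(spec.target_xy, spec.luminance_Y, options)

    if spec.vignette_strength > 0:
        from cvchroma.colorspace import decode_channel

        rr, cc = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r2 = ((rr - cy) ** 2 + (cc - cx) ** 2) / (cy**2 + cx**2)
        scale = 1.0 - spec.vignette_strength * r2
        linear = np.asarray(decode_channel(base_encoded, options))
        field_lin = linear[np.newaxis, np.newaxis, :] * scale[:, :, np.newaxis]
        field_enc = np.asarray(encode_channel(field_lin, options))
        base = field_enc * 255.0
    else:
        base = np.broadcast_to(base_encoded * 255.0, (h, w, 3)).copy()

    rng = np.random.default_rng(spec.seed)
    noisy = base + rng.normal(0.0, spec.noise_sd, size=(h, w, 3)) if spec.noise_sd > 0 else base
    quantized = np.round(noisy)
    n_clipped = int(((quantized < 0) | (quantized > 255)).sum())
    if n_clipped > 0.001 * quantized.size:
        logger.warning(
            "%.2f%% of pixel samples clipped at the 8-bit range",
            100.0 * n_clipped / quantized.size,
        )
    pixels = np.clip(quantized, 0, 255).astype(np.uint8)
    truth = {
        "target_xy": [float(spec.target_xy[0]), float(spec.target_xy[1])],
        "luminance_Y": spec.luminance_Y,
        "noise_sd": spec.noise_sd,
        "size": list(spec.size),
        "seed": spec.seed,
        "vignette_strength": spec.vignette_strength,
        "base_encoded_rgb": [float(v) for v in base_encoded],
        "n_clipped": n_clipped,
    }
    return ImageRecord(pixels=pixels, source_path="<synthetic>"), truth


def generate_experiment(
    exp: SyntheticExperiment,
    out_dir,
    master_seed: int = 0,
    options: ConversionOptions = ConversionOptions(),
) -> Path:
    """Write a full synthetic experiment: PNGs, sample sheet, truth JSON.

    Per-image seeds are derived from ``master_seed`` by the documented
    fixed arithmetic, so reruns with the same master seed are
    byte-identical.  Returns the path of the generated sample sheet, which
    is directly consumable by :func:`cvchroma.quantify.run_experiment`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = {}
    index = 0
    for name, spec, n_rep in exp.conditions:
        for rep in range(n_rep):
            seed = _per_image_seed(master_seed, index)
            rep_spec = dataclasses.replace(spec, seed=seed)
            image, truth = generate_specimen_image(rep_spec, options)
            specimen_id = f"{name.replace(' ', '_')}_r{rep + 1}"
            fname = f"{specimen_id}.png"
            Image.fromarray(image.pixels).save(out_dir / fname)
            h, w = image.shape
            rows.append(
                {
                    "specimen_id": specimen_id,
                    "condition": name,
                    "image_path": fname,
                    "r0": 0,
                    "r1": h,
                    "c0": 0,
                    "c1": w,
                }
            )
            truths[specimen_id] = truth
            index += 1

    import pandas as pd

    sheet_path = out_dir / "sample_sheet.csv"
    pd.DataFrame(rows).to_csv(sheet_path, index=False)
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "master_seed": master_seed,
                "drift": list(exp.drift) if exp.drift else None,
                "options": options.summary(),
                "specimens": truths,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return sheet_path
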