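"""Specimen measurement, replicate-group summaries, and ΔC between groups.

A specimen photograph is reduced to one chromaticity point either by the
default *mean-then-convert* route (histogram → mean encoded RGB → gamma
decode → XYZ → xy, matching the histogram workflow of the photographic
method) or *per-pixel* (each pixel projected to xy, black pixels excluded,
coordinates averaged).  For near-uniform stained patches the two routes
differ negligibly; both are provided and the choice is recorded in every
output row.

Replicate groups are summarized by the arithmetic mean and sample standard
deviation (n−1 denominator) of x and y, and conditions are compared with the
ΔC Euclidean distance between group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cvchroma.colorspace import (
    ConversionOptions,
    decode_channel,
    delta_c,
    delta_e_ab,
    rgb_to_xyz,
    xyz_to_lab,
    xyz_to_xy,
)
from cvchroma.imaging import (
    ImageRecord,
    ROISpec,
    compute_histogram,
    histogram_mean,
    load_image,
    resolve_roi,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpecimenMeasurement",
    "GroupSummary",
    "ColorDifferenceResult",
    "measure_specimen",
    "summarize_group",
    "compare_groups",
    "run_experiment",
    "ExperimentResult",
]

MODES = ("mean-then-convert", "per-pixel")


@dataclass(frozen=True)
class SpecimenMeasurement:
    """One image + ROI reduced to a chromaticity point (with L*a*b*)."""

    specimen_id: str
    condition: str
    x: float
    y: float
    L: float
    a: float
    b: float
    mean_r: float
    mean_g: float
    mean_b: float
    n_pixels: int
    mode: str
    linearize: bool
    n_black_excluded: int = 0

    @property
    def chromaticity(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class GroupSummary:
    """Mean and sample SD of (x, y) over the replicates of one condition."""

    condition: str
    n: int
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    single_replicate: bool = False  # SDs reported as 0 when n = 1

    @property
    def mean(self) -> tuple[float, float]:
        return (self.mean_x, self.mean_y)


@dataclass(frozen=True)
class ColorDifferenceResult:
    """ΔC (and optionally ΔE*ab) between two condition means."""

    condition_a: str
    condition_b: str
    delta_c: float
    delta_e_ab: float | None = None


def measure_specimen(
    image: ImageRecord,
    roi: ROISpec,
    options: ConversionOptions = ConversionOptions(),
    mode: str = "mean-then-convert",
    specimen_id: str = "",
    condition: str = "",
) -> SpecimenMeasurement:
    """Reduce one image + ROI to a single chromaticity measurement.

    ``mean-then-convert`` (default): ROI histogram → per-channel mean →
    gamma decode → XYZ → (x, y).  ``per-pixel``: every ROI pixel is
    converted to (x, y) individually (black pixels excluded with a logged
    count) and the coordinates are averaged.

    Raises
    ------
    ValueError
        In mean mode when the ROI mean is pure black; in per-pixel mode
        when every ROI pixel is black — chromaticity is undefined there.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    mask = resolve_roi(image, roi)
    hist = compute_histogram(image, mask)
    mean_rgb = histogram_mean(hist)
    n_black = 0

    if mode == "mean-then-convert":
        linear = decode_channel(mean_rgb, options)
        xyz = rgb_to_xyz(linear)
        if xyz.sum() == 0:
            raise ValueError(
                f"specimen {specimen_id or '<unnamed>'}: ROI mean is pure black; "
                "chromaticity undefined"
            )
        xy = xyz_to_xy(xyz)
        lab = xyz_to_lab(xyz, options)
    else:
        encoded = image.pixels[mask].astype(float) / 255.0
        linear = decode_channel(encoded, options)
        xyz = rgb_to_xyz(linear)
        nonblack = xyz.sum(axis=-1) > 0
        n_black = int((~nonblack).sum())
        if n_black:
            logger.info(
                "specimen %s: excluded %d black pixel(s) from per-pixel "
                "chromaticity",
                specimen_id or "<unnamed>",
                n_black,
            )
        if not nonblack.any():
            raise ValueError(
                f"specimen {specimen_id or '<unnamed>'}: every ROI pixel is "
                "black; chromaticity undefined"
            )
        xy = xyz_to_xy(xyz[nonblack]).mean(axis=0)
        lab = xyz_to_lab(xyz.mean(axis=0), options)

    return SpecimenMeasurement(
        specimen_id=specimen_id,
        condition=condition,
        x=float(xy[0]),
        y=float(xy[1]),
        L=float(lab[0]),
        a=float(lab[1]),
        b=float(lab[2]),
        mean_r=float(mean_rgb[0]),
        mean_g=float(mean_rgb[1]),
        mean_b=float(mean_rgb[2]),
        n_pixels=hist.n_pixels,
        mode=mode,
        linearize=options.linearize,
        n_black_excluded=n_black,
    )


def summarize_group(
    measurements: list[SpecimenMeasurement], condition: str | None = None
) -> GroupSummary:
    """Mean and sample SD (n−1) of chromaticity across replicates.

    With a single replicate the SDs are reported as 0 and the summary is
    flagged ``single_replicate``.
    """
    if not measurements:
        raise ValueError("cannot summarize an empty measurement list")
    conditions = {m.condition for m in measurements}
    if condition is None:
        if len(conditions) != 1:
            raise ValueError(f"mixed conditions in group: {sorted(conditions)}")
        condition = next(iter(conditions))
    elif conditions != {condition}:
        raise ValueError(
            f"measurements belong to {sorted(conditions)}, expected {condition!r}"
        )
    xs = np.array([m.x for m in measurements])
    ys = np.array([m.y for m in measurements])
    n = len(measurements)
    if n == 1:
        return GroupSummary(condition, 1, float(xs[0]), float(ys[0]), 0.0, 0.0, True)
    return GroupSummary(
        condition=condition,
        n=n,
        mean_x=float(xs.mean()),
        mean_y=float(ys.mean()),
        sd_x=float(xs.std(ddof=1)),
        sd_y=float(ys.std(ddof=1)),
    )


def compare_groups(
    a: GroupSummary,
    b: GroupSummary,
    lab_a: tuple[float, float, float] | None = None,
    lab_b: tuple[float, float, float] | None = None,
) -> ColorDifferenceResult:
    """ΔC between the mean chromaticity points of two groups (symmetric)."""
    dc = delta_c(a.mean, b.mean)
    de = delta_e_ab(lab_a, lab_b) if lab_a is not None and lab_b is not None else None
    return ColorDifferenceResult(a.condition, b.condition, dc, de)


@dataclass
class ExperimentResult:
    """Tables produced by :func:`run_experiment` plus per-row failures."""

    measurements: pd.DataFrame
    summaries: pd.DataFrame
    differences: pd.DataFrame
    errors: list[dict]
    options: ConversionOptions
    mode: str
    baseline: str


def _roi_from_row(row: pd.Series, image: ImageRecord, sheet_dir: Path) -> ROISpec:
    if "mask_path" in row and isinstance(row["mask_path"], str) and row["mask_path"]:
        mask_img = load_image(sheet_dir / row["mask_path"], allow_grayscale=True)
        return ROISpec(kind="mask", mask=mask_img.pixels[:, :, 0] > 0)
    cols = ("r0", "r1", "c0", "c1")
    if all(c in row and pd.notna(row[c]) for c in cols):
        return ROISpec.rectangle(*(int(row[c]) for c in cols))
    return ROISpec.centered_fraction(image.shape)


def run_experiment(
    sample_sheet: pd.DataFrame | str | Path,
    options: ConversionOptions = ConversionOptions(),
    mode: str = "mean-then-convert",
    baseline: str | None = None,
) -> ExperimentResult:
    """Run the full pipeline over a sample sheet.

    The sheet needs columns ``specimen_id``, ``condition``, ``image_path``
    and optionally an ROI per row (``r0, r1, c0, c1`` or ``mask_path``;
    default is a centered rectangle covering 60% of each dimension).
    Relative image paths are resolved against the sheet's directory.

    Rows whose image cannot be read are collected as per-row errors rather
    than aborting the run; if every row fails, a ``RuntimeError`` is raised.
    Pairwise ΔC is computed between each condition and the ``baseline``
    condition (default: the first condition in the sheet, conventionally the
    unstained/day-0 substrate).  Output tables are sorted by condition and
    specimen id, so row order in the sheet does not affect the results.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if isinstance(sample_sheet, (str, Path)):
        sheet_dir = Path(sample_sheet).parent
        sheet = pd.read_csv(sample_sheet, dtype={"specimen_id": str, "condition": str})
    else:
        sheet_dir = Path(".")
        sheet = sample_sheet.copy()
    required = {"specimen_id", "condition", "image_path"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")

    measurements: list[SpecimenMeasurement] = []
    errors: list[dict] = []
    for _, row in sheet.iterrows():
        img_path = Path(row["image_path"])
        if not img_path.is_absolute():
            img_path = sheet_dir / img_path
        try:
            image = load_image(img_path)
            roi = _roi_from_row(row, image, sheet_dir)
            m = measure_specimen(
                image,
                roi,
                options=options,
                mode=mode,
                specimen_id=str(row["specimen_id"]),
                condition=str(row["condition"]),
            )
            measurements.append(m)
        except (OSError, ValueError) as exc:
            logger.warning("row %r failed: %s", str(row["specimen_id"]), exc)
            errors.append({"specimen_id": str(row["specimen_id"]), "error": str(exc)})
    if not measurements:
        raise RuntimeError(
            f"all {len(sheet)} sample-sheet rows failed; first error: "
            f"{errors[0]['error'] if errors else 'empty sheet'}"
        )

    meas_df = pd.DataFrame([vars(m) for m in measurements]).sort_values(
        ["condition", "specimen_id"], kind="mergesort", ignore_index=True
    )

    # stable condition order: baseline first, then sheet appearance order
    cond_order = list(dict.fromkeys(sheet["condition"].astype(str)))
    measured_conds = [c for c in cond_order if c in set(meas_df["condition"])]
    if baseline is None:
        baseline = measured_conds[0]
    elif baseline not in measured_conds:
        raise ValueError(
            f"baseline condition {baseline!r} not among measured conditions "
            f"{measured_conds}"
        )

    summaries = {
        cond: summarize_group(
            [m for m in measurements if m.condition == cond], cond
        )
        for cond in measured_conds
    }
    summ_df = pd.DataFrame([vars(summaries[c]) for c in measured_conds])

    base = summaries[baseline]
    diffs = [
        compare_groups(base, summaries[c])
        for c in measured_conds
        if c != baseline
    ]
    diff_df = pd.DataFrame(
        [
            {
                "condition_a": d.condition_a,
                "condition_b": d.condition_b,
                "delta_c": float(f"{d.delta_c:.5g}"),
            }
            for d in diffs
        ],
        columns=["condition_a", "condition_b", "delta_c"],
    )

    return ExperimentResult(
        measurements=meas_df,
        summaries=summ_df,
        differences=diff_df,
        errors=errors,
        options=options,
        mode=mode,
        baseline=baseline,
    )
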