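"""ROI-based objective image-quality metrics: attenuation, noise and CNR.

Attenuation is the mean HU over a circular ROI, image noise the standard
deviation of HU, and the contrast-to-noise ratio

    CNR = (HU_coronary - HU_fat) / SD_coronary

where the noise term is the coronary ROI's own SD. The fat ROI's SD is also
of interest (clinical reports quote noise measured in adipose tissue) and is
reported separately as the image-noise column of the summary table; both
quantities are computed.

Pixel inclusion follows the pixel-centre-in-disk rule (no partial-area
weighting), matching the circular-ROI semantics of common measurement tools,
and the SD uses the n-1 sample denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import CircularROI, GeometryError, ImageVolume


class DegenerateROIError(ValueError):
    """The ROI selects no pixel (radius below the pixel pitch)."""


class UndefinedCNRError(ZeroDivisionError):
    """CNR is undefined because the coronary ROI has zero SD."""


@dataclass(frozen=True)
class ROIMetrics:
    label: str
    mean_hu: float
    sd_hu: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass(frozen=True)
class CNRResult:
    coronary_label: str
    cnr: float


def roi_pixel_mask(volume: ImageVolume, roi: CircularROI) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within the ROI radius."""
    plane = volume.axial_slice(roi.slice_index) if volume.data.ndim == 3 else volume
    ny, nx = plane.data.shape
    sy, sx = plane.spacing
    cy, cx = roi.center
    if (
        cy - roi.radius < 0
        or cx - roi.radius < 0
        or cy + roi.radius > ny * sy
        or cx + roi.radius > nx * sx
    ):
        raise GeometryError(
            f"ROI '{roi.label}' extends outside the image bounds"
        )
    y = (np.arange(ny) + 0.5) * sy - cy
    x = (np.arange(nx) + 0.5) * sx - cx
    return (y[:, None] ** 2 + x[None, :] ** 2) <= roi.radius**2


def roi_mean_sd(volume: ImageVolume, roi: CircularROI) -> ROIMetrics:
    """Mean and sample SD of attenuation over a circular ROI.

    A single-pixel ROI reports SD 0 (the sample SD is undefined at n = 1).
    """
    plane = volume.axial_slice(roi.slice_index) if volume.data.ndim == 3 else volume
    mask = roi_pixel_mask(plane, roi)
    vals = plane.data[mask]
    if vals.size == 0:
        raise DegenerateROIError(
            f"ROI '{roi.label}' (radius {roi.radius} mm) selects no pixel"
        )
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ROIMetrics(roi.label, float(np.mean(vals)), sd, int(vals.size))


def cnr(coronary: ROIMetrics, fat: ROIMetrics) -> CNRResult:
    """Contrast-to-noise ratio of a coronary/fat ROI pair.

    The denominator is the coronary ROI's SD; a zero SD makes the ratio
    undefined and raises rather than returning infinity.
    """
    if coronary.sd_hu <= 0:
        raise UndefinedCNRError(
            f"CNR undefined for ROI '{coronary.label}': coronary SD is 0"
        )
    return CNRResult(
        coronary.label, (coronary.mean_hu - fat.mean_hu) / coronary.sd_hu
    )


def prox_dist_of(label: str) -> str:
    """Group a coronary ROI label into the proximal/distal split."""
    if label.endswith("_dist"):
        return "distal"
    return "proximal"  # LM and *_prox


def metrics_table(
    metrics: pd.DataFrame,
    by_location: bool = False,
    expected_grid: "list | None" = None,
) -> pd.DataFrame:
    """Per-(family, level) summary of attenuation, noise and CNR.

    ``metrics`` is the tidy per-ROI table (columns ``subject, family, level,
    label, mean_hu, sd_hu, n_pixels, cnr``; ``cnr`` is NaN for the fat ROI).
    The summary reports, per reconstruction cell: mean +/- SD across
    subjects and coronary ROIs of attenuation and CNR, and of the fat-ROI SD
    as the image-noise column — the shape of a per-kernel results table.
    With ``by_location`` the coronary rows are additionally split into
    proximal/distal. Cells of ``expected_grid`` (``(family, level)`` pairs)
    that are absent from the data are reported as NaN rows rather than
    silently dropped.
    """
    df = metrics.copy()
    is_fat = df["label"] == "fat"
    cor = df[~is_fat].copy()
    fat = df[is_fat]
    keys = ["family", "level"]
    if by_location:
        cor["prox_dist"] = cor["label"].map(prox_dist_of)
        cor_keys = keys + ["prox_dist"]
    else:
        cor_keys = keys

    def _msd(g: pd.Series) -> tuple[float, float]:
        return float(g.mean()), float(g.std(ddof=1)) if len(g) > 1 else 0.0

    rows = []
    cor_groups = dict(tuple(cor.groupby(cor_keys, sort=False)))
    fat_groups = dict(tuple(fat.groupby(keys, sort=False)))
    cells = list(cor_groups.keys())
    if expected_grid is not None:
        present = {(k[0], k[1]) for k in cells}
        for cell in expected_grid:
            if tuple(cell) not in present:
                cells.append(
                    tuple(cell) + (("proximal",) if by_location else ())
                )
    for key in cells:
        fam, lvl = key[0], key[1]
        g = cor_groups.get(key)
        fg = fat_groups.get((fam, lvl))
        row = {"family": fam, "level": lvl}
        if by_location:
            row["prox_dist"] = key[2]
        if g is None:
            row.update(
                attenuation_mean=np.nan, attenuation_sd=np.nan,
                noise_mean=np.nan, noise_sd=np.nan,
                cnr_mean=np.nan, cnr_sd=np.nan, n=0,
            )
        else:
            am, asd = _msd(g["mean_hu"])
            cm, csd = _msd(g["cnr"].dropna())
            nm, nsd = (_msd(fg["sd_hu"]) if fg is not None else (np.nan, np.nan))
            row.update(
                attenuation_mean=am, attenuation_sd=asd,
                noise_mean=nm, noise_sd=nsd,
                cnr_mean=cm, cnr_sd=csd, n=int(len(g)),
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    order = {f: i for i, f in enumerate(("Br", "Bv", "Qr"))}
    sort_cols = ["family", "level"] + (["prox_dist"] if by_location else [])
    out["_f"] = out["family"].map(order)
    out = (
        out.sort_values(["_f", "level"] + (["prox_dist"] if by_location else []),
                        kind="stable")
        .drop(columns="_f")
        .reset_index(drop=True)
    )
    return out
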