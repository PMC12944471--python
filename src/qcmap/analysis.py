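"""ROI statistics and linearity analysis of conductivity maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ShapeError
from .volumes import ConductivityMap, LabelMask

__all__ = ["RoiStat", "LinearFit", "roi_stats", "linearity", "evaluate_map"]


@dataclass
class RoiStat:
    """Mean +/- std of valid conductivity voxels for one label.

    A label whose voxels are all invalid yields an empty record
    (mean and std are None, n_valid is 0) — absence, not zero.
    """

    label: int
    mean: float | None
    std: float | None
    n_valid: int


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def roi_stats(cmap: ConductivityMap, mask: LabelMask) -> list[RoiStat]:
    """Per-label mean/std/count over valid voxels, ordered by label."""
    if cmap.shape != mask.shape:
        raise ShapeError("conductivity map and label mask shapes differ")
    out = []
    for lab in mask.present_labels():
        sel = (mask.labels == lab) & cmap.valid
        n = int(sel.sum())
        if n == 0:
            out.append(RoiStat(label=lab, mean=None, std=None, n_valid=0))
        else:
            vals = cmap.sigma[sel]
            out.append(
                RoiStat(label=lab, mean=float(vals.mean()), std=float(vals.std()), n_valid=n)
            )
    return out


def roi_stats_frame(stats_list: list[RoiStat]) -> pd.DataFrame:
    """Tabular view with units in the column headers."""
    return pd.DataFrame(
        {
            "label": [s.label for s in stats_list],
            "mean_sigma_S_per_m": [s.mean for s in stats_list],
            "std_sigma_S_per_m": [s.std for s in stats_list],
            "n_valid_voxels": [s.n_valid for s in stats_list],
        }
    )


def linearity(x, y) -> LinearFit:
    """Ordinary least-squares line through (x, y) and its R^2.

    Used to quantify how linearly the recovered per-tube conductivities track
    the nominal NaCl concentrations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("x and y must be 1D and equal length")
    if x.size < 3:
        raise DegenerateInputError("linearity needs at least 3 points")
    if np.all(x == x[0]):
        raise DegenerateInputError("all x values equal; slope undefined")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def evaluate_map(
    cmap: ConductivityMap,
    truth_sigma: np.ndarray,
    mask: LabelMask,
    nominal_x: list[float] | None = None,
) -> dict:
    """Compare a reconstructed map against a known ground-truth field.

    Returns per-label bias, RMSE, mean +/- std and count over valid voxels,
    plus (when ``nominal_x`` gives one value per label) the OLS linearity of
    per-label means against those nominal values.
    """
    truth_sigma = np.asarray(truth_sigma, dtype=float)
    if truth_sigma.shape != cmap.shape or mask.shape != cmap.shape:
        raise ShapeError("map, truth and mask must be aligned")
    rows = []
    means = []
    for lab in mask.present_labels():
        sel = (mask.labels == lab) & cmap.valid
        n = int(sel.sum())
        if n == 0:
            rows.append(
                {"label": lab, "mean_S_per_m": None, "std_S_per_m": None,
                 "bias_S_per_m": None, "rmse_S_per_m": None, "n_valid": 0}
            )
            means.append(np.nan)
            continue
        err = cmap.sigma[sel] - truth_sigma[sel]
        rows.append(
            {
                "label": lab,
                "mean_S_per_m": float(cmap.sigma[sel].mean()),
                "std_S_per_m": float(cmap.sigma[sel].std()),
                "bias_S_per_m": float(err.mean()),
                "rmse_S_per_m": float(np.sqrt(np.mean(err**2))),
                "n_valid": n,
            }
        )
        means.append(float(cmap.sigma[sel].mean()))
    report: dict = {"per_label": rows}
    if nominal_x is not None and len(nominal_x) == len(rows) and np.isfinite(means).all():
        fit = linearity(np.asarray(nominal_x, dtype=float), np.asarray(means))
        report["linearity"] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
        }
    return report
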