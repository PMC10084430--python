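"""Migration accuracy statistics for micrometer displacement series.

A displacement series is 35 stereoradiographs: five baseline recordings and
two each at 10, 20, 30, 40, 50, 100, 200, 300, 400, 500, 1000, 2000, 3000,
4000, 5000 um of imposed axial micrometer displacement.  The measured
displacement is the difference between an exam's estimated position and the
coordinate-wise median of the five baseline positions; because the
micrometer axes and the cage axes are never perfectly aligned, the measured
3D displacements are projected onto the axial direction obtained from a
total-least-squares line fit of the series' own displacement estimates.
The error is measured minus imposed displacement, summarized per
method / bone / view / axis as mean (SD) and as Bland-Altman bias with
limits of agreement (LOA = bias +/- 1.96 SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROTOCOL_DISPLACEMENTS_UM = (10, 20, 30, 40, 50, 100, 200, 300, 400, 500,
                             1000, 2000, 3000, 4000, 5000)
N_BASELINE = 5
LOA_FACTOR = 1.96


class MigrationError(ValueError):
    """Unusable displacement series or statistics input."""


@dataclass
class DisplacementSeries:
    """Estimated positions of one body across one micrometer series."""

    positions: np.ndarray       # (n, 3) estimated positions, mm
    imposed_um: np.ndarray      # (n,) imposed displacement, 0 = baseline
    method: str = ""
    bone: str = ""
    view: str = "AP"
    axis_label: str = "x"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.imposed_um = np.asarray(self.imposed_um, float).reshape(-1)
        if len(self.positions) != len(self.imposed_um):
            raise MigrationError("positions and imposed arrays differ in length")

    @property
    def is_baseline(self) -> np.ndarray:
        return self.imposed_um == 0


def baseline_position(series: DisplacementSeries) -> np.ndarray:
    """Coordinate-wise median of the baseline recordings (5 by protocol).

    The median makes the zero-position estimate robust to a single gross
    outlier among the baseline recordings.
    """
    base = series.positions[series.is_baseline]
    if len(base) == 0:
        raise MigrationError("series has no baseline recordings")
    if len(base) != N_BASELINE:
        import warnings

        warnings.warn(f"baseline has {len(base)} recordings, protocol is "
                      f"{N_BASELINE}", stacklevel=2)
    return np.median(base, axis=0)


def fit_axis(marker_displacements: np.ndarray) -> np.ndarray:
    """Axial direction: total-least-squares line through the origin.

    First principal direction of the displacement cloud, unit norm, signed
    to correlate positively with the displacement magnitudes.
    """
    D = np.asarray(marker_displacements, float).reshape(-1, 3)
    if len(D) < 2 or not np.any(np.linalg.norm(D, axis=1) > 0):
        raise MigrationError("need at least 2 non-zero displacements")
    _, _, Vt = np.linalg.svd(D, full_matrices=False)
    axis = Vt[0]
    if (D @ axis).sum() < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def project_displacement(series: DisplacementSeries, axis: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Measured scalar displacements along ``axis`` and their errors (mm)."""
    axis = np.asarray(axis, float)
    base = baseline_position(series)
    measured = (series.positions - base) @ axis
    errors = measured - series.imposed_um / 1000.0
    return measured, errors


def analyze_series(series: DisplacementSeries) -> pd.DataFrame:
    """Full single-series analysis: baseline, axis fit, projection, errors."""
    base = baseline_position(series)
    moved = ~series.is_baseline
    disp = series.positions[moved] - base
    axis = fit_axis(disp)
    measured, errors = project_displacement(series, axis)
    return pd.DataFrame({
        "method": series.method, "bone": series.bone, "view": series.view,
        "axis": series.axis_label, "imposed_um": series.imposed_um,
        "measured_mm": measured, "error_mm": errors,
        "is_baseline": series.is_baseline,
    })


@dataclass
class BlandAltmanSummary:
    """Mean bias and limits of agreement with normal-theory 95% CIs.

    ``loa_low/high = bias -/+ 1.96 SD``; the bias CI uses SE = SD/sqrt(n)
    and each LOA limit the standard Bland-Altman SE = SD * sqrt(3/n), both
    at z = 1.96.
    """

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    ci_bias: tuple
    ci_loa_low: tuple
    ci_loa_high: tuple
    n: int


def bland_altman(errors: np.ndarray) -> BlandAltmanSummary:
    """Bland-Altman bias / LOA summary of a set of errors (mm)."""
    e = np.asarray(errors, float).ravel()
    n = len(e)
    if n < 2:
        raise MigrationError("need at least 2 errors for Bland-Altman")
    bias = float(e.mean())
    sd = float(e.std(ddof=1))
    lo = bias - LOA_FACTOR * sd
    hi = bias + LOA_FACTOR * sd
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    z = LOA_FACTOR
    return BlandAltmanSummary(
        bias=bias, sd=sd, loa_low=lo, loa_high=hi,
        ci_bias=(bias - z * se_bias, bias + z * se_bias),
        ci_loa_low=(lo - z * se_loa, lo + z * se_loa),
        ci_loa_high=(hi - z * se_loa, hi + z * se_loa), n=n)


def summarize_accuracy(errors: pd.DataFrame,
                       by: tuple = ("method", "bone", "view", "axis"),
                       pool_views: bool = True) -> pd.DataFrame:
    """Grouped mean (SD) error table, mirroring per-view and combined rows.

    ``errors`` is long-format with at least the grouping columns and
    ``error_mm``.  With ``pool_views`` the per-view groups are additionally
    pooled into rows with view = 'combined'.  Empty groups are omitted.
    """
    if "error_mm" not in errors.columns:
        raise MigrationError("expected an 'error_mm' column")
    df = errors.copy()
    if "is_baseline" in df.columns:
        df = df[~df["is_baseline"]]
    rows = []

    def _agg(sub: pd.DataFrame, keys: dict) -> None:
        if len(sub) == 0:
            return
        rows.append({**keys, "n": len(sub),
                     "mean_mm": sub["error_mm"].mean(),
                     "sd_mm": sub["error_mm"].std(ddof=1)})

    for key, sub in df.groupby(list(by), sort=True):
        _agg(sub, dict(zip(by, key if isinstance(key, tuple) else (key,))))
    if pool_views and "view" in by:
        rest = [b for b in by if b != "view"]
        for key, sub in df.groupby(rest, sort=True):
            keys = dict(zip(rest, key if isinstance(key, tuple) else (key,)))
            keys["view"] = "combined"
            _agg(sub, keys)
    return pd.DataFrame(rows)


def bland_altman_plot(errors: np.ndarray, imposed_mm: np.ndarray, path,
                      title: str = "") -> None:
    """Error-vs-imposed scatter with bias and LOA lines (summary figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = bland_altman(errors)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(imposed_mm, errors, s=12, alpha=0.7)
    for y, style in ((s.bias, "-"), (s.loa_low, "--"), (s.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("imposed displacement (mm)")
    ax.set_ylabel("error (mm)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
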