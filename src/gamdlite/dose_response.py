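"""Mini-G recruitment assay analysis: drift correction, AUC, 4PL fits.

Plate-reader luminescence traces (split-luciferase complementation) are
corrected for substrate-autooxidation drift by pointwise division by the
mean wild-type (non-transfected) control trace, followed by subtraction
of the corrected vehicle (L-15 medium) control.  The post-addition area
under the curve per concentration is normalized to the canonical
system's 100 µM response (100%) and L-15 (0%), and a variable-slope
four-parameter logistic curve

    R(log c) = bottom + (Emax − bottom) / (1 + 10^{(logEC50 − log c)·h})

is fitted, reporting pEC50 = −logEC50, Emax, Hill slope and bottom with
asymptotic standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PlateData",
    "NormalizedResponse",
    "DoseResponseFit",
    "FitError",
    "baseline_correct",
    "compute_auc",
    "normalize_auc",
    "fit_4pl",
    "analyze_plate",
    "four_param_logistic",
]

WILD_TYPE = "wild-type"
L15 = "L-15"

HILL_BOUNDS = (0.2, 5.0)


class FitError(RuntimeError):
    """The 4PL optimizer failed to converge."""


@dataclass
class PlateData:
    """Long-format plate: one row per (well, timepoint).

    Columns: well, condition, conc_molar (NaN for controls), time_min,
    rlu.  Condition labels "wild-type" and "L-15" mark the controls;
    ``baseline_min`` is the pre-addition window length.
    """

    table: pd.DataFrame
    baseline_min: float = 15.0
    post_min: float = 45.0

    REQUIRED = ("well", "condition", "conc_molar", "time_min", "rlu")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"plate table missing columns {missing}")
        for cond in (WILD_TYPE, L15):
            if not (self.table["condition"] == cond).any():
                raise ValueError(f"plate lacks a {cond!r} control well")
        for _, g in self.table.groupby("well"):
            t = g["time_min"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.table["time_min"].unique())

    def trace_matrix(self) -> pd.DataFrame:
        """Wells × timepoints pivot of raw RLU."""
        return self.table.pivot_table(index="well", columns="time_min",
                                      values="rlu")

    def well_conditions(self) -> pd.Series:
        return self.table.groupby("well")[["condition", "conc_molar"]].first()

    @classmethod
    def from_csv(cls, path, **kw) -> "PlateData":
        return cls(pd.read_csv(path), **kw)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


@dataclass
class NormalizedResponse:
    """Normalized AUC (%) per concentration for one condition."""

    condition: str
    conc_molar: np.ndarray
    response_pct: np.ndarray
    n_replicates: np.ndarray
    canonical_conc: Optional[float] = None

    @property
    def log_conc(self) -> np.ndarray:
        return np.log10(self.conc_molar)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters; ``determined`` is False for flat/failed fits
    (reported as n.d.)."""

    pec50: float = math.nan
    emax: float = math.nan
    hill_slope: float = math.nan
    bottom: float = math.nan
    se: dict = field(default_factory=dict)
    n_points: int = 0
    determined: bool = False
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "pEC50": self.pec50, "Emax": self.emax,
            "hill_slope": self.hill_slope, "bottom": self.bottom,
            "se": self.se, "n_points": self.n_points,
            "determined": self.determined, "message": self.message,
        }


def four_param_logistic(logc, bottom, emax, logec50, hill):
    return bottom + (emax - bottom) / (1.0 + 10.0 ** ((logec50 - logc) * hill))


def baseline_correct(plate: PlateData, scalar_wildtype: bool = False) -> pd.DataFrame:
    """Drift-correct all traces against the plate controls.

    Every trace is divided pointwise by the mean wild-type control trace
    (or, with ``scalar_wildtype``, by its grand mean), then the
    corrected mean L-15 control trace is subtracted pointwise.  Returns
    a wells × timepoints matrix.
    """
    mat = plate.trace_matrix()
    conds = plate.well_conditions()["condition"]
    wt = mat.loc[conds[conds == WILD_TYPE].index].mean(axis=0)
    if (wt == 0).any():
        raise ValueError("wild-type control has zero intensity at a timepoint")
    if scalar_wildtype:
        divided = mat / float(wt.mean())
    else:
        divided = mat / wt
    l15 = divided.loc[conds[conds == L15].index].mean(axis=0)
    return divided - l15


def compute_auc(times, values, window: Optional[tuple] = None) -> float:
    """Trapezoidal AUC of a trace over ``window`` (default: whole trace)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if window is not None:
        lo, hi = window
        if lo < t.min() - 1e-9 or hi > t.max() + 1e-9:
            raise ValueError(f"window {window} outside trace [{t.min()}, {t.max()}]")
        m = (t >= lo) & (t <= hi)
        t, v = t[m], v[m]
    if len(t) < 2:
        raise ValueError("need at least 2 points in the AUC window")
    return float(np.trapezoid(v, t))


def normalize_auc(aucs, canonical_max_auc: float, l15_auc: float) -> np.ndarray:
    """Map AUCs onto the 0–100% scale set by L-15 and the canonical
    system's 100 µM response: 100·(AUC − AUC_L15)/(AUC_can − AUC_L15)."""
    denom = canonical_max_auc - l15_auc
    if denom == 0:
        raise ValueError("canonical and L-15 AUCs coincide; cannot normalize")
    return 100.0 * (np.asarray(aucs, dtype=float) - l15_auc) / denom


def fit_4pl(log_conc, response, nd_span_factor: float = 3.0) -> DoseResponseFit:
    """Variable-slope 4PL least-squares fit of response (%) vs log10 c.

    Initial guesses: bottom = min, Emax = max, logEC50 at the
    half-range crossing, Hill slope 1 (bounded to [0.2, 5]).  The fit is
    reported not-determined when the fitted span is under
    ``nd_span_factor`` × residual SD or the slope sticks at its bounds.
    """
    x = np.asarray(log_conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct concentrations")

    lo, hi = float(y.min()), float(y.max())
    span = hi - lo
    if span < 1e-9:
        return DoseResponseFit(n_points=len(x), determined=False,
                               message="flat response")
    half = lo + 0.5 * span
    above = x[y >= half]
    x0 = float(above.min()) if len(above) else float(np.median(x))
    p0 = [lo, hi, x0, 1.0]
    bounds = ([-np.inf, -np.inf, x.min() - 10.0, HILL_BOUNDS[0]],
              [np.inf, np.inf, x.max() + 10.0, HILL_BOUNDS[1]])
    try:
        popt, pcov = curve_fit(four_param_logistic, x, y, p0=p0,
                               bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, emax, logec50, hill = popt
    resid_sd = float(np.std(y - four_param_logistic(x, *popt)))
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    fitted_span = abs(emax - bottom)
    at_bounds = (
        abs(hill - HILL_BOUNDS[0]) < 1e-6 or abs(hill - HILL_BOUNDS[1]) < 1e-6
        or logec50 <= x.min() - 9.99 or logec50 >= x.max() + 9.99
    )
    determined = fitted_span >= nd_span_factor * resid_sd and not at_bounds
    return DoseResponseFit(
        pec50=-logec50, emax=float(emax), hill_slope=float(hill),
        bottom=float(bottom),
        se={"bottom": float(se[0]), "emax": float(se[1]),
            "pEC50": float(se[2]), "hill": float(se[3])},
        n_points=len(x), determined=bool(determined),
        message="" if determined else "not determined (flat span or bounded fit)",
    )


def analyze_plate(plate: PlateData, condition: str,
                  canonical_condition: Optional[str] = None,
                  canonical_conc: float = 1e-4,
                  scalar_wildtype: bool = False):
    """End-to-end plate analysis for one assay condition.

    Corrects traces, integrates the post-addition window, averages
    replicates per concentration, normalizes to the canonical system's
    ``canonical_conc`` response, and fits the 4PL curve.  Returns
    (NormalizedResponse, DoseResponseFit).
    """
    canonical_condition = canonical_condition or condition
    corrected = baseline_correct(plate, scalar_wildtype=scalar_wildtype)
    times = corrected.columns.to_numpy(dtype=float)
    window = (plate.baseline_min, plate.baseline_min + plate.post_min)
    aucs = corrected.apply(
        lambda row: compute_auc(times, row.to_numpy(), window), axis=1
    )
    meta = plate.well_conditions()
    df = meta.assign(auc=aucs)

    l15_auc = float(df.loc[df["condition"] == L15, "auc"].mean())
    can = df[(df["condition"] == canonical_condition)
             & np.isclose(df["conc_molar"].astype(float), canonical_conc)]
    if can.empty:
        raise ValueError(
            f"canonical condition {canonical_condition!r} at {canonical_conc} M "
            "not present on the plate"
        )
    canonical_auc = float(can["auc"].mean())

    sel = df[df["condition"] == condition].dropna(subset=["conc_molar"])
    grouped = sel.groupby("conc_molar")["auc"].agg(["mean", "count"])
    resp = normalize_auc(grouped["mean"].to_numpy(), canonical_auc, l15_auc)
    norm = NormalizedResponse(
        condition=condition,
        conc_molar=grouped.index.to_numpy(dtype=float),
        response_pct=resp,
        n_replicates=grouped["count"].to_numpy(),
        canonical_conc=canonical_conc,
    )
    fit = fit_4pl(norm.log_conc, norm.response_pct)
    return norm, fit
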