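"""Reporter-assay analysis: GFP-positive fractions and points of departure.

Per-cell reporter intensities from treated and vehicle wells are
log-transformed (log(intensity + 0.001)); a treated cell counts as
GFP-positive when its transformed intensity strictly exceeds
Q3 + 0.25·IQR of the matching vehicle-control cell population.
Concentration–response curves of the GFP-positive fraction are fitted
with a natural cubic spline (3 degrees of freedom) on log10
concentration by ordinary least squares; the point of departure (POD)
is the lowest concentration at which the fitted curve clears an
effective threshold of 0.1 plus the pointwise one-sided 90% confidence
half-width of the fitted mean — i.e. the response must exceed 0.1 by
more than the local uncertainty of the fit, which guards against
replicate noise near the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

__all__ = [
    "WellMeasurement",
    "PodResult",
    "gfp_positive_fraction",
    "pod_estimate",
    "viability_summaries",
    "read_cell_table",
    "wells_from_cell_table",
    "condition_response",
]

LOG_OFFSET = 0.001
GFP_THRESHOLD_FRACTION = 0.1


@dataclass
class WellMeasurement:
    """Per-cell reporter readout for one well (or pooled replicate wells)."""

    condition: str
    concentration: float  # µM; 0 for vehicle
    cell_intensities: np.ndarray
    is_vehicle: bool = False
    pi_positive: np.ndarray | None = None  # per-cell booleans, optional
    plate: int | str | None = None  # replicate plate; vehicles match by plate

    def __post_init__(self) -> None:
        self.cell_intensities = np.asarray(self.cell_intensities, dtype=float)
        if self.cell_intensities.size == 0:
            raise ValueError("well has no cells")
        if not self.is_vehicle and not self.concentration > 0:
            raise ValueError("treated wells need a positive concentration")
        if self.pi_positive is not None:
            self.pi_positive = np.asarray(self.pi_positive, dtype=bool)
            if self.pi_positive.size != self.cell_intensities.size:
                raise ValueError("pi_positive length must match cell count")

    @property
    def n_cells(self) -> int:
        return int(self.cell_intensities.size)


def _log_transform(intensities: np.ndarray) -> np.ndarray:
    return np.log(intensities + LOG_OFFSET)


def gfp_positive_fraction(treated: WellMeasurement, vehicle: WellMeasurement) -> float:
    """Fraction of treated cells above the vehicle-derived GFP threshold.

    Threshold T = Q3 + 0.25·IQR of the log-transformed vehicle population
    (linear-interpolation quantiles); cells count when strictly above T.
    A vehicle well with zero IQR degrades T to Q3.
    """
    v = _log_transform(vehicle.cell_intensities)
    t = _log_transform(treated.cell_intensities)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    threshold = q3 + 0.25 * iqr  # iqr == 0 leaves threshold at Q3
    return float(np.mean(t > threshold))


@dataclass(frozen=True)
class PodResult:
    """Point of departure in µM (``None`` when the response never clears the
    threshold); ``below_range`` flags a curve already above threshold at the
    lowest tested concentration."""

    pod: float | None
    threshold_used: float
    below_range: bool = False
    fit: dict | None = None


def _ns_basis(log_c: np.ndarray, knots_from: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis with 3 df, knots placed from the design."""
    design = patsy.dmatrix(
        "cr(x, df=3)", {"x": knots_from}, return_type="dataframe"
    )
    build = design.design_info
    return np.asarray(patsy.build_design_matrices([build], {"x": log_c})[0])


def pod_estimate(
    concentrations: Sequence[float],
    fractions: Sequence[float],
    threshold: float = GFP_THRESHOLD_FRACTION,
    n_grid: int = 400,
    confidence: float = 0.90,
) -> PodResult:
    """Spline concentration–response fit and threshold-crossing POD.

    ``concentrations`` (µM, > 0) and ``fractions`` are per-well points;
    replicates appear as repeated concentrations.  The fraction is
    modeled as a natural cubic spline (3 df) of log10 concentration; the
    POD is the lowest concentration on a dense log-spaced grid where the
    fitted mean exceeds ``threshold`` plus the one-sided ``confidence``
    upper half-width of the fitted mean, linearly interpolated between
    grid points.  Monotone consequence: raising ``threshold`` never
    lowers the POD.
    """
    conc = np.asarray(concentrations, dtype=float)
    frac = np.asarray(fractions, dtype=float)
    if conc.shape != frac.shape or conc.size == 0:
        raise ValueError("concentrations and fractions must align and be non-empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (µM)")
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct concentrations for a 3-df spline")

    log_c = np.log10(conc)
    X = sm.add_constant(_ns_basis(log_c, log_c)[:, 1:], has_constant="add")
    model = sm.OLS(frac, X).fit()

    grid = np.linspace(log_c.min(), log_c.max(), n_grid)
    Xg = sm.add_constant(_ns_basis(grid, log_c)[:, 1:], has_constant="add")
    pred = model.get_prediction(Xg)
    # two-sided (2*confidence - 1) CI == one-sided `confidence` upper bound
    frame = pred.summary_frame(alpha=2 * (1 - confidence))
    mean = frame["mean"].to_numpy()
    margin = frame["mean_ci_upper"].to_numpy() - mean
    margin = np.nan_to_num(margin, nan=0.0)

    effective = threshold + margin
    above = mean >= effective
    if not above.any():
        return PodResult(pod=None, threshold_used=threshold)
    first = int(np.argmax(above))
    if first == 0:
        return PodResult(
            pod=float(10 ** grid[0]), threshold_used=threshold, below_range=True
        )
    # linear interpolation of the crossing between the bracketing grid points
    g0, g1 = grid[first - 1], grid[first]
    d0 = mean[first - 1] - effective[first - 1]
    d1 = mean[first] - effective[first]
    log_pod = g0 + (g1 - g0) * (-d0) / (d1 - d0) if d1 != d0 else g1
    return PodResult(
        pod=float(10**log_pod),
        threshold_used=threshold,
        fit={"params": model.params.tolist(), "scale": float(model.scale)},
    )


def viability_summaries(
    treated: WellMeasurement, vehicle: WellMeasurement
) -> dict[str, float]:
    """PI-positive fraction among treated cells and the log10 ratio of
    treated to vehicle cell counts."""
    if treated.n_cells == 0:
        raise ValueError("no treated cells")
    if vehicle.n_cells == 0:
        raise ValueError("no vehicle cells")
    pi = treated.pi_positive
    pi_fraction = float(np.mean(pi)) if pi is not None else float("nan")
    return {
        "pi_positive_fraction": pi_fraction,
        "log10_cell_count_ratio": float(np.log10(treated.n_cells / vehicle.n_cells)),
    }


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Load a per-cell CSV: plate, well, condition, concentration_uM,
    cell_id, gfp_intensity, pi_positive."""
    df = pd.read_csv(path)
    need = {"condition", "concentration_uM", "gfp_intensity"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    return df


def wells_from_cell_table(df: pd.DataFrame) -> list[WellMeasurement]:
    """Group cells into WellMeasurements by (plate, condition, concentration).

    The condition named ``vehicle`` (case-insensitive) or concentration 0
    is flagged as vehicle; replicate plates stay separate so each treated
    well can be gated against its own plate's vehicle population.
    """
    keys = ["condition", "concentration_uM"]
    if "plate" in df.columns:
        keys = ["plate"] + keys
    wells = []
    for key, sub in df.groupby(keys):
        if "plate" in df.columns:
            plate, condition, conc = key
        else:
            (condition, conc), plate = key, None
        is_vehicle = str(condition).lower() == "vehicle" or conc == 0
        pi = sub["pi_positive"].to_numpy(bool) if "pi_positive" in sub.columns else None
        wells.append(
            WellMeasurement(
                condition=str(condition),
                concentration=float(conc),
                cell_intensities=sub["gfp_intensity"].to_numpy(float),
                is_vehicle=is_vehicle,
                pi_positive=pi,
                plate=plate,
            )
        )
    return wells


def condition_response(
    wells: Sequence[WellMeasurement], condition: str
) -> tuple[list[float], list[float]]:
    """Per-well concentrations and GFP-positive fractions for one condition,
    each treated well gated against the vehicle of its own plate (falling
    back to the pooled vehicle when plates are absent)."""
    vehicles = {w.plate: w for w in wells if w.is_vehicle}
    if not vehicles:
        raise ValueError("no vehicle wells supplied")
    concs: list[float] = []
    fracs: list[float] = []
    for w in wells:
        if w.is_vehicle or w.condition != condition:
            continue
        vehicle = vehicles.get(w.plate) or next(iter(vehicles.values()))
        concs.append(w.concentration)
        fracs.append(gfp_positive_fraction(w, vehicle))
    order = np.argsort(concs)
    return [concs[i] for i in order], [fracs[i] for i in order]
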