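"""Quantification of biochemical binding readouts.

Covers cross-titration grid normalization (proximity-assay heat maps),
competition IC50 fitting on a four-parameter logistic (under the assay
conditions the apparent IC50 equals the dissociation constant KD), generic
ratio normalizations for pull-down / secretion / proximity measurements with
loading-fraction correction, and thermal-unfolding midpoints from
A330/A350-vs-temperature melt curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Non-convergence or absent transition in a sigmoid fit."""


@dataclass
class DoseResponse:
    """A concentration (uM) or temperature (C) series with one response per point."""

    x: np.ndarray
    y: np.ndarray
    kind: str = "competition"  # or "melt"
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if not (np.all(np.diff(self.x) > 0) or np.all(np.diff(self.x) < 0)):
            raise ValueError("x must be strictly monotone")
        if not np.isfinite(self.y).all():
            raise ValueError("non-finite response values")


@dataclass
class TitrationGrid:
    """Cross-titration signal over a (row concentration x column concentration) grid."""

    row_concentrations: np.ndarray  # nM, sorted
    col_concentrations: np.ndarray  # nM, sorted
    signal: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.row_concentrations = np.asarray(self.row_concentrations, float)
        self.col_concentrations = np.asarray(self.col_concentrations, float)
        self.signal = np.asarray(self.signal, float)
        if np.any(self.row_concentrations <= 0) or np.any(self.col_concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if (np.any(np.diff(self.row_concentrations) < 0)
                or np.any(np.diff(self.col_concentrations) < 0)):
            raise ValueError("concentrations must be sorted ascending")
        if self.signal.shape != (len(self.row_concentrations),
                                 len(self.col_concentrations)):
            raise ValueError("signal matrix dimensions do not match concentrations")


@dataclass
class FitResult:
    midpoint: float          # IC50 (uM) or Tm (C)
    hill_slope: float
    top: float
    bottom: float
    midpoint_stderr: float
    converged: bool
    midpoint_in_range: bool
    apparent_kd: float | None = None  # equals IC50 for competition fits


# --------------------------------------------------------------------------
# model functions
# --------------------------------------------------------------------------

def logistic_competition(x, top, bottom, ic50, hill):
    """4PL on log-concentration: top plateau at low competitor, bottom at high."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def logistic_melt(t, top, bottom, tm, width):
    """Two-state unfolding sigmoid in temperature; midpoint at ``tm``."""
    t = np.asarray(t, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.exp((t - tm) / width))


# --------------------------------------------------------------------------
# grid normalization
# --------------------------------------------------------------------------

def normalize_titration_grid(grids: list[TitrationGrid],
                             reference_cell: tuple[float, float]
                             ) -> pd.DataFrame:
    """Average replicate grids on a percent scale.

    Each replicate is first scaled so the signal of the reference
    concentration pair defines the normalization unit; replicates are then
    averaged elementwise and the result rescaled so the minimum maps to 0%
    and the maximum to 100% (heat-map convention).
    """
    if not grids:
        raise ValueError("no replicate grids supplied")
    rref, cref = reference_cell
    scaled = []
    for g in grids:
        ri = np.flatnonzero(np.isclose(g.row_concentrations, rref))
        ci = np.flatnonzero(np.isclose(g.col_concentrations, cref))
        if len(ri) == 0 or len(ci) == 0:
            raise ValueError(
                f"reference cell {reference_cell} missing from replicate "
                f"{g.replicate_id!r}")
        ref = g.signal[ri[0], ci[0]]
        if ref == 0:
            raise ValueError("zero reference signal")
        scaled.append(g.signal / ref)
    mean = np.mean(scaled, axis=0)
    lo, hi = mean.min(), mean.max()
    if hi == lo:
        raise ValueError("degenerate grid: min equals max after averaging")
    pct = 100.0 * (mean - lo) / (hi - lo)
    g0 = grids[0]
    return pd.DataFrame(pct, index=g0.row_concentrations,
                        columns=g0.col_concentrations)


# --------------------------------------------------------------------------
# competition IC50
# --------------------------------------------------------------------------

def fit_competition_ic50(dr: DoseResponse) -> FitResult:
    """Fit a free-slope 4PL to a competition series; IC50 is the apparent KD.

    Initialization comes from the data quartiles on the log-concentration
    axis. Data that rise with competitor concentration carry no inhibition
    transition and are rejected.
    """
    if len(dr.x) < 5:
        raise ValueError("need at least 5 points")
    if np.any(dr.x <= 0):
        raise ValueError("competition concentrations must be positive")
    x, y = dr.x, dr.y
    order = np.argsort(x)
    x, y = x[order], y[order]
    # direction check: signal must fall with competitor
    lo_mean = y[: max(2, len(y) // 4)].mean()
    hi_mean = y[-max(2, len(y) // 4):].mean()
    span = y.max() - y.min()
    if span == 0 or lo_mean <= hi_mean:
        raise FitError("no inhibition transition in competition data")
    p0 = [y.max(), y.min(), float(np.exp(np.mean(np.log(x)))), 1.0]
    try:
        popt, pcov = curve_fit(
            logistic_competition, x, y, p0=p0,
            bounds=([-np.inf, -np.inf, x.min() / 1e3, 0.05],
                    [np.inf, np.inf, x.max() * 1e3, 20.0]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"IC50 fit did not converge: {exc}") from exc
    top, bottom, ic50, hill = popt
    se = float(np.sqrt(np.abs(pcov[2, 2]))) if np.isfinite(pcov[2, 2]) else np.nan
    return FitResult(midpoint=float(ic50), hill_slope=float(hill),
                     top=float(top), bottom=float(bottom),
                     midpoint_stderr=se, converged=True,
                     midpoint_in_range=bool(x.min() <= ic50 <= x.max()),
                     apparent_kd=float(ic50))


# --------------------------------------------------------------------------
# ratio normalization (pull-down, secretion, proximity)
# --------------------------------------------------------------------------

def normalize_measure(values: dict[str, dict[str, float]],
                      reference: str,
                      background: dict[str, float] | None = None,
                      loading_fractions: dict[str, float] | None = None,
                      mode: str = "bound_over_total",
                      scale: float = 100.0) -> dict[str, float]:
    """Normalize per-condition channel intensities to a reference condition.

    ``values`` maps condition -> channel intensities (e.g. ``{"bound": 10,
    "unbound": 3}``). Optional per-channel background is subtracted first;
    intensities are divided by their loading fraction (the portion of each
    fraction loaded on the gel, e.g. bound 0.33, unbound 0.025) before
    ratios. The default ratio is bound/total with total = corrected bound +
    corrected unbound; ``mode="bound_over_unbound"`` is the alternative.
    The reference condition is scaled to ``scale`` (100 by default).
    """
    def ratio(channels: dict[str, float]) -> float:
        corr = {}
        for ch, v in channels.items():
            if background:
                v = v - background.get(ch, 0.0)
                if v < 0:
                    raise ValueError(
                        f"negative intensity after background subtraction ({ch})")
            if loading_fractions:
                f = loading_fractions.get(ch, 1.0)
                if not 0 < f <= 1:
                    raise ValueError(f"loading fraction {f} outside (0, 1]")
                v = v / f
            corr[ch] = v
        if mode == "bound_over_total":
            total = corr["bound"] + corr.get("unbound", 0.0)
            if total == 0:
                raise ValueError("zero total signal")
            return corr["bound"] / total
        if mode == "bound_over_unbound":
            if corr.get("unbound", 0.0) == 0:
                raise ValueError("zero unbound signal")
            return corr["bound"] / corr["unbound"]
        raise ValueError(f"unknown mode {mode!r}")

    if reference not in values:
        raise KeyError(f"reference condition {reference!r} missing")
    ratios = {cond: ratio(ch) for cond, ch in values.items()}
    if ratios[reference] == 0:
        raise ValueError("zero reference ratio")
    return {cond: scale * r / ratios[reference] for cond, r in ratios.items()}


def corrected_ratio(bound: float, unbound: float,
                    bound_fraction: float = 0.33,
                    unbound_fraction: float = 0.025) -> float:
    """Bound/total ratio after loading-fraction correction (single condition)."""
    b = bound / bound_fraction
    u = unbound / unbound_fraction
    return b / (b + u)


# --------------------------------------------------------------------------
# thermal melt
# --------------------------------------------------------------------------

def melting_midpoint(dr: DoseResponse) -> FitResult:
    """Unfolding midpoint Tm from an A330/A350-vs-temperature curve.

    Fits a two-state sigmoid; when the fit fails, falls back to the extremum
    of the smoothed first derivative. A fit is rejected as transition-free
    when the midpoint lands outside the measured range or the fitted
    amplitude exceeds three times the observed data range (the degenerate
    shallow-slope fit a straight line produces).
    """
    if len(dr.x) < 10:
        raise ValueError("need at least 10 temperature points")
    t, y = dr.x, dr.y
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    span = y.max() - y.min()
    if span == 0:
        raise FitError("flat melt curve: no transition")
    width0 = (t.max() - t.min()) / 20.0
    p0 = [y[0], y[-1], float(t[np.argmax(np.abs(np.gradient(y, t)))]), width0]
    try:
        popt, pcov = curve_fit(logistic_melt, t, y, p0=p0, maxfev=20000)
        top, bottom, tm, width = popt
        converged = True
    except (RuntimeError, ValueError):
        converged = False
        tm, top, bottom, width = np.nan, np.nan, np.nan, np.nan
        pcov = np.full((4, 4), np.nan)
    if not converged:
        # derivative-extremum fallback
        dy = np.gradient(y, t)
        k = int(np.argmax(np.abs(dy)))
        if np.abs(dy[k]) < 3.0 * np.median(np.abs(dy)) or k in (0, len(t) - 1):
            raise FitError("no unfolding transition detected")
        return FitResult(midpoint=float(t[k]), hill_slope=np.nan,
                         top=float(y[0]), bottom=float(y[-1]),
                         midpoint_stderr=np.nan, converged=False,
                         midpoint_in_range=True)
    in_range = bool(t.min() <= tm <= t.max())
    if not in_range or abs(top - bottom) > 3.0 * span:
        raise FitError("no unfolding transition detected")
    se = float(np.sqrt(np.abs(pcov[2, 2]))) if np.isfinite(pcov[2, 2]) else np.nan
    return FitResult(midpoint=float(tm), hill_slope=float(1.0 / width),
                     top=float(top), bottom=float(bottom),
                     midpoint_stderr=se, converged=True,
                     midpoint_in_range=True)


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def write_dose_response(dr: DoseResponse, path) -> str:
    """CSV with a header comment recording kind and units."""
    unit = "uM" if dr.kind == "competition" else "C"
    with open(path, "w") as fh:
        fh.write(f"# kind={dr.kind} x_unit={unit} replicate={dr.replicate_id}\n")
        pd.DataFrame({"x": dr.x, "y": dr.y}).to_csv(fh, index=False)
    return str(path)


def read_dose_response(path) -> DoseResponse:
    with open(path) as fh:
        header = fh.readline()
        kind = "competition"
        for tok in header.lstrip("#").split():
            if tok.startswith("kind="):
                kind = tok.split("=", 1)[1]
        df = pd.read_csv(fh)
    return DoseResponse(x=df["x"].to_numpy(), y=df["y"].to_numpy(), kind=kind)
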