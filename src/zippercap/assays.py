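"""Quantitative assay models.

Four independent computations used to characterize capping inhibitors:

* steady-state SPR affinity — least-squares fit of the 1:1 binding model
  ``Req = C·Rmax/(KD + C) + RI`` to plateau responses vs analyte
  concentration, giving the equilibrium dissociation constant KD (µM),
  the surface binding capacity Rmax and the bulk refractive-index offset RI;
* ThT endpoint fold-reduction — ratio of baseline-subtracted plateau
  fluorescence of an untreated control over an inhibitor-treated sample;
* puncta-per-well normalization — aggregate counts from a seeding reporter
  cell line divided by well confluence, summarized per condition;
* dilution-chain arithmetic for transfection protocols.

Responses are expected blank-subtracted; sensorgram kinetics (kon/koff) are
out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingIsotherm:
    """Blank-subtracted steady-state responses vs analyte concentration."""

    concentrations: tuple[float, ...]  # µM, strictly positive, ascending
    responses: tuple[float, ...]  # response units
    analyte_label: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations, float)
        r = np.asarray(self.responses, float)
        if c.size != r.size or c.size < 5:
            raise ValidationError(
                "isotherm needs >= 5 matched concentration/response pairs"
            )
        if np.any(c <= 0):
            raise ValidationError("concentrations must be strictly positive")
        if np.any(np.diff(c) < 0):
            raise ValidationError("concentrations must be sorted ascending")


@dataclass(frozen=True)
class FitResult:
    """Fitted 1:1 steady-state parameters."""

    kd: float  # µM
    rmax: float  # response units
    ri: float  # response units
    se_kd: float  # µM, curvature-based standard error
    converged: bool
    residuals: tuple[float, ...] = ()

    def as_dict(self) -> dict:
        return {
            "kd_uM": self.kd,
            "rmax_RU": self.rmax,
            "ri_RU": self.ri,
            "se_kd_uM": self.se_kd,
            "converged": self.converged,
            "residuals": list(self.residuals),
        }


@dataclass(frozen=True)
class ThTTrace:
    """One ThT fluorescence time course."""

    times: tuple[float, ...]  # h, strictly increasing
    fluorescence: tuple[float, ...]  # AU
    condition_label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, float)
        f = np.asarray(self.fluorescence, float)
        if t.size != f.size or t.size < 2:
            raise ValidationError("trace needs >= 2 matched time/AU pairs")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass(frozen=True)
class PunctaRecord:
    """Raw puncta count and confluence of one well."""

    raw_puncta: float
    confluence: float  # fraction in (0, 1]
    well_id: str
    condition: str

    def __post_init__(self):
        if self.raw_puncta < 0:
            raise ValidationError("raw_puncta must be >= 0")


# ---------------------------------------------------------------------------
# Steady-state SPR fit
# ---------------------------------------------------------------------------

def steady_state_response(c, kd, rmax, ri):
    """1:1 binding model: Req = C·Rmax/(KD + C) + RI."""
    c = np.asarray(c, float)
    return c * rmax / (kd + c) + ri


_KD_BOUNDS = (1e-6, 1e7)  # µM
_RMAX_BOUNDS = (1e-9, 1e9)


def fit_steady_state_kd(iso: BindingIsotherm) -> FitResult:
    """Fit the 1:1 steady-state model to an isotherm.

    Multi-start least squares with KD initialized at the minimum, median and
    maximum analyte concentration; the best sum-of-squares solution wins.
    ``se_kd`` is the standard error from the curvature (covariance) at the
    optimum. ``converged`` is False when the responses are monotone
    decreasing (non-binding) or when the optimum sits on a parameter bound.
    """
    c = np.asarray(iso.concentrations, float)
    r = np.asarray(iso.responses, float)
    if np.allclose(r, r[0]):
        raise ValidationError("responses are all equal; nothing to fit")

    diffs = np.diff(r)
    non_binding = np.all(diffs <= 0) and r[-1] < r[0]
    if non_binding:
        warnings.warn(
            f"isotherm {iso.analyte_label!r}: responses decrease with "
            "concentration; no binding signal",
            stacklevel=2,
        )

    rmax0 = max(float(r.max() - r.min()), 1e-6)
    ri0 = float(r.min())
    best = None
    for kd0 in (float(c.min()), float(np.median(c)), float(c.max())):
        try:
            popt, pcov = curve_fit(
                steady_state_response,
                c,
                r,
                p0=[kd0, rmax0, ri0],
                bounds=(
                    [_KD_BOUNDS[0], _RMAX_BOUNDS[0], -np.inf],
                    [_KD_BOUNDS[1], _RMAX_BOUNDS[1], np.inf],
                ),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((steady_state_response(c, *popt) - r) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)

    if best is None:
        return FitResult(
            kd=math.nan, rmax=math.nan, ri=math.nan, se_kd=math.nan,
            converged=False,
        )

    _, popt, pcov = best
    kd, rmax, ri = (float(v) for v in popt)
    se_kd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.nan
    on_bound = (
        kd <= _KD_BOUNDS[0] * 1.01
        or kd >= _KD_BOUNDS[1] * 0.99
        or rmax <= _RMAX_BOUNDS[0] * 1.01
    )
    residuals = tuple(
        float(v) for v in (r - steady_state_response(c, kd, rmax, ri))
    )
    return FitResult(
        kd=kd,
        rmax=rmax,
        ri=ri,
        se_kd=se_kd,
        converged=not (non_binding or on_bound),
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# ThT endpoint fold-reduction
# ---------------------------------------------------------------------------

def fold_reduction(
    control: ThTTrace, treated: ThTTrace, window: float = 0.2
) -> float:
    """Control/treated ratio of baseline-subtracted plateau fluorescence.

    The plateau is the mean over the final ``window`` fraction of timepoints
    (default: last 20%); the t=0 value of each trace is subtracted first.
    Returns ``inf`` when the treated plateau is non-positive after baseline
    subtraction (complete inhibition).
    """
    if not (0 < window <= 1):
        raise ValidationError("window must be in (0, 1]")
    tc = np.asarray(control.times, float)
    tt = np.asarray(treated.times, float)
    if tc.min() > tt.max() or tt.min() > tc.max():
        raise ValidationError("traces have non-overlapping time ranges")

    def plateau(trace: ThTTrace) -> float:
        f = np.asarray(trace.fluorescence, float) - trace.fluorescence[0]
        n = max(1, int(math.ceil(window * f.size)))
        return float(f[-n:].mean())

    pc, pt = plateau(control), plateau(treated)
    if pt <= 0:
        return math.inf
    return pc / pt


def summarize_tht(
    control: ThTTrace, treated: ThTTrace, window: float = 0.2
) -> dict:
    """Fold-reduction plus the raw plateau values, as a report row."""
    fold = fold_reduction(control, treated, window)
    return {
        "control": control.condition_label,
        "treated": treated.condition_label,
        "fold_reduction": fold,
        "window_fraction": window,
    }


# ---------------------------------------------------------------------------
# Puncta normalization
# ---------------------------------------------------------------------------

def normalize_puncta(records: list[PunctaRecord]) -> pd.DataFrame:
    """Confluence-normalized puncta per well, summarized per condition.

    normalized = raw_puncta / confluence; per-condition mean and sample SD
    over replicate wells. Wells with non-positive confluence are rejected
    with a warning.
    """
    if not records:
        raise ValidationError("no puncta records")
    rows = []
    for rec in records:
        if rec.confluence <= 0:
            warnings.warn(
                f"well {rec.well_id}: non-positive confluence, rejected",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "condition": rec.condition,
                "well_id": rec.well_id,
                "normalized_puncta": rec.raw_puncta / rec.confluence,
            }
        )
    if not rows:
        raise ValidationError("all puncta records rejected")
    per_well = pd.DataFrame(rows)
    summary = (
        per_well.groupby("condition", sort=True)["normalized_puncta"]
        .agg(
            mean="mean",
            sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    return summary


# ---------------------------------------------------------------------------
# Dilution chain
# ---------------------------------------------------------------------------

def dilution_chain(start: float, steps: list[tuple]) -> float:
    """Apply a sequence of dilution steps to a starting concentration.

    Steps are either ``("ratio", f)`` — a 1:f dilution (a 1:1 mix of two
    equal volumes is ``("ratio", 2)``) — or ``("volume", v, V)`` — transfer
    of v volume units into a final volume V. Units of the result match the
    input (µM in, µM out).
    """
    if start <= 0:
        raise ValidationError("starting concentration must be positive")
    conc = float(start)
    for step in steps:
        kind = step[0]
        if kind == "ratio":
            factor = float(step[1])
            if factor <= 0:
                raise ValidationError(f"dilution factor must be > 0: {step}")
            conc /= factor
        elif kind == "volume":
            v, total = float(step[1]), float(step[2])
            if v <= 0 or total <= 0:
                raise ValidationError(f"volumes must be > 0: {step}")
            conc *= v / total
        else:
            raise ValidationError(f"unknown dilution step kind {kind!r}")
    return conc


# ---------------------------------------------------------------------------
# Dose-response ordering
# ---------------------------------------------------------------------------

def dose_response_table(conditions: list[tuple[float, float]]) -> dict:
    """Order (molar ratio, effect) pairs by dose and flag monotonicity.

    Effects are expected non-increasing with dose (more inhibitor, less
    aggregation/seeding). Returns the sorted table, a monotone flag, the
    first offending dose pair if any, and whether the response is flat.
    """
    if len(conditions) < 2:
        raise ValidationError("need at least 2 dose levels")
    table = pd.DataFrame(conditions, columns=["molar_ratio", "effect"])
    table = table.sort_values("molar_ratio", kind="stable").reset_index(
        drop=True
    )
    effects = table["effect"].to_numpy()
    offending = None
    for i in range(len(effects) - 1):
        if effects[i + 1] > effects[i]:
            offending = (
                float(table["molar_ratio"][i]),
                float(table["molar_ratio"][i + 1]),
            )
            break
    return {
        "table": table,
        "monotone_non_increasing": offending is None,
        "offending_pair": offending,
        "flat": bool(np.allclose(effects, effects[0])),
    }


# ---------------------------------------------------------------------------
# CSV adapters (documented headers)
# ---------------------------------------------------------------------------

ISOTHERM_COLUMNS = ("concentration_uM", "response_RU")
THT_COLUMNS = ("time_h", "fluor_AU")
PUNCTA_COLUMNS = ("well", "condition", "raw_puncta", "confluence")


def read_isotherm_csv(path, analyte_label: str = "") -> BindingIsotherm:
    df = pd.read_csv(path)
    missing = [c for c in ISOTHERM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    df = df.sort_values("concentration_uM")
    return BindingIsotherm(
        concentrations=tuple(df["concentration_uM"].astype(float)),
        responses=tuple(df["response_RU"].astype(float)),
        analyte_label=analyte_label or str(path),
    )


def read_tht_csv(path, condition_label: str = "") -> ThTTrace:
    df = pd.read_csv(path)
    missing = [c for c in THT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return ThTTrace(
        times=tuple(df["time_h"].astype(float)),
        fluorescence=tuple(df["fluor_AU"].astype(float)),
        condition_label=condition_label or str(path),
    )


def read_puncta_csv(path) -> list[PunctaRecord]:
    df = pd.read_csv(path)
    missing = [c for c in PUNCTA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return [
        PunctaRecord(
            raw_puncta=float(row.raw_puncta),
            confluence=float(row.confluence),
            well_id=str(row.well),
            condition=str(row.condition),
        )
        for row in df.itertuples()
    ]
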