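"""Dose-response fitting and mechanism triage.

Each titrated construct is classified as ``saturable`` (consistent with a
dual-receptor bridging mechanism: the response plateaus within the tested
range), ``non_saturating`` (still rising at the top dose, consistent with
receptor clustering), or ``no_signal``. The rule is deterministic and
unit-free:

1. ``no_signal`` if the response amplitude is below a noise floor;
2. otherwise fit a bounded four-parameter Hill curve and a two-parameter
   linear-in-log-dose model; the construct is ``saturable`` iff the Hill fit
   wins by AIC *and* the fitted curve is flat (relative slope below
   ``plateau_eps`` per log10 dose unit) across the top two doses;
3. anything else is ``non_saturating``.

Doses beyond a pronounced response peak (a high-dose hook) are excluded from
the plateau test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class DoseSeries:
    """One construct's titration on one pathway in one cell context."""

    construct_id: str
    doses: list[float]
    responses: list[float]
    pathway: str | None = None
    cell_type: str | None = None

    def __post_init__(self):
        if len(self.doses) != len(self.responses):
            raise ValueError("doses and responses must have equal length")
        if len(self.doses) < 4:
            raise ValueError("a dose series needs at least 4 doses")
        d = np.asarray(self.doses, dtype=float)
        if np.any(d < 0):
            raise ValueError("doses must be >= 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")


@dataclass(frozen=True)
class HillFit:
    e0: float
    emax: float
    ec50_nM: float
    hill: float
    sse: float
    success: bool = True

    def predict(self, dose) -> np.ndarray:
        return _hill(np.asarray(dose, dtype=float), self.e0, self.emax, self.ec50_nM, self.hill)

    def as_dict(self) -> dict:
        return {
            "e0": self.e0,
            "emax": self.emax,
            "ec50_nM": self.ec50_nM,
            "hill": self.hill,
            "sse": self.sse,
            "success": self.success,
        }


@dataclass(frozen=True)
class MechanismCall:
    label: str  # saturable | non_saturating | no_signal
    fit: dict = field(default_factory=dict)
    evidence: float = 0.0  # AIC(linear) - AIC(hill); positive favors the Hill model

    def __post_init__(self):
        if self.label not in {"saturable", "non_saturating", "no_signal"}:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "saturable" and not self.fit.get("ec50_nM", 1.0) > 0:
            raise ValueError("saturable calls require ec50 > 0")


def titration_grid(
    kd_max_nM: float, top_fold: float = 10.0, n_doses: int = 10, step: float = 3.0
) -> list[float]:
    """Standard titration design: zero plus a ``step``-fold dilution series.

    The top dose is ``top_fold`` times the weakest binder affinity, so a
    saturable mechanism plateaus within the tested range while the high-dose
    hook regime stays mild; ``n_doses`` includes the zero dose.
    """
    if kd_max_nM <= 0 or top_fold <= 0 or step <= 1 or n_doses < 4:
        raise ValueError("need kd > 0, top_fold > 0, step > 1, n_doses >= 4")
    top = top_fold * kd_max_nM
    return [0.0] + [top / step**i for i in reversed(range(n_doses - 1))]


def _hill(d, e0, emax, ec50, h):
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d**h / (ec50**h + d**h), 0.0)
    return e0 + (emax - e0) * frac


def fit_hill(series: DoseSeries) -> HillFit:
    """Bounded least-squares four-parameter logistic fit.

    Hill slope is constrained to [0.5, 4] and EC50 to the tested dose range
    scaled by 100-fold either way. Five fixed EC50 starting points are tried;
    the lowest-residual fit wins. If no start converges the fit is returned
    with ``success=False`` and plateau parameters from the data envelope.
    """
    d = np.asarray(series.doses, dtype=float)
    y = np.asarray(series.responses, dtype=float)
    pos = d[d > 0]
    span = max(y.max() - y.min(), 1e-12 * max(abs(y.max()), 1.0))
    lo_ec, hi_ec = pos.min() * 1e-2, pos.max() * 1e2
    bounds = (
        [y.min() - span, y.min() - span, lo_ec, 0.5],
        [y.max() + span, y.max() + span, hi_ec, 4.0],
    )
    starts = np.geomspace(max(pos.min(), lo_ec), min(pos.max(), hi_ec), 5)
    best = None
    for ec0 in starts:
        p0 = [y[0], y[-1], ec0, 1.0]
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_hill, d, y, p0=p0, bounds=bounds, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _hill(d, *popt)) ** 2))
        if best is None or sse < best.sse:
            best = HillFit(*[float(v) for v in popt], sse=sse)
    if best is None:
        return HillFit(
            e0=float(y[0]), emax=float(y[-1]), ec50_nM=float(np.median(pos)),
            hill=1.0, sse=float(np.sum((y - y.mean()) ** 2)), success=False,
        )
    return best


def _aic(sse: float, n: int, k: int) -> float:
    return n * np.log(max(sse, 1e-300) / n) + 2 * k


def _fit_loglinear(d: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    x = np.column_stack([np.ones_like(d), np.log1p(d)])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    sse = float(np.sum((y - x @ coef) ** 2))
    return coef, sse


def estimate_noise_floor(series: DoseSeries, n_sd: float = 3.0) -> float:
    """Heuristic floor: ``n_sd`` times the residual sd around the Hill fit."""
    d = np.asarray(series.doses, dtype=float)
    y = np.asarray(series.responses, dtype=float)
    fit = fit_hill(series)
    resid = y - fit.predict(d)
    dof = max(len(y) - 4, 1)
    return float(n_sd * np.sqrt(np.sum(resid**2) / dof))


def _trim_hook(d: np.ndarray, y: np.ndarray, noise_floor: float, decline_frac: float):
    """Drop doses past the response peak when the hook is pronounced.

    Trimming requires a genuine rise to the peak (above the noise floor), a
    post-peak decline exceeding ``decline_frac`` of that rise, and at least
    four remaining points; milder declines are left in place and treated as
    plateau scatter, so pure-noise and monotone series are never trimmed.
    """
    peak = int(np.argmax(y))
    rise = y[peak] - y[0]
    decline = y[peak] - y[-1]
    if 3 <= peak <= len(y) - 2 and rise > noise_floor and decline > decline_frac * rise:
        return d[: peak + 1], y[: peak + 1], True
    return d, y, False


def classify(
    series: DoseSeries,
    noise_floor: float,
    plateau_eps: float = 0.10,
    hook_decline_frac: float = 0.50,
) -> MechanismCall:
    """Triage one dose series into saturable / non_saturating / no_signal.

    ``noise_floor`` is an absolute response amplitude (same units as the
    responses) below which the series is called ``no_signal``; both the data
    envelope (max − fitted e0) and the fitted dynamic range must clear it, so
    a single outlying well does not masquerade as signal. The decision is
    invariant to affine rescaling of the responses provided the floor is
    rescaled with them.
    """
    d0 = np.asarray(series.doses, dtype=float)
    y0 = np.asarray(series.responses, dtype=float)
    d, y, trimmed = _trim_hook(d0, y0, noise_floor, hook_decline_frac)
    fit_series = (
        DoseSeries(series.construct_id, d.tolist(), y.tolist(), series.pathway, series.cell_type)
        if trimmed
        else series
    )
    hill = fit_hill(fit_series)
    amplitude = float(y.max() - hill.e0)
    fitted_range = float(abs(hill.emax - hill.e0))
    if amplitude < noise_floor or fitted_range < noise_floor:
        return MechanismCall(label="no_signal", fit=hill.as_dict(), evidence=0.0)

    _, sse_lin = _fit_loglinear(d, y)
    evidence = _aic(sse_lin, len(y), 2) - _aic(hill.sse, len(y), 4)

    d_top = d[d > 0][-2:]
    y_hat = hill.predict(d_top)
    denom = max(abs(amplitude), 1e-12) * np.log10(d_top[-1] / d_top[-2])
    rel_slope = float((y_hat[-1] - y_hat[-2]) / denom)

    if hill.success and evidence >= 0 and abs(rel_slope) < plateau_eps:
        return MechanismCall(label="saturable", fit=hill.as_dict(), evidence=float(evidence))
    return MechanismCall(label="non_saturating", fit=hill.as_dict(), evidence=float(evidence))
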