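"""Phenotype readouts: growth efficiency, logistic fits, normalized viability.

Growth efficiency is the endpoint biomass readout, od_final - od_initial
over a fixed incubation. Cold timecourses are summarized by a bounded
three-parameter logistic fit od(t) = K / (1 + exp(-R (t - x0))): K the
carrying capacity (OD), R the logistic rate (per day), x0 the sigmoidal
midpoint (days). Viability is CFU/mL from the densest countable spot of a
1:10 dilution series, normalized by end-point turbidity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    LAWN,
    GrowthMeasurement,
    InsufficientDataError,
    PanelError,
    Timecourse,
    ViabilityMeasurement,
)

__all__ = [
    "efficiency",
    "with_efficiency",
    "LogisticFit",
    "logistic",
    "fit_logistic",
    "average_fit",
    "growth_rate",
    "ViabilityEstimate",
    "quantify_viability",
    "DEFAULT_BOUNDS",
]

#: Parameter box applied to (K, R, x0); each bounded to [-1, 10].
DEFAULT_BOUNDS = (-1.0, 10.0)


def efficiency(m: GrowthMeasurement) -> float:
    """Biomass accumulated over the incubation: od_final - od_initial."""
    return m.od_final - m.od_initial


def with_efficiency(table: pd.DataFrame) -> pd.DataFrame:
    """Growth table with an ``efficiency`` column appended."""
    out = table.copy()
    out["efficiency"] = out["od_final"] - out["od_initial"]
    return out


def logistic(t, K, R, x0):
    return K / (1.0 + np.exp(-R * (np.asarray(t, dtype=float) - x0)))


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters for one replicate timecourse."""

    K: float
    R: float
    x0: float
    converged: bool
    residual_norm: float
    boundary_active: bool = False
    n_averaged: int = 1  # >1 when produced by average_fit
    n_excluded: int = 0  # non-converged fits dropped by average_fit

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.K, self.R, self.x0)


def fit_logistic(
    tc: Timecourse | tuple[Sequence[float], Sequence[float]],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    init: tuple[float, float, float] | None = None,
) -> LogisticFit:
    """Bounded nonlinear least-squares logistic fit of one timecourse.

    Uses the Trust Region Reflective solver with each parameter boxed to
    ``bounds`` (default [-1, 10]). Starting values, unless given: K at the
    maximum observed OD, R at 1/day, x0 at the median timepoint. Fits that
    end at a box face are flagged ``boundary_active``. Non-convergence is
    reported through ``converged=False``, not an exception; fewer than four
    timepoints is an error.
    """
    if isinstance(tc, Timecourse):
        t, y = np.asarray(tc.times, float), np.asarray(tc.ods, float)
    else:
        t, y = (np.asarray(v, dtype=float) for v in tc)
    if t.size < 4:
        raise InsufficientDataError(
            f"logistic fit needs >= 4 timepoints, got {t.size}"
        )
    lo, hi = bounds
    if init is None:
        init = (float(np.max(y)), 1.0, float(np.median(t)))
    p0 = np.clip(init, lo + 1e-9, hi - 1e-9)

    def resid(p):
        return logistic(t, *p) - y

    try:
        res = least_squares(
            resid,
            p0,
            bounds=([lo] * 3, [hi] * 3),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        ok = bool(res.status > 0)
        K, R, x0 = (float(v) for v in res.x)
        rnorm = float(np.linalg.norm(res.fun))
    except Exception:
        ok, (K, R, x0), rnorm = False, (np.nan,) * 3, np.nan
    at_bound = ok and bool(
        np.any(np.abs(np.array([K, R, x0]) - lo) < 1e-8)
        or np.any(np.abs(np.array([K, R, x0]) - hi) < 1e-8)
    )
    return LogisticFit(K, R, x0, converged=ok, residual_norm=rnorm,
                       boundary_active=at_bound)


def average_fit(fits: Sequence[LogisticFit]) -> LogisticFit:
    """Replicate-averaged logistic parameters (arithmetic mean over converged fits)."""
    usable = [f for f in fits if f.converged]
    excluded = len(list(fits)) - len(usable)
    if not usable:
        raise InsufficientDataError("no converged fits to average")
    K = float(np.mean([f.K for f in usable]))
    R = float(np.mean([f.R for f in usable]))
    x0 = float(np.mean([f.x0 for f in usable]))
    rnorm = float(np.mean([f.residual_norm for f in usable]))
    return LogisticFit(
        K, R, x0,
        converged=True,
        residual_norm=rnorm,
        boundary_active=any(f.boundary_active for f in usable),
        n_averaged=len(usable),
        n_excluded=excluded,
    )


def growth_rate(
    timecourses: Sequence[Timecourse],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> np.ndarray:
    """Per-replicate fitted logistic rates R for one strain's timecourses.

    Non-converged replicates are excluded; if every replicate is excluded
    (or the input is empty) an error is raised.
    """
    if not timecourses:
        raise InsufficientDataError("no timecourses supplied")
    rates = [
        f.R for f in (fit_logistic(tc, bounds=bounds) for tc in timecourses)
        if f.converged
    ]
    if not rates:
        raise InsufficientDataError("all replicate fits failed to converge")
    return np.asarray(rates, dtype=float)


@dataclass(frozen=True)
class ViabilityEstimate:
    """CFU/mL (and per-OD) from the densest countable spot."""

    strain_id: str
    replicate_id: str
    cfu_per_ml: float | None
    cfu_per_ml_per_od: float | None
    selected_dilution: float | None
    censored_above: bool = False  # every dilution was a lawn
    below_detection: bool = False  # zero colonies at every countable dilution


def quantify_viability(
    v: ViabilityMeasurement, lawn_threshold: int = 100
) -> ViabilityEstimate:
    """Estimate viable density from a spotting dilution series.

    The selected dilution is the densest (largest factor) at which *every*
    technical spot is countable (below ``lawn_threshold`` and not marked
    LAWN). Technical replicate counts are averaged; CFU/mL = mean count /
    spot volume / dilution factor, then normalized by end-point OD.
    """
    selected = None
    for d, counts in zip(v.dilution_factors, v.spot_counts):
        if all(c != LAWN and int(c) < lawn_threshold for c in counts):
            selected = (d, counts)
            break
    if selected is None:
        return ViabilityEstimate(
            v.strain_id, v.replicate_id, None, None, None, censored_above=True
        )
    d, counts = selected
    mean_count = float(np.mean([int(c) for c in counts]))
    if mean_count == 0:
        return ViabilityEstimate(
            v.strain_id, v.replicate_id, 0.0, 0.0, d, below_detection=True
        )
    cfu = mean_count / v.spot_volume / d
    return ViabilityEstimate(
        v.strain_id, v.replicate_id, cfu, cfu / v.od_end, d
    )


def viability_table(
    measurements: Sequence[ViabilityMeasurement], lawn_threshold: int = 100
) -> pd.DataFrame:
    """Per-replicate viability estimates as a tidy table."""
    rows = []
    for v in measurements:
        est = quantify_viability(v, lawn_threshold=lawn_threshold)
        rows.append(
            {
                "strain_id": est.strain_id,
                "replicate": est.replicate_id,
                "temperature_C": v.temperature,
                "cfu_per_ml": est.cfu_per_ml,
                "cfu_per_ml_per_od": est.cfu_per_ml_per_od,
                "selected_dilution": est.selected_dilution,
                "censored_above": est.censored_above,
                "below_detection": est.below_detection,
            }
        )
    return pd.DataFrame(rows)
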