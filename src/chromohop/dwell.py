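"""Chromatin-binding residence times from slow-acquisition movies.

At 1 s exposures, diffusing molecules are blurred away and only stationary
(chromatin-bound) molecules appear as sharp diffraction-limited spots; the
length of each such track is an apparent dwell time.  Apparent dwell times
are shortened by photobleaching, blinking, drift and defocus loss.  A
stably bound reference species (residence time far beyond the observation
span, such as the cohesin kleisin) calibrates that loss as an apparent time
constant tBleach; true binding constants then follow from

    tBound = tDwell * tBleach / (tBleach - tDwell),

equivalently 1/tDwell = 1/tBound + 1/tBleach: the observed disappearance
rate is the sum of the true unbinding rate and the loss rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .models import AcquisitionSettings
from .motion import compute_motion_stats

__all__ = [
    "DwellTimeFit",
    "select_stationary",
    "fit_dwell_double_exp",
    "fit_dwell_mle",
    "calibrate_tbleach",
    "correct_bleach",
]

LN2 = float(np.log(2.0))


class CorrectionUndefinedError(ValueError):
    """tDwell >= tBleach: binding outlasts what the loss process allows us
    to observe, so the correction diverges."""


@dataclass
class DwellTimeFit:
    """Double-exponential dwell-time fit with optional bleach correction.

    Time constants are exponential taus; ``half_life = ln2 * tau`` is also
    reported because residence times are conventionally printed either way.
    """

    f_fast: float
    f_slow: float
    tdwell_fast: float               # apparent tau, s
    tdwell_slow: float
    n: int
    single_component: bool = False
    tbleach: float | None = None
    tbound_fast: float | None = None  # corrected tau, s
    tbound_slow: float | None = None

    @property
    def half_life_fast(self) -> float:
        return LN2 * self.tdwell_fast

    @property
    def half_life_slow(self) -> float:
        return LN2 * self.tdwell_slow

    @property
    def corrected_half_life_fast(self) -> float | None:
        return None if self.tbound_fast is None else LN2 * self.tbound_fast

    @property
    def corrected_half_life_slow(self) -> float | None:
        return None if self.tbound_slow is None else LN2 * self.tbound_slow

    def apply_bleach_correction(self, tbleach: float) -> "DwellTimeFit":
        self.tbleach = float(tbleach)
        self.tbound_fast = correct_bleach(self.tdwell_fast, tbleach)
        self.tbound_slow = correct_bleach(self.tdwell_slow, tbleach)
        return self

    def to_dict(self) -> dict:
        return {
            "f_fast": self.f_fast,
            "f_slow": self.f_slow,
            "tdwell_fast_s": self.tdwell_fast,
            "tdwell_slow_s": self.tdwell_slow,
            "half_life_fast_s": self.half_life_fast,
            "half_life_slow_s": self.half_life_slow,
            "tbleach_s": self.tbleach,
            "tbound_fast_s": self.tbound_fast,
            "tbound_slow_s": self.tbound_slow,
            "corrected_half_life_fast_s": self.corrected_half_life_fast,
            "corrected_half_life_slow_s": self.corrected_half_life_slow,
            "single_component": self.single_component,
            "n": self.n,
        }


def select_stationary(
    tracks: pd.DataFrame,
    settings: AcquisitionSettings,
    maxD: float = 0.1,
    max_width: float | None = None,
    min_steps: int = 1,
) -> np.ndarray:
    """Dwell times (s) of stationary molecules in a slow-acquisition track set.

    Keeps tracks whose apparent diffusion coefficient D* <= ``maxD`` and
    whose mean fitted Gaussian widths (columns ``sx_um``/``sy_um``, if
    present) are <= ``max_width`` (default 1.5 x psf_sigma).  The dwell time
    of a surviving track is its duration, n_steps * dt.
    """
    if settings.dt < 0.5:
        warnings.warn(
            "select_stationary expects the slow acquisition regime (dt ~ 1 s); "
            "width/D filters are regime-specific",
            stacklevel=2,
        )
    if max_width is None:
        max_width = 1.5 * settings.psf_sigma
    stats = compute_motion_stats(tracks, settings, min_steps=min_steps)
    keep = stats[stats["D_star"] <= maxD]["track_id"]
    sel = tracks[tracks["track_id"].isin(keep)]
    if {"sx_um", "sy_um"}.issubset(sel.columns):
        w = sel.groupby("track_id")[["sx_um", "sy_um"]].mean().mean(axis=1)
        sel = sel[sel["track_id"].isin(w[w <= max_width].index)]
    dwell = sel.groupby("track_id")["frame"].agg(lambda f: f.max() - f.min())
    return (dwell.to_numpy(dtype=float)) * settings.dt


def _survival(dwells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival function 1 - CDF evaluated at the sorted data."""
    t = np.sort(np.asarray(dwells, dtype=float))
    n = t.size
    s = 1.0 - np.arange(1, n + 1) / n
    return t, s


def fit_dwell_double_exp(
    dwells: np.ndarray,
    movie_span: float | None = None,
    min_n: int = 50,
) -> DwellTimeFit:
    """Fit f exp(-t/t1) + (1-f) exp(-t/t2) to the empirical survival curve.

    Least squares on the 1-CDF, the same representation the dwell-time
    distributions are displayed in.  t1 < t2 is enforced by ordering.  If
    the two time constants collapse (within 5%), the fit degenerates to a
    flagged single exponential.  Observations beyond 80% of ``movie_span``
    are excluded as right-censored boundary pile-up.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size == 0:
        raise ValueError("no dwell times provided")
    if movie_span is not None:
        dwells = dwells[dwells <= 0.8 * movie_span]
    if dwells.size < min_n:
        raise ValueError(f"need at least {min_n} dwell observations, got {dwells.size}")
    t, s = _survival(dwells)
    pos = s > 0
    t, s = t[pos], s[pos]

    mean = dwells.mean()

    def resid(theta):
        f, lt1, lt2 = theta
        t1, t2 = np.exp(lt1), np.exp(lt2)
        model = f * np.exp(-t / t1) + (1 - f) * np.exp(-t / t2)
        return model - s

    best = None
    for g1, g2, gf in [(0.3, 3.0, 0.5), (0.1, 1.0, 0.7), (1.0, 10.0, 0.5), (0.05, 5.0, 0.3)]:
        x0 = [gf, np.log(g1 * mean), np.log(g2 * mean)]
        sol = least_squares(resid, x0, bounds=([0.0, -12, -12], [1.0, 12, 12]))
        if best is None or sol.cost < best.cost:
            best = sol
    f, lt1, lt2 = best.x
    t1, t2 = float(np.exp(lt1)), float(np.exp(lt2))
    if t1 > t2:
        t1, t2, f = t2, t1, 1.0 - f

    single = abs(t2 - t1) <= 0.05 * t2 or f < 1e-3 or f > 1 - 1e-3
    if single:
        tau = _fit_single_exp(t, s, mean)
        return DwellTimeFit(1.0, 0.0, tau, tau, int(dwells.size), single_component=True)
    return DwellTimeFit(float(f), float(1 - f), t1, t2, int(dwells.size))


def _fit_single_exp(t: np.ndarray, s: np.ndarray, mean: float) -> float:
    def resid(ltau):
        return np.exp(-t / np.exp(ltau[0])) - s

    sol = least_squares(resid, [np.log(mean)])
    return float(np.exp(sol.x[0]))


def fit_dwell_mle(dwells: np.ndarray) -> DwellTimeFit:
    """Unbinned maximum-likelihood two-exponential mixture fit.

    Cross-check for :func:`fit_dwell_double_exp`; immune to the implicit
    weighting of the survival-curve least squares.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size == 0:
        raise ValueError("no dwell times provided")
    mean = dwells.mean()

    def nll(theta):
        f = 1.0 / (1.0 + np.exp(-theta[0]))
        t1, t2 = np.exp(theta[1]), np.exp(theta[2])
        pdf = f / t1 * np.exp(-dwells / t1) + (1 - f) / t2 * np.exp(-dwells / t2)
        return -np.log(np.maximum(pdf, 1e-300)).sum()

    best = None
    for g in [(0.0, np.log(0.3 * mean), np.log(3 * mean)),
              (1.0, np.log(0.1 * mean), np.log(2 * mean))]:
        sol = minimize(nll, g, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
        if best is None or sol.fun < best.fun:
            best = sol
    f = 1.0 / (1.0 + np.exp(-best.x[0]))
    t1, t2 = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    if t1 > t2:
        t1, t2, f = t2, t1, 1.0 - f
    single = abs(t2 - t1) <= 0.05 * t2
    return DwellTimeFit(float(f), float(1 - f), t1, t2, int(dwells.size),
                        single_component=single)


def calibrate_tbleach(reference_dwells: np.ndarray,
                      movie_span: float | None = None) -> float:
    """Observation-loss time constant from a stably bound reference species.

    The reference's true residence time vastly exceeds the observation
    span, so its apparent dwell distribution reflects only photobleaching /
    blinking / defocus loss.  The dominant (larger-amplitude) component of
    a double-exponential fit is returned as tBleach; a pure loss process
    collapses to a single exponential.
    """
    reference_dwells = np.asarray(reference_dwells, dtype=float)
    if reference_dwells.size == 0:
        raise ValueError("no reference dwell times")
    if np.ptp(reference_dwells) == 0:
        raise ValueError("reference dwell distribution shows no decay")
    if movie_span is not None:
        frac_censored = np.mean(reference_dwells >= 0.8 * movie_span)
        if frac_censored > 0.5:
            raise ValueError(
                "most reference dwells run to the movie end: the loss process "
                "is slower than the observation span and tBleach is unresolved"
            )
    fit = fit_dwell_double_exp(reference_dwells, movie_span=movie_span)
    if fit.single_component:
        tb = fit.tdwell_slow
    else:
        tb = fit.tdwell_fast if fit.f_fast >= fit.f_slow else fit.tdwell_slow
    if movie_span is not None and tb >= movie_span:
        warnings.warn("tBleach is at/above the movie span; loss is unresolved",
                      stacklevel=2)
    return float(tb)


def correct_bleach(tdwell: float, tbleach: float) -> float:
    """True binding time constant from the apparent one.

    tBound = tDwell * tBleach / (tBleach - tDwell); strictly increasing in
    tDwell and diverging as tDwell -> tBleach (binding longer than the loss
    process lets us observe).
    """
    if tdwell <= 0 or tbleach <= 0:
        raise ValueError("time constants must be > 0")
    if tdwell >= tbleach:
        raise CorrectionUndefinedError(
            f"tDwell ({tdwell:g} s) >= tBleach ({tbleach:g} s): "
            "binding outlasts the observable window"
        )
    return float(tdwell * tbleach / (tbleach - tdwell))
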