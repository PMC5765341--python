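"""Applied analyses: equilibrium frequency versus drive strength.

Built for the maize Ab10 presets (``maize_solid``, ``maize_dashed``): sweep
the drive parameter d over its mechanistic range (0 to 2/3, i.e. ovule
transmission 0.5 to 5/6), locate the attractor at each d, and compare the
predicted adult-census driver frequency with the range observed in maize
land races (0 to 33% of adult plants).  The driver persists only inside a
window of d values: below the lower boundary the wild type is globally
stable, above the upper boundary the driver sweeps to fixation.

Two window estimators are reported side by side: the transcritical
crossings of the closed-form fixation eigenvalues (lambda0 = 1 gives the
lower boundary, lambda1 = 1 the upper), and a direct global scan that
iterates the recursion on a d grid and brackets where an interior attractor
appears and disappears.  For well-behaved presets the two coincide; both are
exposed because they are logically distinct claims (local invasibility vs.
observed global attraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibria import global_outcome
from .model import GameteFreqState, adult_allele_frequency
from .params import DriveParams
from .stability import lambda0, lambda1

__all__ = [
    "DriveWindow",
    "equilibrium_curve",
    "drive_window",
    "land_race_consistency",
]

#: mechanistic maximum of d (ovule transmission 5/6) used as the default
#: upper end of drive grids
D_MAX_MECHANISTIC = 2.0 / 3.0


@dataclass(frozen=True)
class DriveWindow:
    """Interval of drive values supporting a stable interior equilibrium."""

    d_low: float
    d_high: float
    method: str  # "eigenvalue-crossing" | "global-scan"
    empty: bool = False

    @property
    def transmission_low(self) -> float:
        return (1 + self.d_low) / 2.0

    @property
    def transmission_high(self) -> float:
        return (1 + self.d_high) / 2.0

    def as_dict(self) -> dict[str, object]:
        return {
            "method": self.method,
            "empty": self.empty,
            "d_low": self.d_low,
            "d_high": self.d_high,
            "ovule_transmission_low": self.transmission_low,
            "ovule_transmission_high": self.transmission_high,
        }


def _attractor_at(base: DriveParams, d: float, tol: float, max_gen: int):
    gb = global_outcome(base.replace(d=float(d)), tol=tol, max_gen=max_gen)
    if gb.outcome == "STABLE_POLYMORPHISM":
        return gb, GameteFreqState(*gb.attractors[0])
    if gb.outcome == "AB10_FIXATION":
        return gb, GameteFreqState(1.0, 1.0)
    if gb.outcome == "N10_FIXATION":
        return gb, GameteFreqState(0.0, 0.0)
    return gb, None


def equilibrium_curve(
    base: DriveParams,
    d_grid: np.ndarray,
    tol: float = 1e-10,
    max_gen: int = 200_000,
) -> pd.DataFrame:
    """Attractor frequencies for each drive value on a grid.

    Columns: d, ovule_transmission, p_f_hat, p_m_hat (attractor at the
    gamete census; 0 or 1 at fixations), adult_freq (allele frequency at the
    flowering census), outcome, and cycling/converged diagnostics.  Rows
    with non-point attractors (cycling or disagreeing starts) carry NaN
    frequencies and the diagnostic label.
    """
    rows = []
    for d in np.atleast_1d(np.asarray(d_grid, dtype=float)):
        gb, state = _attractor_at(base, d, tol, max_gen)
        if state is None:
            pf = pm = adult = math.nan
        else:
            pf, pm = state
            adult = adult_allele_frequency(state, base.replace(d=float(d)))
        rows.append(
            {
                "d": float(d),
                "ovule_transmission": (1 + float(d)) / 2.0,
                "p_f_hat": pf,
                "p_m_hat": pm,
                "adult_freq": adult,
                "outcome": gb.outcome,
                "cycling": gb.cycling,
            }
        )
    return pd.DataFrame(rows)


def _eigen_crossings(base: DriveParams, xtol: float) -> DriveWindow:
    # lambda0 increases in d, lambda1 decreases: the window is
    # (d: lambda0 = 1, d: lambda1 = 1) when both crossings exist in [0, 1].
    g0 = lambda d: lambda0(base.replace(d=d)) - 1.0
    l1_fn = lambda d: lambda1(base.replace(d=d))
    g1 = lambda d: (l1_fn(d) - 1.0) if math.isfinite(l1_fn(d)) else math.inf

    if g0(0.0) >= 0.0:
        d_low = 0.0  # driver invades even without drive
    elif g0(1.0) < 0.0:
        return DriveWindow(math.nan, math.nan, "eigenvalue-crossing", empty=True)
    else:
        d_low = float(brentq(g0, 0.0, 1.0, xtol=xtol))
    if g1(1.0) >= 0.0 or math.isinf(g1(0.0)):
        d_high = 1.0  # the normal allele always invades: no fixation of the driver
    elif g1(0.0) < 0.0:
        d_high = 0.0
    else:
        d_high = float(brentq(g1, 0.0, 1.0, xtol=xtol))
    if d_high <= d_low:
        return DriveWindow(d_low, d_high, "eigenvalue-crossing", empty=True)
    return DriveWindow(d_low, d_high, "eigenvalue-crossing")


def _global_scan(
    base: DriveParams, d_grid: np.ndarray, xtol: float, tol: float, max_gen: int
) -> DriveWindow:
    grid = np.sort(np.atleast_1d(np.asarray(d_grid, dtype=float)))

    def interior(d: float) -> bool:
        gb, _ = _attractor_at(base, d, tol, max_gen)
        return gb.outcome == "STABLE_POLYMORPHISM"

    flags = [interior(d) for d in grid]
    if not any(flags):
        return DriveWindow(math.nan, math.nan, "global-scan", empty=True)
    first = int(np.argmax(flags))
    last = len(flags) - 1 - int(np.argmax(flags[::-1]))

    def refine(lo: float, hi: float, lo_interior: bool) -> float:
        # bisect the boolean transition between lo and hi
        while hi - lo > xtol:
            mid = (lo + hi) / 2.0
            if interior(mid) == lo_interior:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    d_low = grid[0] if first == 0 else refine(grid[first - 1], grid[first], False)
    d_high = (
        grid[-1]
        if last == len(grid) - 1
        else refine(grid[last], grid[last + 1], True)
    )
    return DriveWindow(float(d_low), float(d_high), "global-scan")


def drive_window(
    base: DriveParams,
    method: str = "both",
    d_grid: np.ndarray | None = None,
    xtol: float = 1e-6,
    tol: float = 1e-10,
    max_gen: int = 200_000,
) -> dict[str, DriveWindow]:
    """Drive interval supporting an interior attractor, by one or both methods.

    ``eigenvalue-crossing`` solves lambda0(d) = 1 and lambda1(d) = 1 by
    bisection; ``global-scan`` brackets the appearance/disappearance of an
    interior attractor on ``d_grid`` (default 0 to 2/3, step 0.002) and
    refines by bisection.  Returns a dict keyed by method so callers can
    compare the two estimates.
    """
    if d_grid is None:
        d_grid = np.arange(0.0, D_MAX_MECHANISTIC + 1e-12, 0.002)
    out: dict[str, DriveWindow] = {}
    if method in ("both", "eigenvalue-crossing"):
        out["eigenvalue-crossing"] = _eigen_crossings(base, xtol)
    if method in ("both", "global-scan"):
        out["global-scan"] = _global_scan(base, d_grid, xtol, tol, max_gen)
    if not out:
        raise ValueError(
            "method must be 'eigenvalue-crossing', 'global-scan' or 'both'"
        )
    return out


def land_race_consistency(
    base: DriveParams,
    observed_adult_freq_max: float,
    d_grid: np.ndarray,
    tol: float = 1e-10,
    max_gen: int = 200_000,
) -> pd.DataFrame:
    """Flag drive values whose attractor matches observed adult frequencies.

    For each d the attractor's adult allele frequency is compared with the
    observed range (0, ``observed_adult_freq_max``]; the flag is true for a
    positive equilibrium frequency not exceeding the observed maximum.  The
    frame's ``attrs['consistent_d_range']`` records the (min, max) flagged d.
    """
    if not 0.0 < observed_adult_freq_max < 1.0:
        raise ValueError("observed_adult_freq_max must lie in (0, 1)")
    frame = equilibrium_curve(base, d_grid, tol=tol, max_gen=max_gen)
    frame["within_observed_range"] = (
        (frame["adult_freq"] > 0.0)
        & (frame["adult_freq"] <= observed_adult_freq_max)
    )
    flagged = frame.loc[frame["within_observed_range"], "d"]
    frame.attrs["observed_adult_freq_max"] = observed_adult_freq_max
    frame.attrs["consistent_d_range"] = (
        (float(flagged.min()), float(flagged.max())) if len(flagged) else None
    )
    return frame
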