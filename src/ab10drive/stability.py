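"""Invasion analysis at the two fixation equilibria.

The loss and fixation states of the driver are fixed points of the
recursion.  Local stability of each is governed by the leading eigenvalue of
the 2x2 linearization there.  Both eigenvalues have closed forms with a
direct reading: (relative seed-to-flowering survival of the heterozygote
against the resident homozygote) times (its relative fitness through ovules
plus through pollen, each including gamete transmission).

    lambda0 = (1 - h v) [ (1 - h_f f)(1 - h_s s)(1 + d)/2 + (1 - h_m m)/2 ]

for a rare driver invading the wild-type population, and

    lambda1 = (1 - h v)/(1 - v) *
              [ (1 - h_f f)(1 - h_s s)(1 - d) / (2 (1 - f)(1 - s))
                + (1 - h_m m) / (2 (1 - m)) ]

for the normal allele invading a driver-fixed population.  An eigenvalue
above 1 means the rare allele increases; the sign pattern of
(lambda0 - 1, lambda1 - 1) yields four qualitative outcomes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import model_weights, _step_raw
from .params import DriveParams

__all__ = [
    "Outcome",
    "StabilityReport",
    "lambda0",
    "lambda1",
    "lambda0_arrays",
    "lambda1_arrays",
    "jacobian_leading_eigen",
    "classify_outcome",
    "stability_report",
    "boundary_curve",
]

#: classification tolerance on |lambda - 1|; ties resolve to the <= 1 branch
EIGEN_TIE_TOL = 1e-12


class Outcome(str, enum.Enum):
    """Four-way qualitative outcome from the fixation eigenvalues.

    N10_FIXATION            lambda0 <= 1 < lambda1: only the normal allele
                            invades when rare; the driver is lost.
    AB10_FIXATION           lambda0 > 1 >= lambda1: only the driver invades;
                            it sweeps to fixation.
    BISTABLE                both <= 1: neither allele invades when rare; the
                            outcome depends on the starting frequency via an
                            unstable interior equilibrium.
    PROTECTED_POLYMORPHISM  both > 1: either allele invades when rare,
                            generically a stable interior equilibrium.
    """

    N10_FIXATION = "N10_FIXATION"
    AB10_FIXATION = "AB10_FIXATION"
    BISTABLE = "BISTABLE"
    PROTECTED_POLYMORPHISM = "PROTECTED_POLYMORPHISM"


def lambda0(params: DriveParams) -> float:
    """Leading eigenvalue for a rare driver invading the wild type."""
    p = params
    return (1 - p.h * p.v) * (
        (1 - p.h_f * p.f) * (1 - p.h_s * p.s) * (1 + p.d) / 2.0
        + (1 - p.h_m * p.m) / 2.0
    )


def lambda1(params: DriveParams) -> float:
    """Leading eigenvalue for the normal allele invading a driver-fixed
    population.

    When any of v, f, s, m equals 1 the resident homozygote is inviable or
    sterile and the normal allele trivially invades: the value is flagged
    as ``math.inf`` rather than raising.
    """
    p = params
    if 1.0 in (p.v, p.f, p.s, p.m):
        return math.inf
    return ((1 - p.h * p.v) / (1 - p.v)) * (
        (1 - p.h_f * p.f) * (1 - p.h_s * p.s) * (1 - p.d)
        / (2.0 * (1 - p.f) * (1 - p.s))
        + (1 - p.h_m * p.m) / (2.0 * (1 - p.m))
    )


def lambda0_arrays(
    d: np.ndarray, v: np.ndarray, f: np.ndarray, s: np.ndarray, m: np.ndarray,
    h: np.ndarray, h_f: np.ndarray, h_s: np.ndarray, h_m: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`lambda0` over parameter arrays."""
    return (1 - h * v) * (
        (1 - h_f * f) * (1 - h_s * s) * (1 + d) / 2.0 + (1 - h_m * m) / 2.0
    )


def lambda1_arrays(
    d: np.ndarray, v: np.ndarray, f: np.ndarray, s: np.ndarray, m: np.ndarray,
    h: np.ndarray, h_f: np.ndarray, h_s: np.ndarray, h_m: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`lambda1`; degenerate residents map to +inf."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ((1 - h * v) / (1 - v)) * (
            (1 - h_f * f) * (1 - h_s * s) * (1 - d) / (2.0 * (1 - f) * (1 - s))
            + (1 - h_m * m) / (2.0 * (1 - m))
        )
    degenerate = (v == 1) | (f == 1) | (s == 1) | (m == 1)
    return np.where(degenerate, np.inf, out)


class DegenerateResidentError(ZeroDivisionError):
    """The resident population at the requested fixation is inviable."""


def jacobian(state: tuple[float, float], params: DriveParams,
             eps: float = 1e-100) -> np.ndarray:
    """2x2 linearization of the one-generation map by complex-step
    differentiation.

    The raw recursion is a rational map, analytic wherever the normalizers
    are nonzero, so J[i, j] = Im(f_i(x + i*eps*e_j)) / eps is exact to
    machine precision (no subtractive cancellation), including at the
    fixation corners and near-degenerate residents.
    """
    w = model_weights(params)
    J = np.empty((2, 2))
    for j in range(2):
        z = [complex(state[0]), complex(state[1])]
        z[j] += 1j * eps
        fz = _step_raw(z[0], z[1], w)
        for i in range(2):
            J[i, j] = fz[i].imag / eps
    return J


def jacobian_leading_eigen(params: DriveParams, fixation: str) -> float:
    """Spectral radius of the numeric Jacobian at a fixation.

    Serves as the independent oracle for the closed forms.  ``fixation`` is
    ``"N10"`` (driver absent) or ``"Ab10"`` (driver fixed).

    Raises
    ------
    DegenerateResidentError
        At the driver fixation when the resident is inviable/sterile
        (v, f, s or m equal to 1), mirroring the infinite flag of
        :func:`lambda1`.
    """
    if fixation == "N10":
        point = (0.0, 0.0)
    elif fixation == "Ab10":
        p = params
        if 1.0 in (p.v, p.f, p.s, p.m):
            raise DegenerateResidentError(
                "resident driver homozygote is inviable or sterile"
            )
        point = (1.0, 1.0)
    else:
        raise ValueError("fixation must be 'N10' or 'Ab10'")
    J = jacobian(point, params)
    if not np.all(np.isfinite(J)):
        raise DegenerateResidentError("map not differentiable at fixation")
    return float(np.max(np.abs(np.linalg.eigvals(J))))


def classify_outcome(params: DriveParams) -> Outcome:
    """Map the fixation-eigenvalue sign pattern to the four-way outcome.

    Values within ``EIGEN_TIE_TOL`` of 1 are treated as <= 1 (measure-zero
    set under random draws; the tie rule keeps classification deterministic).
    """
    return _classify(lambda0(params), lambda1(params))


def _classify(l0: float, l1: float) -> Outcome:
    inv0 = l0 > 1.0 + EIGEN_TIE_TOL  # driver invades the wild type
    inv1 = l1 > 1.0 + EIGEN_TIE_TOL  # normal allele invades the driver
    if inv0 and inv1:
        return Outcome.PROTECTED_POLYMORPHISM
    if inv0:
        return Outcome.AB10_FIXATION
    if inv1:
        return Outcome.N10_FIXATION
    return Outcome.BISTABLE


@dataclass(frozen=True)
class StabilityReport:
    """Both fixation eigenvalues and the implied qualitative outcome."""

    lambda0: float
    lambda1: float
    outcome: Outcome

    @property
    def lambda1_infinite(self) -> bool:
        return math.isinf(self.lambda1)

    def as_dict(self) -> dict[str, object]:
        return {
            "lambda0": self.lambda0,
            "lambda1": self.lambda1 if math.isfinite(self.lambda1) else "inf",
            "outcome": self.outcome.value,
        }


def stability_report(params: DriveParams) -> StabilityReport:
    l0, l1 = lambda0(params), lambda1(params)
    return StabilityReport(l0, l1, _classify(l0, l1))


def boundary_curve(
    params_base: DriveParams,
    eigen: str,
    drive_grid: np.ndarray,
    tol: float = 1e-10,
) -> list[dict[str, float]]:
    """For each drive value, the ovule-cost root f of eigenvalue = 1.

    Traces the transcritical boundary in the (drive, f) plane: for each d in
    ``drive_grid``, all other parameters held at ``params_base``, find the f
    in [0, 1] at which the chosen eigenvalue (``"lambda0"`` or ``"lambda1"``)
    equals 1, by bisection (the eigenvalues are monotone in f).  Rows carry
    d, the equivalent ovule transmission (1+d)/2, and ``f_root`` (NaN when
    the eigenvalue does not cross 1 on [0, 1]).
    """
    if eigen == "lambda0":
        fn = lambda0
    elif eigen == "lambda1":
        fn = lambda1
    else:
        raise ValueError("eigen must be 'lambda0' or 'lambda1'")

    rows = []
    for d in np.atleast_1d(np.asarray(drive_grid, dtype=float)):
        def g(f_val: float, d=float(d)) -> float:
            val = fn(params_base.replace(d=d, f=f_val))
            return val - 1.0 if math.isfinite(val) else math.inf

        f_hi = 1.0 - 1e-12 if eigen == "lambda1" else 1.0
        g_lo, g_hi = g(0.0), g(f_hi)
        if g_lo == 0.0:
            root = 0.0
        elif g_hi == 0.0:
            root = f_hi
        elif g_lo * g_hi > 0 or not (math.isfinite(g_lo) and math.isfinite(g_hi)):
            root = math.nan
        else:
            root = float(brentq(g, 0.0, f_hi, xtol=tol))
        rows.append(
            {"d": float(d), "ovule_transmission": (1 + float(d)) / 2.0,
             "f_root": root}
        )
    return rows
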