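"""Interior equilibria of the recursion and global behavior.

At a fixed point the two map residuals vanish.  Multiplying through by the
(interior-positive) mean fitnesses gives two polynomial residuals

    P(p_f, p_m) = A p_f p_m (1 - p_f) + (Bd - B p_f) S - p_f q_f q_m
    Q(p_f, p_m) = C p_f p_m (1 - p_m) + E (1/2 - p_m) S - p_m q_f q_m

with S = p_f q_m + p_m q_f and the composite weights of
:mod:`ab10drive.model`.  P is quadratic in p_f and linear in p_m; Q is
linear in p_f and quadratic in p_m.  Two enumeration routes are provided:

* ``newton`` — damped Newton from a deterministic grid of interior starts,
  with deduplication (the default, and the reference procedure);
* ``elimination`` — solve Q for p_f = -b(p_m)/a(p_m) and substitute into P,
  clearing denominators to a single quintic in p_m whose real interior roots
  enumerate every interior equilibrium (Q linear in p_f means each p_m root
  pairs with exactly one p_f).

Both routes agree on random parameter sets; elimination is complete and much
faster in bulk, Newton requires no polynomial bookkeeping.  Up to three
interior equilibria are observed across random parameter draws, consistent
with the quintic always carrying at least two roots outside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    GameteFreqState,
    Trajectory,
    _step_raw,
    iterate_to_equilibrium,
    model_weights,
)
from .params import DriveParams
from .stability import Outcome, classify_outcome, jacobian

__all__ = [
    "Equilibrium",
    "GlobalBehavior",
    "DegenerateParametersError",
    "residual",
    "find_internal_equilibria",
    "classify_equilibrium_stability",
    "count_internal_equilibria_batch",
    "global_outcome",
]

#: roots closer than this to a boundary are attributed to the fixations
INTERIOR_MARGIN = 1e-6
#: max-norm radius within which two roots are the same equilibrium
DEDUP_RADIUS = 1e-6
#: acceptance threshold on the map residual of a reported equilibrium
RESIDUAL_TOL = 1e-11
#: stability margin around eigenvalue modulus 1
STABILITY_EPS = 1e-9

_BATTERY_EPS = 1e-4
_START_BATTERY = (
    (_BATTERY_EPS, _BATTERY_EPS),
    (1 - _BATTERY_EPS, 1 - _BATTERY_EPS),
    (0.5, 0.5),
    (0.1, 0.9),
    (0.9, 0.1),
)


class DegenerateParametersError(ValueError):
    """The map is the identity on the diagonal (the neutral family)."""


def residual(state: GameteFreqState, params: DriveParams) -> tuple[float, float]:
    """Fixed-point defect ``step(state) - state`` (exact at fixations)."""
    state = GameteFreqState(*state).validate()
    w = model_weights(params)
    pf2, pm2, _, _ = _step_raw(state.p_f, state.p_m, w)
    return pf2 - state.p_f, pm2 - state.p_m


def _check_nondegenerate(w) -> None:
    # identity-on-diagonal iff both diagonal residual polynomials vanish
    if (
        abs(w.A - 2 * w.B + 1) < 1e-14
        and abs(2 * w.Bd - 1) < 1e-14
        and abs(w.C - 2 * w.E + 1) < 1e-14
        and abs(w.E - 1) < 1e-14
    ):
        raise DegenerateParametersError(
            "neutral parameter family: every diagonal state is a fixed point"
        )


def _poly_residuals(pf, pm, A, B, Bd, C, E):
    """Polynomial residuals (P, Q); accepts scalars or ndarrays."""
    S = pf + pm - 2 * pf * pm
    wt = (1 - pf) * (1 - pm)
    P = A * pf * pm * (1 - pf) + (Bd - B * pf) * S - pf * wt
    Q = C * pf * pm * (1 - pm) + E * (0.5 - pm) * S - pm * wt
    return P, Q


def _poly_jacobian(pf, pm, A, B, Bd, C, E):
    """Analytic partials of (P, Q) w.r.t. (pf, pm)."""
    S = pf + pm - 2 * pf * pm
    dS_pf = 1 - 2 * pm
    dS_pm = 1 - 2 * pf
    P_pf = A * pm * (1 - 2 * pf) - B * S + (Bd - B * pf) * dS_pf \
        - (1 - pm) * (1 - 2 * pf)
    P_pm = A * pf * (1 - pf) + (Bd - B * pf) * dS_pm + pf * (1 - pf)
    Q_pf = C * pm * (1 - pm) + E * (0.5 - pm) * dS_pf + pm * (1 - pm)
    Q_pm = C * pf * (1 - 2 * pm) - E * S + E * (0.5 - pm) * dS_pm \
        - (1 - pf) * (1 - 2 * pm)
    return P_pf, P_pm, Q_pf, Q_pm


def _quintic_coeffs(A, B, Bd, C, E):
    """Ascending coefficients (length 6) of the eliminated quintic in p_m.

    Q(p_f, p_m) = a(p_m) p_f + b(p_m) with a, b quadratic; substituting
    p_f = -b/a into P and clearing a**2 gives
    R = c2 b**2 - c1 a b + c0 a**2, deg R = 5.  Works on scalars or
    broadcastable arrays; coefficient axis is the leading one.
    """
    one = np.ones_like(np.asarray(A, dtype=float))
    a = np.stack([E / 2 * one, (C + 1) - 2 * E * one, 2 * E - (C + 1) * one])
    b = np.stack([0 * one, E / 2 * one - 1, (1 - E) * one])
    c2 = np.stack([(1 - B) * one, (2 * B - A - 1) * one])
    c1 = np.stack([(Bd - 1) * one, (A - 2 * Bd - B + 1) * one])
    c0 = np.stack([0 * one, Bd * one])

    def conv(x, y):
        nx, ny = x.shape[0], y.shape[0]
        out = np.zeros((nx + ny - 1,) + x.shape[1:])
        for i in range(nx):
            for j in range(ny):
                out[i + j] += x[i] * y[j]
        return out

    bb = conv(b, b)
    ab = conv(a, b)
    aa = conv(a, a)
    R = conv(c2, bb) - conv(c1, ab) + conv(c0, aa)
    return R, a, b


@dataclass(frozen=True)
class Equilibrium:
    """An interior fixed point with its local-stability label."""

    p_f: float
    p_m: float
    stability: str  # stable | unstable | saddle | indeterminate
    residual_norm: float

    @property
    def state(self) -> GameteFreqState:
        return GameteFreqState(self.p_f, self.p_m)

    def as_dict(self) -> dict[str, float | str]:
        return {
            "p_f": self.p_f,
            "p_m": self.p_m,
            "stability": self.stability,
            "residual_norm": self.residual_norm,
        }


def classify_equilibrium_stability(
    eq: Equilibrium | GameteFreqState, params: DriveParams
) -> str:
    """Label a fixed point by the spectral structure of its linearization.

    All eigenvalue moduli < 1 - eps: ``stable``; any modulus > 1 + eps:
    ``unstable`` (``saddle`` when one modulus is on each side of 1);
    otherwise ``indeterminate`` (within eps of the unit circle).
    """
    pf = eq.p_f
    pm = eq.p_m
    J = jacobian((pf, pm), params)
    mods = np.sort(np.abs(np.linalg.eigvals(J)))
    if mods[-1] < 1 - STABILITY_EPS:
        return "stable"
    if mods[-1] > 1 + STABILITY_EPS:
        return "saddle" if mods[0] < 1 - STABILITY_EPS else "unstable"
    return "indeterminate"


def _newton_roots(
    w, grid_size: int, max_iter: int = 200, ftol: float = 1e-14
) -> list[tuple[float, float]]:
    """Damped Newton on (P, Q) from a grid_size x grid_size interior grid.

    Vectorized over starting points; step halving (up to 12 times) enforces
    residual decrease; diverging points are dropped.
    """
    g = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    pf, pm = (c.ravel() for c in np.meshgrid(g, g))
    A, B, Bd, C, E = w.A, w.B, w.Bd, w.C, w.E
    for _ in range(max_iter):
        P, Q = _poly_residuals(pf, pm, A, B, Bd, C, E)
        r2 = P * P + Q * Q
        if np.all(r2 < ftol**2):
            break
        Ppf, Ppm, Qpf, Qpm = _poly_jacobian(pf, pm, A, B, Bd, C, E)
        det = Ppf * Qpm - Ppm * Qpf
        safe = np.abs(det) > 1e-300
        dpf = np.where(safe, (P * Qpm - Q * Ppm) / np.where(safe, det, 1.0), 0.0)
        dpm = np.where(safe, (Q * Ppf - P * Qpf) / np.where(safe, det, 1.0), 0.0)
        # damping: halve until the residual does not increase
        lam = np.ones_like(pf)
        pf_new, pm_new = pf - dpf, pm - dpm
        for _halve in range(12):
            Pn, Qn = _poly_residuals(pf_new, pm_new, A, B, Bd, C, E)
            worse = (Pn * Pn + Qn * Qn > r2) & (r2 > ftol**2)
            if not np.any(worse):
                break
            lam = np.where(worse, lam / 2, lam)
            pf_new = np.where(worse, pf - lam * dpf, pf_new)
            pm_new = np.where(worse, pm - lam * dpm, pm_new)
        pf, pm = pf_new, pm_new
        # drop runaway points
        keep = (pf > -1.0) & (pf < 2.0) & (pm > -1.0) & (pm < 2.0)
        if not np.all(keep):
            pf, pm = pf[keep], pm[keep]
    P, Q = _poly_residuals(pf, pm, A, B, Bd, C, E)
    ok = (np.abs(P) < ftol) & (np.abs(Q) < ftol)
    ok &= (pf > INTERIOR_MARGIN) & (pf < 1 - INTERIOR_MARGIN)
    ok &= (pm > INTERIOR_MARGIN) & (pm < 1 - INTERIOR_MARGIN)
    return list(zip(pf[ok].tolist(), pm[ok].tolist()))


def _elimination_roots(w) -> list[tuple[float, float]]:
    """All interior roots via the eliminated quintic in p_m."""
    R, a, b = _quintic_coeffs(w.A, w.B, w.Bd, w.C, w.E)
    coeffs = R[::-1]  # descending for np.roots
    coeffs = np.trim_zeros(coeffs, "f")
    if coeffs.size <= 1:
        return []
    roots = np.roots(coeffs)
    out = []
    for z in roots:
        if abs(z.imag) > 1e-9:
            continue
        pm = float(z.real)
        if not (INTERIOR_MARGIN < pm < 1 - INTERIOR_MARGIN):
            continue
        denom = a[0] + a[1] * pm + a[2] * pm * pm
        if abs(denom) < 1e-12:
            continue
        pf = float(-(b[0] + b[1] * pm + b[2] * pm * pm) / denom)
        if INTERIOR_MARGIN < pf < 1 - INTERIOR_MARGIN:
            out.append((pf, pm))
    return out


def _polish(pf, pm, w, iters: int = 6) -> tuple[float, float]:
    A, B, Bd, C, E = w.A, w.B, w.Bd, w.C, w.E
    for _ in range(iters):
        P, Q = _poly_residuals(pf, pm, A, B, Bd, C, E)
        Ppf, Ppm, Qpf, Qpm = _poly_jacobian(pf, pm, A, B, Bd, C, E)
        det = Ppf * Qpm - Ppm * Qpf
        if abs(det) < 1e-300:
            break
        pf -= (P * Qpm - Q * Ppm) / det
        pm -= (Q * Ppf - P * Qpf) / det
    return pf, pm


def _dedup(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    kept: list[tuple[float, float]] = []
    for p in sorted(points):
        if all(
            max(abs(p[0] - k[0]), abs(p[1] - k[1])) > DEDUP_RADIUS for k in kept
        ):
            kept.append(p)
    return kept


def find_internal_equilibria(
    params: DriveParams,
    method: str = "newton",
    grid_size: int = 21,
) -> list[Equilibrium]:
    """Enumerate interior fixed points, sorted by p_f.

    ``method`` is ``"newton"`` (multi-start damped Newton, the default) or
    ``"elimination"`` (quintic resultant).  Every returned equilibrium has
    both coordinates in (1e-6, 1 - 1e-6) and a one-generation map residual
    below 1e-11.

    Raises
    ------
    DegenerateParametersError
        For the neutral family, where every diagonal state is fixed and
        enumeration is meaningless.
    """
    w = model_weights(params)
    _check_nondegenerate(w)
    if method == "newton":
        raw = _newton_roots(w, grid_size)
    elif method == "elimination":
        raw = [_polish(pf, pm, w) for pf, pm in _elimination_roots(w)]
    else:
        raise ValueError("method must be 'newton' or 'elimination'")
    raw = [
        p
        for p in raw
        if INTERIOR_MARGIN < p[0] < 1 - INTERIOR_MARGIN
        and INTERIOR_MARGIN < p[1] < 1 - INTERIOR_MARGIN
    ]
    out = []
    for pf, pm in _dedup(raw):
        r = residual(GameteFreqState(pf, pm), params)
        rnorm = max(abs(r[0]), abs(r[1]))
        if rnorm > RESIDUAL_TOL:
            continue
        label = classify_equilibrium_stability(GameteFreqState(pf, pm), params)
        out.append(Equilibrium(pf, pm, label, rnorm))
    return sorted(out, key=lambda e: e.p_f)


def count_internal_equilibria_batch(
    A: np.ndarray,
    B: np.ndarray,
    Bd: np.ndarray,
    C: np.ndarray,
    E: np.ndarray,
    method: str = "newton",
    grid_size: int = 21,
    max_iter: int = 60,
) -> np.ndarray:
    """Interior-equilibrium counts for a batch of parameter sets.

    Inputs are the composite weights (see :func:`ab10drive.model.model_weights`)
    as 1-D arrays of equal length.  ``newton`` runs the damped multi-start
    scheme vectorized over draws x starts; ``elimination`` solves the batch
    of quintics.  Returns an integer array of counts.
    """
    A, B, Bd, C, E = (np.asarray(x, dtype=float).ravel() for x in (A, B, Bd, C, E))
    n = A.size
    if method == "elimination":
        counts = np.zeros(n, dtype=int)
        R, a, b = _quintic_coeffs(A, B, Bd, C, E)  # shapes (6|3, n)
        for i in range(n):
            coeffs = np.trim_zeros(R[::-1, i], "f")
            if coeffs.size <= 1:
                continue
            roots = np.roots(coeffs)
            c = 0
            seen: list[tuple[float, float]] = []
            for z in roots:
                if abs(z.imag) > 1e-9:
                    continue
                pm = float(z.real)
                if not (INTERIOR_MARGIN < pm < 1 - INTERIOR_MARGIN):
                    continue
                denom = a[0, i] + a[1, i] * pm + a[2, i] * pm * pm
                if abs(denom) < 1e-12:
                    continue
                pf = -(b[0, i] + b[1, i] * pm + b[2, i] * pm * pm) / denom
                if not (INTERIOR_MARGIN < pf < 1 - INTERIOR_MARGIN):
                    continue
                if all(
                    max(abs(pf - s[0]), abs(pm - s[1])) > DEDUP_RADIUS
                    for s in seen
                ):
                    seen.append((pf, pm))
                    c += 1
            counts[i] = c
        return counts
    if method != "newton":
        raise ValueError("method must be 'newton' or 'elimination'")

    g = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    gf, gm = (c.ravel() for c in np.meshgrid(g, g))
    ns = gf.size
    pf = np.broadcast_to(gf, (n, ns)).copy()
    pm = np.broadcast_to(gm, (n, ns)).copy()
    Ax, Bx, Bdx, Cx, Ex = (x[:, None] for x in (A, B, Bd, C, E))
    ftol = 1e-14
    for _ in range(max_iter):
        P, Q = _poly_residuals(pf, pm, Ax, Bx, Bdx, Cx, Ex)
        r2 = P * P + Q * Q
        active = r2 > ftol**2
        if not np.any(active):
            break
        Ppf, Ppm, Qpf, Qpm = _poly_jacobian(pf, pm, Ax, Bx, Bdx, Cx, Ex)
        det = Ppf * Qpm - Ppm * Qpf
        safe = np.abs(det) > 1e-300
        inv = np.where(safe, det, 1.0)
        dpf = np.where(safe & active, (P * Qpm - Q * Ppm) / inv, 0.0)
        dpm = np.where(safe & active, (Q * Ppf - P * Qpf) / inv, 0.0)
        pf_new, pm_new = pf - dpf, pm - dpm
        for _halve in range(8):
            Pn, Qn = _poly_residuals(pf_new, pm_new, Ax, Bx, Bdx, Cx, Ex)
            worse = (Pn * Pn + Qn * Qn > r2) & active
            if not np.any(worse):
                break
            dpf = np.where(worse, dpf / 2, dpf)
            dpm = np.where(worse, dpm / 2, dpm)
            pf_new = np.where(worse, pf - dpf, pf_new)
            pm_new = np.where(worse, pm - dpm, pm_new)
        pf, pm = pf_new, pm_new
        np.clip(pf, -1.0, 2.0, out=pf)
        np.clip(pm, -1.0, 2.0, out=pm)
    P, Q = _poly_residuals(pf, pm, Ax, Bx, Bdx, Cx, Ex)
    ok = (np.abs(P) < ftol) & (np.abs(Q) < ftol)
    ok &= (pf > INTERIOR_MARGIN) & (pf < 1 - INTERIOR_MARGIN)
    ok &= (pm > INTERIOR_MARGIN) & (pm < 1 - INTERIOR_MARGIN)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        pts = list(zip(pf[i][ok[i]].tolist(), pm[i][ok[i]].tolist()))
        counts[i] = len(_dedup(pts))
    return counts


@dataclass
class GlobalBehavior:
    """Attractors reached from a standard battery of starting points."""

    outcome: str
    attractors: list[tuple[float, float]]
    per_start: list[dict[str, object]] = field(default_factory=list)
    eigen_outcome: Outcome | None = None
    agrees_with_eigenvalues: bool = False
    cycling: bool = False

    def as_dict(self) -> dict[str, object]:
        return {
            "outcome": self.outcome,
            "attractors": [list(a) for a in self.attractors],
            "eigen_outcome": self.eigen_outcome.value if self.eigen_outcome else None,
            "agrees_with_eigenvalues": self.agrees_with_eigenvalues,
            "cycling": self.cycling,
            "per_start": self.per_start,
        }


_CORNER_TOL = 1e-5


def _attractor_label(state: GameteFreqState) -> str:
    if state.p_f < _CORNER_TOL and state.p_m < _CORNER_TOL:
        return "loss"
    if state.p_f > 1 - _CORNER_TOL and state.p_m > 1 - _CORNER_TOL:
        return "fixation"
    return "interior"


def global_outcome(
    params: DriveParams,
    starts: tuple[tuple[float, float], ...] = _START_BATTERY,
    tol: float = 1e-12,
    max_gen: int = 1_000_000,
) -> GlobalBehavior:
    """Iterate from a battery of starts and label the global behavior.

    The label summarizes where the battery lands: ``N10_FIXATION`` (all
    runs lose the driver), ``AB10_FIXATION`` (all fix it),
    ``STABLE_POLYMORPHISM`` (all reach one interior attractor),
    ``BISTABLE`` (corners only, start-dependent), or ``MIXED``.  The
    agreement flag compares against the eigenvalue classification.
    """
    _check_nondegenerate(model_weights(params))
    per_start = []
    labels = set()
    interior: list[tuple[float, float]] = []
    cycling = False
    for s0 in starts:
        traj: Trajectory = iterate_to_equilibrium(
            GameteFreqState(*s0), params, tol=tol, max_gen=max_gen
        )
        cycling |= traj.cycling
        lab = _attractor_label(traj.final)
        labels.add(lab)
        if lab == "interior":
            if all(
                max(abs(traj.final.p_f - a[0]), abs(traj.final.p_m - a[1]))
                > 1e-6
                for a in interior
            ):
                interior.append((traj.final.p_f, traj.final.p_m))
        per_start.append(
            {
                "start": list(s0),
                "final": [traj.final.p_f, traj.final.p_m],
                "label": lab,
                "converged": traj.converged,
                "cycling": traj.cycling,
                "generations": traj.generations,
            }
        )
    if labels == {"loss"}:
        outcome = "N10_FIXATION"
    elif labels == {"fixation"}:
        outcome = "AB10_FIXATION"
    elif labels == {"interior"} and len(interior) == 1:
        outcome = "STABLE_POLYMORPHISM"
    elif labels == {"loss", "fixation"}:
        outcome = "BISTABLE"
    else:
        outcome = "MIXED"
    eig = classify_outcome(params)
    expected = {
        Outcome.N10_FIXATION: "N10_FIXATION",
        Outcome.AB10_FIXATION: "AB10_FIXATION",
        Outcome.PROTECTED_POLYMORPHISM: "STABLE_POLYMORPHISM",
        Outcome.BISTABLE: "BISTABLE",
    }[eig]
    attractors = interior or sorted(
        {(round(p["final"][0]), round(p["final"][1])) for p in per_start
         if p["label"] != "interior"}
    )
    return GlobalBehavior(
        outcome=outcome,
        attractors=[(float(a), float(b)) for a, b in attractors],
        per_start=per_start,
        eigen_outcome=eig,
        agrees_with_eigenvalues=(outcome == expected),
        cycling=cycling,
    )
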