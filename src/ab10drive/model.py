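"""One-generation recursions of the two-sex drive model.

The population is censused at the gamete stage: ``p_f`` is the driver
frequency among ovules and ``p_m`` among pollen, immediately after drive and
gametic selection.  One generation consists of random union of gametes,
seed-viability and survival selection on the resulting genotypes, and
production of the next gamete pool with fecundity selection and drive.

With q = 1 - p, the next-generation ovule frequency is

    p_f' = [ p_f p_m (1-f)(1-s)(1-v)
             + ((p_f q_m + p_m q_f)/2) (1-h_f f)(1-h_s s)(1-h v)(1+d) ] / W_f

and the pollen frequency is

    p_m' = [ p_f p_m (1-m)(1-v)
             + ((p_f q_m + p_m q_f)/2) (1-h_m m)(1-h v) ] / W_m

where W_f and W_m are the corresponding normalizing mean fitnesses (the same
numerators with the drive factor removed and both alleles of heterozygotes
counted, plus the wild-type term q_f q_m).

A haploid pollen-drive effect is deliberately not modeled: transmission of
either allele through pollen of heterozygotes is exactly 1/2.  Extending the
model would replace that 1/2 in the male terms by a drive-weighted fraction,
symmetrically to the female (1+d)/2 — an extension hook documented here but
out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

from .params import DriveParams

__all__ = [
    "GameteFreqState",
    "Trajectory",
    "DegenerateNormalizerError",
    "step",
    "mean_fitnesses",
    "iterate_to_equilibrium",
    "adult_genotype_frequencies",
    "adult_allele_frequency",
    "max_transmission",
]


class DegenerateNormalizerError(ZeroDivisionError):
    """A mean fitness is zero, so the recursion is undefined at this state."""


class GameteFreqState(NamedTuple):
    """Driver frequency in ovules (``p_f``) and pollen (``p_m``)."""

    p_f: float
    p_m: float

    @property
    def q_f(self) -> float:
        return 1.0 - self.p_f

    @property
    def q_m(self) -> float:
        return 1.0 - self.p_m

    def validate(self) -> "GameteFreqState":
        if not (0.0 <= self.p_f <= 1.0 and 0.0 <= self.p_m <= 1.0):
            raise ValueError(f"frequencies outside [0, 1]: {self}")
        return self


class ModelWeights(NamedTuple):
    """Composite coefficients of the recursion, precomputed from params.

    A  = (1-f)(1-s)(1-v)        driver-homozygote female weight
    B  = (1-h_f f)(1-h_s s)(1-h v)  heterozygote female weight (no drive)
    Bd = B (1+d)/2              heterozygote female weight with drive
    C  = (1-m)(1-v)             driver-homozygote male weight
    E  = (1-h_m m)(1-h v)       heterozygote male weight
    """

    A: float
    B: float
    Bd: float
    C: float
    E: float


def model_weights(params: DriveParams) -> ModelWeights:
    p = params
    B = (1 - p.h_f * p.f) * (1 - p.h_s * p.s) * (1 - p.h * p.v)
    return ModelWeights(
        A=(1 - p.f) * (1 - p.s) * (1 - p.v),
        B=B,
        Bd=B * (1 + p.d) / 2.0,
        C=(1 - p.m) * (1 - p.v),
        E=(1 - p.h_m * p.m) * (1 - p.h * p.v),
    )


def _step_raw(
    p_f: float, p_m: float, w: ModelWeights
) -> tuple[float, float, float, float]:
    """Evaluate the recursion algebraically; returns (p_f', p_m', W_f, W_m).

    No domain clamping — used both by :func:`step` and by finite-difference
    linearization, which perturbs slightly outside [0, 1].
    """
    q_f = 1.0 - p_f
    q_m = 1.0 - p_m
    cross = p_f * q_m + p_m * q_f
    hom = p_f * p_m
    wt = q_f * q_m

    W_f = w.A * hom + w.B * cross + wt
    W_m = w.C * hom + w.E * cross + wt
    num_f = w.A * hom + w.Bd * cross
    num_m = w.C * hom + w.E * cross / 2.0
    return (
        num_f / W_f if W_f != 0.0 else math.nan,
        num_m / W_m if W_m != 0.0 else math.nan,
        W_f,
        W_m,
    )


def step(state: GameteFreqState, params: DriveParams) -> GameteFreqState:
    """Advance the gamete-census frequencies by one generation.

    Raises
    ------
    DegenerateNormalizerError
        If either mean fitness is zero (possible only at extreme corners,
        e.g. the driver fixed with a lethal homozygous cost).
    """
    state = GameteFreqState(*state).validate()
    w = model_weights(params)
    pf2, pm2, W_f, W_m = _step_raw(state.p_f, state.p_m, w)
    if W_f == 0.0 or W_m == 0.0:
        raise DegenerateNormalizerError(
            f"mean fitness zero at {state} (W_f={W_f}, W_m={W_m})"
        )
    # guard rounding at the corners
    return GameteFreqState(min(max(pf2, 0.0), 1.0), min(max(pm2, 0.0), 1.0))


def mean_fitnesses(
    state: GameteFreqState, params: DriveParams
) -> tuple[float, float]:
    """Normalizing mean fitnesses (W_f, W_m) at the given state."""
    state = GameteFreqState(*state).validate()
    _, _, W_f, W_m = _step_raw(state.p_f, state.p_m, model_weights(params))
    return W_f, W_m


@dataclass
class Trajectory:
    """Iterates of the recursion with convergence diagnostics."""

    states: list[GameteFreqState]
    converged: bool
    generations: int
    cycling: bool = False
    fitnesses: list[tuple[float, float]] = field(default_factory=list)

    @property
    def final(self) -> GameteFreqState:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Generation-indexed table with columns p_f, p_m, W_f, W_m."""
        return pd.DataFrame(
            {
                "generation": range(len(self.states)),
                "p_f": [s.p_f for s in self.states],
                "p_m": [s.p_m for s in self.states],
                "W_f": [w[0] for w in self.fitnesses],
                "W_m": [w[1] for w in self.fitnesses],
            }
        )


def iterate_to_equilibrium(
    state0: GameteFreqState,
    params: DriveParams,
    tol: float = 1e-12,
    max_gen: int = 1_000_000,
    record: bool = False,
) -> Trajectory:
    """Iterate the recursion until successive states differ by < ``tol``.

    Convergence is measured in the max-norm over both coordinates.  A
    period-2 cycle (successive distance stagnant while the two-generation
    distance vanishes, for 100 consecutive generations) is reported via
    ``cycling`` rather than mistaken for an equilibrium.  Non-convergence
    within ``max_gen`` is reported in the trajectory, never raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    w = model_weights(params)
    pf, pm = GameteFreqState(*state0).validate()
    states = [GameteFreqState(pf, pm)]
    fits: list[tuple[float, float]] = []
    if record:
        fits.append(mean_fitnesses(states[0], params))
    cycle_run = 0
    prev2: tuple[float, float] | None = None
    for gen in range(1, max_gen + 1):
        pf2, pm2, W_f, W_m = _step_raw(pf, pm, w)
        if W_f == 0.0 or W_m == 0.0:
            raise DegenerateNormalizerError(
                f"mean fitness zero at ({pf}, {pm})"
            )
        pf2 = min(max(pf2, 0.0), 1.0)
        pm2 = min(max(pm2, 0.0), 1.0)
        if record:
            states.append(GameteFreqState(pf2, pm2))
            fits.append((W_f, W_m))
        delta = max(abs(pf2 - pf), abs(pm2 - pm))
        if prev2 is not None:
            delta2 = max(abs(pf2 - prev2[0]), abs(pm2 - prev2[1]))
            cycle_run = cycle_run + 1 if (delta2 < tol <= delta) else 0
        prev2 = (pf, pm)
        pf, pm = pf2, pm2
        if delta < tol:
            if not record:
                states = [states[0], GameteFreqState(pf, pm)]
            return Trajectory(states, True, gen, False, fits)
        if cycle_run >= 100:
            if not record:
                states = [states[0], GameteFreqState(pf, pm)]
            return Trajectory(states, False, gen, True, fits)
    if not record:
        states = [states[0], GameteFreqState(pf, pm)]
    return Trajectory(states, False, max_gen, False, fits)


def adult_genotype_frequencies(
    state: GameteFreqState, params: DriveParams
) -> tuple[float, float, float]:
    """Genotype frequencies among adults censused at flowering.

    Adults are zygotes (random union of the gamete pools) reweighted by the
    seed-viability and seed-to-flowering survival weights and renormalized.
    Fecundity weights (ovule number f, pollen viability m) act after the
    adult census and are excluded.  Returns (driver hom., het., wild-type).
    """
    state = GameteFreqState(*state).validate()
    p = params
    w_hom = (1 - p.s) * (1 - p.v)
    w_het = (1 - p.h_s * p.s) * (1 - p.h * p.v)
    g_hom = state.p_f * state.p_m * w_hom
    g_het = (state.p_f * state.q_m + state.p_m * state.q_f) * w_het
    g_wt = state.q_f * state.q_m
    total = g_hom + g_het + g_wt
    if total == 0.0:
        raise DegenerateNormalizerError(f"no surviving adults at {state}")
    return g_hom / total, g_het / total, g_wt / total


def adult_allele_frequency(state: GameteFreqState, params: DriveParams) -> float:
    """Driver allele frequency among adults at flowering."""
    g_hom, g_het, _ = adult_genotype_frequencies(state, params)
    return g_hom + g_het / 2.0


def max_transmission(p_mii: float, drive_efficiency: float) -> float:
    """Expected driver transmission through ovules of a heterozygote.

    Drive operates only when driver and normal chromatids separate at the
    second meiotic division (an MII segregation pattern, probability
    ``p_mii``, requiring a crossover between centromere and knob); the
    driver then reaches the egg with probability ``drive_efficiency``.
    Under an MI pattern segregation is Mendelian.  With the canonical
    p_mii = 2/3 and full drive, the cap is 2/3 * 1 + 1/3 * 1/2 = 5/6.
    """
    if not (0.0 <= p_mii <= 1.0 and 0.0 <= drive_efficiency <= 1.0):
        raise ValueError("both arguments must lie in [0, 1]")
    return p_mii * drive_efficiency + (1.0 - p_mii) * 0.5
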