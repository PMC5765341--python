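"""Monte-Carlo classification of the parameter space.

Seven sampling scenarios tabulate how often random parameter sets fall into
each of the four qualitative outcomes:

* ``general`` — all nine parameters independent uniform on (0, 1);
* ``weak_selection`` — every homozygous cost (v, f, s, m) uniform on
  (0, 0.1), i.e. each fitness component of the driver homozygote is within
  90% of the wild type; drive and dominances free;
* ``constant_dominance`` — one shared dominance value, itself uniform on
  (0, 1), applied to all four components;
* ``recessive`` / ``additive`` / ``dominant`` — shared dominance fixed at
  0, 1/2, 1;
* ``actual_drive`` — drive restricted to the range observed in maize land
  races, 0.2 <= d <= 0.6; everything else free.

All draws are uniform on the stated ranges; sweeps are reproducible given
(scenario, n, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .equilibria import count_internal_equilibria_batch
from .params import DriveParams
from .stability import Outcome, lambda0_arrays, lambda1_arrays

__all__ = [
    "Scenario",
    "SCENARIOS",
    "sample_params",
    "sample_param_arrays",
    "run_sweep",
    "SweepResult",
    "eigen_prediction_coverage",
]

_COSTS = ("v", "f", "s", "m")
_DOMS = ("h", "h_f", "h_s", "h_m")
_EIG_ORDER = ("d", "v", "f", "s", "m", "h", "h_f", "h_s", "h_m")


@dataclass(frozen=True)
class Scenario:
    """A named sampling scheme over the nine model parameters.

    ``dominance_mode`` is ``"free"`` (four independent draws),
    ``"shared-random"`` (one draw used for all four), or ``"fixed"`` with
    ``dominance_value`` giving the common constant.
    """

    name: str
    d_range: tuple[float, float] = (0.0, 1.0)
    cost_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {c: (0.0, 1.0) for c in _COSTS}
    )
    dominance_mode: str = "free"
    dominance_value: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in [self.d_range, *self.cost_ranges.values()]:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"range ({lo}, {hi}) outside [0, 1]")
        if self.dominance_mode not in ("free", "shared-random", "fixed"):
            raise ValueError(f"bad dominance mode {self.dominance_mode!r}")
        if self.dominance_mode == "fixed" and self.dominance_value is None:
            raise ValueError("fixed dominance mode needs dominance_value")


SCENARIOS: dict[str, Scenario] = {
    "general": Scenario("general"),
    "weak_selection": Scenario(
        "weak_selection",
        cost_ranges={c: (0.0, 0.1) for c in _COSTS},
    ),
    "constant_dominance": Scenario(
        "constant_dominance", dominance_mode="shared-random"
    ),
    "recessive": Scenario("recessive", dominance_mode="fixed", dominance_value=0.0),
    "additive": Scenario("additive", dominance_mode="fixed", dominance_value=0.5),
    "dominant": Scenario("dominant", dominance_mode="fixed", dominance_value=1.0),
    "actual_drive": Scenario("actual_drive", d_range=(0.2, 0.6)),
}


def sample_param_arrays(
    scenario: Scenario, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw ``n`` parameter sets as a dict of 1-D arrays (fixed draw order)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[str, np.ndarray] = {}
    out["d"] = rng.uniform(*scenario.d_range, n)
    for c in _COSTS:
        out[c] = rng.uniform(*scenario.cost_ranges.get(c, (0.0, 1.0)), n)
    if scenario.dominance_mode == "free":
        for name in _DOMS:
            out[name] = rng.uniform(0.0, 1.0, n)
    elif scenario.dominance_mode == "shared-random":
        shared = rng.uniform(0.0, 1.0, n)
        for name in _DOMS:
            out[name] = shared.copy()
    else:
        for name in _DOMS:
            out[name] = np.full(n, float(scenario.dominance_value))
    return out


def sample_params(scenario: Scenario, rng: np.random.Generator) -> DriveParams:
    """Draw a single parameter set."""
    arrays = sample_param_arrays(scenario, 1, rng)
    return DriveParams(**{k: float(v[0]) for k, v in arrays.items()})


def _composite_weights(p: Mapping[str, np.ndarray]):
    B = (1 - p["h_f"] * p["f"]) * (1 - p["h_s"] * p["s"]) * (1 - p["h"] * p["v"])
    return (
        (1 - p["f"]) * (1 - p["s"]) * (1 - p["v"]),  # A
        B,
        B * (1 + p["d"]) / 2.0,  # Bd
        (1 - p["m"]) * (1 - p["v"]),  # C
        (1 - p["h_m"] * p["m"]) * (1 - p["h"] * p["v"]),  # E
    )


@dataclass
class SweepResult:
    """Outcome tally of a Monte-Carlo sweep."""

    scenario: str
    n: int
    seed: int
    counts: dict[str, int]
    proportions: dict[str, float]
    draws: pd.DataFrame
    equilibria_counted: bool = False
    multi_equilibrium_draws: int | None = None
    max_equilibrium_count: int | None = None

    def summary(self) -> dict[str, object]:
        out: dict[str, object] = {
            "scenario": self.scenario,
            "n": self.n,
            "seed": self.seed,
            "counts": self.counts,
            "proportions": self.proportions,
        }
        if self.equilibria_counted:
            out["multi_equilibrium_draws"] = self.multi_equilibrium_draws
            out["max_equilibrium_count"] = self.max_equilibrium_count
        return out


def run_sweep(
    scenario: Scenario | str,
    n: int,
    seed: int,
    count_equilibria: bool = False,
    equilibrium_method: str = "newton",
    chunk: int = 2000,
) -> SweepResult:
    """Classify ``n`` random draws via the fixation eigenvalues.

    When ``count_equilibria`` is set, interior equilibria are also
    enumerated per draw (``equilibrium_method`` is ``"newton"`` or
    ``"elimination"``) and multi-equilibrium draws tallied; this dominates
    runtime, so eigenvalue-only sweeps are the default.  Identical
    (scenario, n, seed) triples give identical results.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    rng = np.random.default_rng(seed)
    p = sample_param_arrays(scenario, n, rng)
    l0 = lambda0_arrays(**{k: p[k] for k in _EIG_ORDER})
    l1 = lambda1_arrays(**{k: p[k] for k in _EIG_ORDER})
    inv0 = l0 > 1.0
    inv1 = l1 > 1.0
    outcome = np.where(
        inv0 & inv1,
        Outcome.PROTECTED_POLYMORPHISM.value,
        np.where(
            inv0,
            Outcome.AB10_FIXATION.value,
            np.where(inv1, Outcome.N10_FIXATION.value, Outcome.BISTABLE.value),
        ),
    )
    draws = pd.DataFrame({k: p[k] for k in _EIG_ORDER})
    draws["lambda0"] = l0
    draws["lambda1"] = l1
    draws["outcome"] = outcome

    multi = None
    max_count = None
    if count_equilibria:
        A, B, Bd, C, E = _composite_weights(p)
        counts = np.empty(n, dtype=int)
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            counts[lo:hi] = count_internal_equilibria_batch(
                A[lo:hi], B[lo:hi], Bd[lo:hi], C[lo:hi], E[lo:hi],
                method=equilibrium_method,
            )
        draws["n_internal_equilibria"] = counts
        multi = int(np.sum(counts >= 2))
        max_count = int(counts.max()) if n else 0

    tallies = {o.value: int(np.sum(outcome == o.value)) for o in Outcome}
    return SweepResult(
        scenario=scenario.name,
        n=n,
        seed=seed,
        counts=tallies,
        proportions={k: v / n for k, v in tallies.items()},
        draws=draws,
        equilibria_counted=count_equilibria,
        multi_equilibrium_draws=multi,
        max_equilibrium_count=max_count,
    )


def eigen_prediction_coverage(
    scenario: Scenario | str,
    n: int,
    seed: int,
    method: str = "elimination",
) -> float:
    """Fraction of draws whose global behavior the eigenvalues predict.

    Global behavior follows from the fixation-eigenvalue signs exactly when
    at most one interior equilibrium exists; this returns that fraction.
    """
    result = run_sweep(
        scenario, n, seed, count_equilibria=True, equilibrium_method=method
    )
    counts = result.draws["n_internal_equilibria"].to_numpy()
    return float(np.mean(counts <= 1))
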