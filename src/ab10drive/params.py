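"""Model parameters and per-genotype fitness weights.

The model tracks a single locus with two alleles: a female meiotic driver
(Ab10 in maize) and the normal homolog (N10).  Heterozygous mothers transmit
the driver to a fraction ``(1 + d) / 2`` of their ovules; transmission through
pollen is Mendelian.  The driver additionally carries four relative fitness
costs, each with its own dominance coefficient:

====== ============================================ =========
cost    fitness component                            dominance
====== ============================================ =========
``f``   ovule number (female fecundity)              ``h_f``
``s``   seed viability via seed size (maternal)      ``h_s``
``m``   pollen viability                             ``h_m``
``v``   seed-to-flowering survival (offspring)       ``h``
====== ============================================ =========

All nine parameters are dimensionless and lie in [0, 1].  Endpoints are
admitted (fully recessive ``h = 0`` and lethal ``v = 1`` cases are standard);
degenerate divisions that arise at the endpoints are handled per operation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import yaml

PARAM_NAMES = ("d", "f", "h_f", "s", "h_s", "m", "h_m", "v", "h")


class ParameterError(ValueError):
    """A parameter value or parameter file fails validation."""


@dataclass(frozen=True)
class DriveParams:
    """The nine scalar parameters of the drive model.

    Parameters
    ----------
    d
        Drive strength: heterozygous mothers put the driver in ``(1+d)/2``
        of ovules.
    f, h_f
        Homozygous reduction in viable ovule number and its dominance.
    s, h_s
        Homozygous reduction in seed viability (seed size, a maternal
        effect) and its dominance.
    m, h_m
        Homozygous reduction in pollen viability and its dominance.
    v, h
        Homozygous reduction in seed-to-flowering survival (offspring
        genotype) and its dominance.
    """

    d: float = 0.0
    f: float = 0.0
    h_f: float = 0.0
    s: float = 0.0
    h_s: float = 0.0
    m: float = 0.0
    h_m: float = 0.0
    v: float = 0.0
    h: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)):
                raise ParameterError(f"{name} must be a number, got {value!r}")
            object.__setattr__(self, name, float(value))
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(
                    f"{name} = {value} outside the admissible range [0, 1]"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **changes: float) -> "DriveParams":
        return dataclasses.replace(self, **changes)

    def __iter__(self) -> Iterator[float]:
        return (getattr(self, name) for name in PARAM_NAMES)


@dataclass(frozen=True)
class GenotypeWeights:
    """Table of per-genotype weights implied by a :class:`DriveParams`.

    Rows are (driver homozygote, heterozygote, wild-type homozygote).  Each
    row carries the gamete transmission fractions (driver vs. normal, for
    ovules and pollen) and the four viability/fecundity weights.  The
    wild-type row is identically 1 / Mendelian by construction.
    """

    ovule_transmission: tuple[tuple[float, float], ...]
    pollen_transmission: tuple[tuple[float, float], ...]
    pollen_viability: tuple[float, float, float]
    ovule_number: tuple[float, float, float]
    seed_viability: tuple[float, float, float]
    survival: tuple[float, float, float]


def genotype_weights(params: DriveParams) -> GenotypeWeights:
    """Expand the nine parameters into the per-genotype weight table."""
    p = params
    return GenotypeWeights(
        ovule_transmission=((1.0, 0.0), ((1 + p.d) / 2, (1 - p.d) / 2), (0.0, 1.0)),
        pollen_transmission=((1.0, 0.0), (0.5, 0.5), (0.0, 1.0)),
        pollen_viability=(1 - p.m, 1 - p.h_m * p.m, 1.0),
        ovule_number=(1 - p.f, 1 - p.h_f * p.f, 1.0),
        seed_viability=(1 - p.s, 1 - p.h_s * p.s, 1.0),
        survival=(1 - p.v, 1 - p.h * p.v, 1.0),
    )


#: Named parameter presets.
#:
#: ``maize_solid``  — field estimates for Ab10 fitness components (seed set,
#:     seed size, pollen viability, with measured heterozygote dominances) and
#:     no direct offspring-genotype survival cost (v = 0).
#: ``maize_dashed`` — the same estimates plus a hypothetical offspring-genotype
#:     survival cost (v = 0.3, h = 0.238, the averages of the measured
#:     components).
#: ``mimulus``      — the Mimulus guttatus centromere driver: recessive pollen
#:     (m = 0.19) and ovule-number (f = 0.21) costs, within-species drive
#:     d = 0.16.
#:
#: Presets pin d where a single published value exists (mimulus); the maize
#: presets leave d = 0 so callers sweep it.
PRESETS: dict[str, DriveParams] = {
    "maize_solid": DriveParams(
        d=0.0, f=0.650, h_f=0.212, s=0.190, h_s=0.327, m=0.063, h_m=0.176,
        v=0.0, h=0.0,
    ),
    "maize_dashed": DriveParams(
        d=0.0, f=0.650, h_f=0.212, s=0.190, h_s=0.327, m=0.063, h_m=0.176,
        v=0.3, h=0.238,
    ),
    "mimulus": DriveParams(
        d=0.16, f=0.21, h_f=0.0, s=0.0, h_s=0.0, m=0.19, h_m=0.0, v=0.0, h=0.0,
    ),
}


def params_from_mapping(data: Mapping[str, object]) -> DriveParams:
    """Build :class:`DriveParams` from a mapping, rejecting unknown keys."""
    unknown = set(data) - set(PARAM_NAMES)
    if unknown:
        raise ParameterError(
            f"unknown parameter key(s) {sorted(unknown)}; "
            f"admissible keys are {list(PARAM_NAMES)}"
        )
    return DriveParams(**{k: float(v) for k, v in data.items()})  # type: ignore[arg-type]


def load_params(source: str | Path) -> DriveParams:
    """Load parameters from a preset name or a JSON/YAML file.

    The file must be a flat mapping of parameter names to floats; unknown
    keys are rejected with the offending key named.
    """
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    path = Path(source)
    if not path.exists():
        raise ParameterError(
            f"{source!r} is neither a preset ({sorted(PRESETS)}) nor a file"
        )
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ParameterError(f"{path}: expected a flat mapping of parameters")
    return params_from_mapping(data)


def save_params(params: DriveParams, path: str | Path) -> None:
    """Write parameters as JSON (or YAML for .yml/.yaml paths)."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(params.as_dict(), sort_keys=False))
    else:
        path.write_text(json.dumps(params.as_dict(), indent=2) + "\n")
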