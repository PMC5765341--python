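"""Output writers and run manifests shared by the CLI subcommands.

Every file the CLI writes is accompanied by a JSON manifest recording the
subcommand, its full configuration, the seed, the tool version, and the
output paths — enough to reproduce the file exactly.  Numbers are serialized
with 12 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__

FLOAT_FORMAT = "%.12g"


def _jsonify(obj):
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        if math.isnan(obj):
            return "nan"
        return float(FLOAT_FORMAT % obj)
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(data), indent=2) + "\n")


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class RunManifest:
    """Reproducibility record for one CLI invocation."""

    subcommand: str
    config: dict
    seed: int | None = None
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )

    def write(self, path: str | Path) -> None:
        write_json(
            {
                "subcommand": self.subcommand,
                "config": self.config,
                "seed": self.seed,
                "outputs": self.outputs,
                "version": self.version,
                "timestamp": self.timestamp,
            },
            path,
        )


def manifest_path_for(output: str | Path) -> Path:
    output = Path(output)
    return output.with_name(output.name + ".manifest.json")
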