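"""Run configuration, dispatch and provenance records.

Configs are plain mappings (JSON or YAML files; JSON is the canonical form
written back into provenance records) with the keys::

    command, alpha, beta, lambda, gamma_f, gamma_b, k_delay, steps,
    domain, source, initial, seed, output, format

``run`` validates the config, dispatches to the library entry points and
writes a JSON provenance record (config echo, package version, seed) next
to every output artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .fields import save_field
from .fixtures import make_fixture
from .lattice import DelayHistory, simulate_delayed, simulate_lattice
from .params import GainPair, Hyperparams

_COMMANDS = ("simulate", "analyze", "ring", "dispersion", "fixtures")


@dataclass
class RunConfig:
    command: str
    alpha: float = 0.0
    beta: float = 0.0
    lam: float = 0.0
    gamma_f: float = 1.0
    gamma_b: float = 1.0
    k_delay: int = 0
    steps: int = 1
    domain: str = "infinite_truncated"
    source: Optional[float] = None
    initial: str = "dirac"
    seed: int = 0
    output: Optional[str] = None
    format: str = "csv"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ValueError(f"unknown command {self.command!r}")
        if self.format not in ("csv", "archive"):
            raise ValueError("format must be 'csv' or 'archive'")

    @property
    def params(self) -> Hyperparams:
        return Hyperparams(self.alpha, self.beta, self.lam)

    @property
    def gains(self) -> GainPair:
        return GainPair(self.gamma_f, self.gamma_b)

    def to_json(self) -> dict:
        d = asdict(self)
        d["lambda"] = d.pop("lam")
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON or YAML config file into a RunConfig."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)      # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "lambda" in data:
        data["lam"] = data.pop("lambda")
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    extra = {k: v for k, v in data.items() if k not in known}
    kwargs = {k: v for k, v in data.items() if k in known}
    return RunConfig(**kwargs, extra=extra)


def write_provenance(config: RunConfig, output: Path) -> Path:
    record = {
        "package": "pcwave",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_json(),
    }
    path = output.with_suffix(output.suffix + ".provenance.json")
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path


def run(config: RunConfig) -> dict:
    """Dispatch a validated config; returns a summary of produced artifacts."""
    if config.command != "simulate":
        raise ValueError(
            f"config.run handles 'simulate'; use the CLI for {config.command!r}")
    n_layers = int(config.extra.get("n_layers", 2 * config.steps + 1))
    fix = make_fixture(config.initial, n_layers, config.seed,
                       **config.extra.get("fixture_options", {}))
    init = np.asarray(fix.payload, dtype=float)
    if config.k_delay > 0:
        depth = 2 * config.k_delay + 1
        hist = DelayHistory(np.tile(init, (depth, 1)))
        field_out = simulate_delayed(hist, config.params, config.k_delay,
                                     config.steps)
    else:
        src = config.source
        if config.domain == "semi_infinite" and src is None:
            src = float(init[0])
        field_out = simulate_lattice(init, config.params, config.gains,
                                     n_steps=config.steps, domain=config.domain,
                                     source=src)
    artifacts = {}
    if config.output:
        out = Path(config.output)
        written = save_field(field_out, out, format=config.format)
        prov = write_provenance(config, written)
        artifacts = {"field": str(written), "provenance": str(prov)}
    return {"field": field_out, "artifacts": artifacts}
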