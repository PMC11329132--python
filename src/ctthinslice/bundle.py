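"""Trained-model bundles: five position generators plus provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np

from . import cgan, nn
from .pairing import POSITIONS, PositionLabel


@dataclass
class ModelBundle:
    """Five trained position-specific generators plus the method tag.

    ``generators`` maps each of the five :class:`PositionLabel` values to
    a callable ``(N,1,H,W) -> (N,1,H,W)``.  ``method`` is 1 (raw-image
    targets) or 2 (residual targets).  ``provenance`` records training
    configuration and the case identifiers the bundle was fitted on.
    """

    method: int
    generators: dict[PositionLabel, Callable]
    k: int = 3
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in (1, 2):
            raise ValueError(f"method must be 1 or 2, got {self.method}")
        missing = [p.value for p in POSITIONS if p not in self.generators]
        if missing:
            raise ValueError(f"bundle is missing position models: {missing}")

    @property
    def training_case_ids(self) -> list[str]:
        return list(self.provenance.get("case_ids", []))

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in POSITIONS:
            gen = self.generators[p]
            h.update(p.value.encode())
            if hasattr(gen, "named_params"):
                h.update(cgan.checksum(gen).encode())
        return h.hexdigest()

    # -- serialization (one archive per position model + a JSON manifest) ---
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        specs = {}
        for p in POSITIONS:
            gen = self.generators[p]
            if not isinstance(gen, cgan.UNetGenerator):
                raise TypeError("only UNetGenerator bundles are serializable")
            np.savez(directory / f"gen_{p.value}.npz", **nn.state_dict(gen))
            specs[p.value] = gen.spec.__dict__
        manifest = {
            "format": "ctthinslice-bundle-v1",
            "method": self.method,
            "k": self.k,
            "generator_specs": specs,
            "provenance": self.provenance,
        }
        (directory / "bundle.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "bundle.json").read_text())
        if manifest.get("format") != "ctthinslice-bundle-v1":
            raise ValueError("unrecognized bundle format")
        generators: dict[PositionLabel, Callable] = {}
        for p in POSITIONS:
            spec = cgan.GeneratorSpec(**manifest["generator_specs"][p.value])
            gen = cgan.UNetGenerator(spec)
            with np.load(directory / f"gen_{p.value}.npz") as data:
                nn.load_state_dict(gen, dict(data))
            generators[p] = gen
        return cls(method=manifest["method"], generators=generators,
                   k=manifest["k"], provenance=manifest["provenance"])


def stub_bundle(generators: Callable | Mapping[PositionLabel, Callable],
                method: int, k: int = 3) -> ModelBundle:
    """Bundle built from stub generators (baselines, closure tests).

    ``generators`` is either one callable used for every position or a
    mapping from position label to callable.
    """
    if isinstance(generators, Mapping):
        gens = {PositionLabel.from_string(p): g for p, g in generators.items()}
    else:
        gens = {p: generators for p in POSITIONS}
    return ModelBundle(method=method, generators=gens, k=k,
                       provenance={"stub": True})
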