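"""Run configuration: one JSON document that fully determines a run.

Unknown keys are rejected and every violation is reported at once; each
CLI run writes its resolved config next to its outputs so any result can
be reproduced from the sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    matrix: str | None = None
    genes: str | None = None
    barcodes: str | None = None
    clusters: str | None = None
    lr_db: str | None = None
    test_matrix: str | None = None
    scale_factor: float = 1e4
    min_cells_per_ident: int = 0
    min_frac: float = 0.1
    max_p: float = 0.05
    min_z: float | None = None
    min_score: float = 0.0
    pseudocount: float = 0.01
    weight: str = "weight_scale"
    n_neighbors: int = 10
    seed: int = 0
    out_dir: str = "."

    def validate(self) -> None:
        problems = []
        if self.scale_factor <= 0:
            problems.append("scale_factor must be positive")
        if self.min_cells_per_ident < 0:
            problems.append("min_cells_per_ident must be >= 0")
        if not 0 <= self.min_frac <= 1:
            problems.append("min_frac must be in [0, 1]")
        if not 0 < self.max_p <= 1:
            problems.append("max_p must be in (0, 1]")
        if self.min_score < 0:
            problems.append("min_score must be >= 0")
        if self.pseudocount < 0:
            problems.append("pseudocount must be >= 0")
        if self.weight not in ("weight_norm", "weight_scale"):
            problems.append("weight must be weight_norm or weight_scale")
        if self.n_neighbors < 1:
            problems.append("n_neighbors must be >= 1")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
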