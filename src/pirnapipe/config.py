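"""Run configuration: every numeric threshold in the pipeline, with defaults.

Unknown keys are rejected at load time; the effective configuration is
echoed into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    # trimming
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_quality: int = 20
    min_length: int = 25
    # ncRNA decontamination / generic matching
    min_identity: float = 80.0
    max_mismatches: int = 1
    min_query_coverage: float = 90.0
    # genome alignment
    alignment_cap: int = 100
    # cluster counting
    intersect_fraction: float = 1.0  # fixed full-containment contract
    # differential expression
    de_padj: float = 0.05
    de_lfc: float = 1.0
    # signatures
    distance_window: int = 200
    lowess_span: float = 0.1
    # mRNA table processing
    mad_multiplier: float = 3.0
    anova_alpha: float = 0.05
    min_samples: int = 4
    # orchestration
    seed: int = 0
    output_dir: str = "pirnapipe_out"

    def __post_init__(self) -> None:
        if self.intersect_fraction != 1.0:
            raise ValueError("only full containment (intersect_fraction=1.0) is supported")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, directory) -> None:
        Path(directory).mkdir(parents=True, exist_ok=True)
        with open(Path(directory) / "run_config.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
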