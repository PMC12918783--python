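"""Run configuration with documented defaults and YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults match the module-level documentation: coverage threshold 108
    cell lines, strict zero-expression tolerance, 100 permutation rounds at
    a 0.005 per-tail quantile, up to 4 PCA components per pathway, a 0.5
    association cutoff, top-3 reciprocal lists and a novelty index cutoff
    of 5 on the 0–100 scale.
    """

    dependency_path: str | None = None
    expression_path: str | None = None
    gmt_path: str | None = None
    corpus_path: str | None = None
    min_lines: int = 108
    zero_tol: float = 0.0
    n_permutations: int = 100
    tail_quantile: float = 0.005
    pairs_per_round: int = 10_000
    k_components: int = 4
    min_genes: int = 3
    assoc_cutoff: float = 0.5
    top_n: int = 3
    index_cutoff: float = 5.0
    seed: int = 0
    output_dir: str = "coessence_out"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def updated(self, **overrides) -> "RunConfig":
        data = self.to_dict()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
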