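"""Run configuration: every tunable of the pipeline in one flat record.

The defaults are the reference study conditions: a 10 Hz Morlet m=5
narrowband at fs=100 Hz, 1000 independent samples, coupling 0.9 at a
3-sample lag, a 20x20 grid with unit spacing, CL=0.15 at depth 2, and
thresholds -log10(p) in {1.3, 2, 3, 4, 5}.  Configurations round-trip
losslessly through YAML.
"""
from __future__ import annotations

import dataclasses

import yaml

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    f0: float = 10.0
    m: float = 5.0
    fs: float = 100.0
    n_independent: int = 1000
    coupling: float = 0.9
    lag: int = 3
    grid_size: int = 20
    d_g: float = 1.0
    n_parcels: int = 400
    cl: float = 0.15
    theta: int = 2
    delete_frac: float = 0.15
    n_perturb: int = 40
    percentile: float = 99.7
    levels: tuple = (1.3, 2.0, 3.0, 4.0, 5.0)
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["levels"] = list(d["levels"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"{path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        return cls(**d)
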