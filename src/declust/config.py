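"""Run configuration: every tunable, with defaults, plus seed fan-out."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np
import yaml

#: fixed stage order; the run seed fans out to one child seed per stage
_STAGES = ("clustering", "markers", "simulation", "folds", "fixture")


@dataclass
class RunConfig:
    """All pipeline tunables.

    Defaults follow the method's stated operating point: top 5000
    variable genes, DBSCAN ε=4 / minPts=8 on the array grid, 5% sub-cluster
    floor and 50% seed sampling, top t=10 markers per type at
    p(T1)<0.05 / p(T2)>0.05, 10 cells per simulated spot, 10 CV folds.
    """

    top_n_genes: int = 5000
    variable_on_normalized: bool = True
    eps: float = 4.0
    min_pts: int = 8
    frac_threshold: float = 0.05
    seed_frac: float = 0.5
    h_min: int = 2
    h_max: int = 15
    n_clusters: int | None = None      # fixed h overrides the elbow search
    neighbor_k: int = 8
    neighbor_radius: float = 2.0
    min_cluster_size: int = 3
    t_markers: int = 10
    alpha1: float = 0.05
    alpha2: float = 0.05
    pseudobulk_agg: str = "mean"
    deconv_method: str = "clipped_ols"
    cells_per_spot: int = 10
    folds: int = 10
    rng_seed: int = 0

    def stage_seeds(self) -> dict:
        """Deterministic per-stage child seeds from ``rng_seed``."""
        children = np.random.SeedSequence(self.rng_seed).spawn(len(_STAGES))
        return {name: int(ss.generate_state(1)[0] % (2 ** 31))
                for name, ss in zip(_STAGES, children)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
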