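"""Run configuration: defaults, YAML loading and flag overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """End-to-end analysis settings.

    Defaults follow the standard configuration of the method: basis
    dimension K = 60, five 10-stop replicates per route, a 2-degree
    buffered convex hull for the prediction mask and 0.1% occupancy-mass
    tails for the range limits.
    """

    K: int = 60
    J: int = 5
    buffer_deg: float = 2.0
    tail_mass: float = 0.001
    grid_spacing: float = 0.5
    n_chains: int = 3
    n_warmup: int = 2000
    n_samples: int = 2000
    thin: int = 1
    seed: int = 0
    n_pilot_periods: int = 10
    fix_omega: bool = False
    # hyperpriors
    lambda_shape: float = 0.05
    lambda_rate: float = 0.005
    sigma_rw_scale: float = 2.0
    sigma_obs_scale: float = 2.0
    alpha_var: float = 10.0
    null_space_sd: float = 10.0
    slab_variance: float = 100.0
    # file paths
    sites: str = "sites.csv"
    detections: str = "detections.csv"
    covariates: str = "covariates.csv"
    draws: str = "draws.npz"
    out_dir: str = "."

    @classmethod
    def load(cls, path: str | None = None, **overrides) -> "RunConfig":
        """Build from an optional YAML file plus keyword overrides.

        Unknown keys in either source raise, naming the offending field.
        """
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        valid = set(cls.__dataclass_fields__)
        unknown = set(values) - valid
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**values)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
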