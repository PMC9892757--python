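"""Run configuration: every tunable of the pipeline in one validated place.

Defaults are the grid-search optima reported for the method (mu=0.5, beta=8,
k=64, lr=5e-5, alpha=0.1, gamma=2, node dropout 0.5, regular dropout 0.7,
500 epochs).  ``validate_config`` rejects unknown keys, wrong types and
out-of-range values by name so that config files fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .model import ModelConfig

__all__ = ["RunConfig", "validate_config"]


@dataclass(frozen=True)
class RunConfig:
    # similarity fusion and graph assembly
    mu: float = 0.5            # GIP weight in the conditional fusion
    beta: float = 8.0          # similarity-block penalty factor
    lambda_prime: float = 1.0  # original GIP bandwidth
    sim_norm: str = "sym_degree"
    # model
    k: int = 64
    lr: float = 5e-5
    alpha: float = 0.1
    gamma: float = 2.0
    dp_node: float = 0.5
    dp_reg: float = 0.7
    epochs: int = 500
    n_gcn_layers: int = 2
    n_gat_layers: int = 1
    seed: int = 0
    # evaluation
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu out of range [0, 1]: {self.mu}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive: {self.beta}")
        if self.lambda_prime <= 0:
            raise ValueError(f"lambda_prime must be positive: {self.lambda_prime}")
        if self.sim_norm not in ("sym_degree", "max"):
            raise ValueError(f"sim_norm must be 'sym_degree' or 'max': {self.sim_norm}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold out of range (0, 1): {self.threshold}")
        # delegate model-parameter validation
        self.model_config()

    def model_config(self, seed: int | None = None) -> ModelConfig:
        return ModelConfig(
            k=self.k, lr=self.lr, alpha=self.alpha, gamma=self.gamma,
            dp_node=self.dp_node, dp_reg=self.dp_reg, epochs=self.epochs,
            n_gcn_layers=self.n_gcn_layers, n_gat_layers=self.n_gat_layers,
            seed=self.seed if seed is None else seed,
        )

    def replace(self, **kwargs) -> "RunConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return RunConfig(**current)


_FIELD_TYPES = {
    "mu": float, "beta": float, "lambda_prime": float, "sim_norm": str,
    "k": int, "lr": float, "alpha": float, "gamma": float,
    "dp_node": float, "dp_reg": float, "epochs": int,
    "n_gcn_layers": int, "n_gat_layers": int, "seed": int, "threshold": float,
}


def validate_config(raw: dict | None) -> RunConfig:
    """Build a RunConfig from a parsed YAML/JSON mapping.

    An empty mapping yields the full default configuration.  Unknown keys,
    wrong types and out-of-range values raise ``ValueError`` naming the key.
    """
    raw = dict(raw or {})
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        want = _FIELD_TYPES[key]
        if want is float:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ValueError(f"config key {key!r} must be a number, got {value!r}")
            coerced[key] = float(value)
        elif want is int:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ValueError(f"config key {key!r} must be an integer, got {value!r}")
            coerced[key] = value
        else:
            if not isinstance(value, str):
                raise ValueError(f"config key {key!r} must be a string, got {value!r}")
            coerced[key] = value
    try:
        return RunConfig(**coerced)
    except ValueError as err:
        raise ValueError(str(err)) from None
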