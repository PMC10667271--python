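"""Configuration objects for the simulation and the pipeline.

Defaults mirror the sampled design of a gradual-drying resurrection-
plant experiment:
two tissues (shoot, root), six dehydration states from fully hydrated
down to <10% relative water content plus a rehydrated recovery point,
and triplicate sampling per tissue x state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

DEFAULT_STATES = ("hydrated", "RWC80", "RWC60", "RWC40", "RWC10", "rehydrated")
DEFAULT_TISSUES = ("shoot", "root")

#: Dehydration states during active drying (hydrated reference excluded).
DRYING_STATES = ("RWC80", "RWC60", "RWC40", "RWC10")


class ConfigurationError(ValueError):
    """Raised when a configuration violates one of its invariants."""


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module: where it lives and when it moves.

    Parameters
    ----------
    tissue : str
        Tissue whose samples share the module's latent factor. In the
        other tissue the member genes behave as independent noise.
    active_states : tuple of str
        Dehydration states in which member genes are shifted by the
        planted effect size (so they become true DEGs there).
    direction : {"up", "down"}
        Sign of the planted shift relative to the hydrated reference.
    """

    tissue: str
    active_states: tuple
    direction: str

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ConfigurationError(
                f"module direction must be 'up' or 'down', got {self.direction!r}"
            )


def _default_modules() -> tuple:
    # Broad shoot response (same genes move in every drying state) versus a
    # root module that switches on only at 40% RWC: the shoot/root network
    # contrast the overlay summaries are designed to expose.
    return (
        ModuleSpec("shoot", DRYING_STATES, "up"),
        ModuleSpec("shoot", DRYING_STATES, "down"),
        ModuleSpec("root", ("RWC40",), "down"),
        ModuleSpec("root", ("RWC60", "RWC40", "RWC10"), "up"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-omics data generator.

    All randomness derives from ``seed`` through named substreams, so
    regenerating one table never perturbs the others.
    """

    n_genes: int = 1200
    module_size: int = 50
    modules: tuple = field(default_factory=_default_modules)
    n_metabolites: int = 30
    states: tuple = DEFAULT_STATES
    tissues: tuple = DEFAULT_TISSUES
    replicates: int = 3
    noise_sd: float = 0.1
    module_corr: float = 0.4
    deg_log2fc: float = 2.0
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def __post_init__(self):
        if self.module_size * self.n_modules > self.n_genes:
            raise ConfigurationError(
                "module_size * n_modules exceeds n_genes "
                f"({self.module_size} * {self.n_modules} > {self.n_genes})"
            )
        if not 0.0 < self.module_corr < 1.0:
            raise ConfigurationError(
                f"module_corr must lie in (0, 1), got {self.module_corr}"
            )
        if self.replicates < 2:
            raise ConfigurationError(
                f"replicates must be >= 2, got {self.replicates}"
            )
        if "hydrated" not in self.states:
            raise ConfigurationError("states must include 'hydrated'")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.deg_log2fc < 1:
            raise ConfigurationError(
                f"deg_log2fc must be >= 1, got {self.deg_log2fc}"
            )
        for m in self.modules:
            if m.tissue not in self.tissues:
                raise ConfigurationError(f"module tissue {m.tissue!r} not in tissues")
            unknown = set(m.active_states) - set(self.states)
            if unknown:
                raise ConfigurationError(
                    f"module active states {sorted(unknown)} not in states"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modules"] = [asdict(m) for m in self.modules]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "modules" in d:
            d["modules"] = tuple(
                ModuleSpec(m["tissue"], tuple(m["active_states"]), m["direction"])
                for m in d["modules"]
            )
        for key in ("states", "tissues"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings: thresholds, inputs and output layout.

    The analysis thresholds default to the pipeline's standard rule set:
    fold change >= 2 with BH-adjusted p < 0.05 for DEGs, the top 10,000
    genes by coefficient of variation, and |Pearson r| > 0.964 for
    network edges.
    """

    simulate: SimulationConfig | None = None
    input_dir: str | None = None
    outdir: str = "desiccnet_out"
    fc_threshold: float = 2.0
    alpha: float = 0.05
    top_k: int = 10000
    corr_threshold: float = 0.964
    seed: int = 0

    def __post_init__(self):
        if self.fc_threshold <= 0:
            raise ConfigurationError("fc_threshold must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0.0 < self.corr_threshold <= 1.0:
            # 1.0 is allowed: |r| > 1 is impossible, yielding an empty network
            raise ConfigurationError("corr_threshold must lie in (0, 1]")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.simulate is None and self.input_dir is None:
            raise ConfigurationError(
                "either a simulate block or an input_dir is required"
            )

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "fc_threshold": self.fc_threshold,
            "alpha": self.alpha,
            "top_k": self.top_k,
            "corr_threshold": self.corr_threshold,
            "seed": self.seed,
            "input_dir": self.input_dir,
            "simulate": self.simulate.to_dict() if self.simulate else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulate")
        if sim is not None:
            d["simulate"] = SimulationConfig.from_dict(sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
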