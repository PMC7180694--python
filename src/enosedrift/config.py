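"""Run configuration: every tunable default in one serializable record."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .kernels import KernelSpec


@dataclass
class MethodConfig:
    """Full method configuration for the batch protocol.

    kernel        kernel for K_x (linear by default)
    mu            MICF variance/independence trade-off
    h             MICF subspace dimension; None = min(n_features, n-1)
    level_coded   use literal level indices instead of one-hot in Y
    use_micf      project through the MICF subspace
    use_ifld      run the pseudo-label refinement loop (else one-shot fit)
    classifier    benchmark classifier name ("logistic" or "mlp")
    k             FLD dimension; None = n_classes - 1
    max_iter/tol  IFLD stopping rule
    pooled_target adapt all target batches jointly instead of per batch
    source_only_scatter   ablation: scatter matrices from source only
    seed          run-level seed for every stochastic component
    """

    kernel: KernelSpec = field(default_factory=KernelSpec)
    mu: float = 1.0
    h: int | None = None
    level_coded: bool = False
    use_micf: bool = True
    use_ifld: bool = True
    classifier: str = "logistic"
    classifier_params: dict = field(default_factory=dict)
    k: int | None = None
    max_iter: int = 20
    tol: float = 0.0
    pooled_target: bool = False
    source_only_scatter: bool = False
    seed: int = 0

    @property
    def method_tag(self) -> str:
        if self.use_micf and self.use_ifld:
            return "micf-ifld"
        if self.use_micf:
            return "micf"
        if self.use_ifld:
            return "ifld"
        return "baseline"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = self.kernel.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MethodConfig":
        d = dict(d)
        if "kernel" in d and isinstance(d["kernel"], dict):
            d["kernel"] = KernelSpec.from_dict(d["kernel"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MethodConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
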