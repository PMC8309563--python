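"""Run configuration: every hyperparameter of the three pipelines and
the windowing, serialisable to/from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .cnn import CnnConfig


@dataclass
class RunConfig:
    # windowing
    window_seconds: float = 1.0
    overlap: float = 0.5
    fs: float = 64.0
    # pipeline 1: handcrafted features + ReliefF + SVM
    svm_gamma: float = 0.001
    svm_c: float = 1000.0
    relieff_k: int = 10
    relieff_n_samples: int | str = "all"
    top_n_features: int | None = None  # None = rank only, keep all 55
    # pipeline 2: per-channel LDA + KNN
    lda_components: int | None = None  # None = l - 1
    lda_shrinkage: str | float = "auto"
    knn_k: int = 5
    # pipeline 3: per-channel CNN
    cnn: CnnConfig = field(default_factory=CnnConfig)
    # orchestration
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, cnn=replace(self.cnn, seed=seed))

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cnn_data = data.pop("cnn", {})
        if "fc_sizes" in cnn_data:
            cnn_data["fc_sizes"] = tuple(cnn_data["fc_sizes"])
        return cls(cnn=CnnConfig(**cnn_data), **data)
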