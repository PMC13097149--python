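"""Configuration records for training and experiment orchestration.

Paper-scale defaults follow the published protocol (AdamW, lr 1e-4,
cosine annealing, batch 16, max 150 epochs, patience 25); the ``desk``
profile scales everything down so the full pipeline runs on one CPU in
minutes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

from .data.specs import DEFAULT_RESOLUTION


@dataclass
class SegTrainConfig:
    epochs: int = 150
    batch_size: int = 16
    lr: float = 1e-4
    weight_decay: float = 1e-4
    base_width: int = 16
    val_fraction: float = 0.2
    resolution: int = DEFAULT_RESOLUTION
    max_train_samples: Optional[int] = None   # cap for desk-scale speed

    @classmethod
    def desk(cls, **over) -> "SegTrainConfig":
        d = dict(epochs=8, batch_size=8, lr=2e-3)
        d.update(over)
        return cls(**d)


@dataclass
class ClsTrainConfig:
    epochs: int = 150
    patience: int = 25
    batch_size: int = 16
    lr: float = 1e-4
    weight_decay: float = 1e-4
    backbone: str = "tiny"
    dropout: float = 0.3
    lambdas: Tuple[float, float, float, float] = (1.0, 1.0, 0.5, 0.1)
    background_attenuation: float = 0.0
    val_fraction: float = 0.2
    resolution: int = DEFAULT_RESOLUTION
    use_attention: bool = True
    use_segmentation: bool = True       # all-ones mask when False
    uncertainty_loss: str = "confidence_penalty"   # or "off"
    augment: bool = True

    @classmethod
    def desk(cls, **over) -> "ClsTrainConfig":
        d = dict(epochs=20, patience=5, batch_size=16, lr=2e-3)
        d.update(over)
        return cls(**d)

    def effective_lambdas(self) -> Tuple[float, float, float, float]:
        l1, l2, l3, l4 = self.lambdas
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambda weights must be nonnegative")
        if self.uncertainty_loss == "off":
            l4 = 0.0
        return (l1, l2, l3, l4)


@dataclass
class ExperimentConfig:
    """Full cross-validated experiment over a synthetic dataset."""

    name: str = "full"
    n_classes: int = 3
    n_per_class: int = 200
    resolution: int = DEFAULT_RESOLUTION
    k_folds: int = 2
    seed: int = 42
    mc_passes: int = 25
    n_bins: int = 10
    n_explain: int = 8
    uncertainty_method: str = "entropy"   # better OOD behaviour at desk scale
    use_tta: bool = False
    use_attention_loss: bool = True
    use_uncertainty: bool = True
    seg: SegTrainConfig = field(default_factory=SegTrainConfig.desk)
    cls: ClsTrainConfig = field(default_factory=ClsTrainConfig.desk)
    dataset_dir: Optional[str] = None   # load instead of generate when set

    def validate(self) -> "ExperimentConfig":
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not self.use_attention_loss:
            l = list(self.cls.lambdas)
            l[2] = 0.0
            self.cls.lambdas = tuple(l)
        if not self.use_uncertainty:
            self.cls.uncertainty_loss = "off"
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("seg"), dict):
            d["seg"] = SegTrainConfig(**d["seg"])
        if isinstance(d.get("cls"), dict):
            c = dict(d["cls"])
            if isinstance(c.get("lambdas"), list):
                c["lambdas"] = tuple(c["lambdas"])
            d["cls"] = ClsTrainConfig(**c)
        return cls(**d).validate()
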