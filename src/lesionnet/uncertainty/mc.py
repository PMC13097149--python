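"""Monte-Carlo-dropout predictive distributions and uncertainty scores."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ..classifier.model import LesionPipeline


@dataclass
class MCPrediction:
    samples: np.ndarray   # T x C stochastic probability vectors
    mean: np.ndarray      # length C
    variance: np.ndarray  # length C (population, divide-by-T)
    T: int

    def validate(self) -> "MCPrediction":
        if self.samples.shape != (self.T, self.mean.shape[0]):
            raise ValueError("samples must be T x C")
        if not np.allclose(self.samples.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each sample row must sum to 1")
        if (self.variance < 0).any():
            raise ValueError("variance must be nonnegative")
        return self


def predictive_moments(samples: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Population mean and variance over the T stochastic passes
    (divide by T, not T-1)."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2 or samples.shape[0] < 1:
        raise ValueError("need a nonempty T x C sample matrix")
    mean = samples.mean(axis=0)
    var = ((samples - mean) ** 2).mean(axis=0)
    return mean, var


def mc_predict(pipe: LesionPipeline, image: np.ndarray, T: int,
               seed: int) -> MCPrediction:
    """T stochastic forward passes with dropout active at inference."""
    if T < 1:
        raise ValueError("T must be >= 1")
    x = pipe.prepare([image])
    masks = pipe.predict_soft_masks(x)
    rng = np.random.default_rng(seed)
    pipe.classifier.eval()
    rows = [
        pipe.forward_batch(x, masks=masks, dropout_rng=rng)["probs"][0]
        for _ in range(T)
    ]
    samples = np.stack(rows)
    mean, var = predictive_moments(samples)
    return MCPrediction(samples=samples, mean=mean, variance=var, T=T).validate()


def mc_predict_batch(pipe: LesionPipeline, images: np.ndarray, T: int,
                     seed: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MC inference over N prepared images.

    Returns (samples (T,N,C), mean (N,C), variance (N,C)).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    x = pipe.prepare(list(images))
    masks = pipe.predict_soft_masks(x)
    rng = np.random.default_rng(seed)
    pipe.classifier.eval()
    passes = []
    for _ in range(T):
        probs = []
        for i in range(0, len(x), 32):
            probs.append(pipe.forward_batch(
                x[i:i + 32], masks=masks[i:i + 32], dropout_rng=rng)["probs"])
        passes.append(np.concatenate(probs, axis=0))
    samples = np.stack(passes)          # T x N x C
    mean = samples.mean(axis=0)
    var = ((samples - mean) ** 2).mean(axis=0)
    return samples, mean, var


def uncertainty_score(pred: MCPrediction, method: str = "class_variance") -> float:
    """Scalarize the per-class MC moments."""
    return _score(pred.mean, pred.variance, method)


def _score(mean: np.ndarray, variance: np.ndarray, method: str) -> float:
    if method == "class_variance":
        return float(variance[int(mean.argmax())])
    if method == "entropy":
        p = np.clip(mean, 1e-12, 1.0)
        return float(-(p * np.log(p)).sum())
    raise ValueError(f"unknown uncertainty method {method!r}")


def uncertainty_scores(mean: np.ndarray, variance: np.ndarray,
                       method: str = "class_variance") -> np.ndarray:
    """Vectorized scoring for (N,C) moment arrays."""
    if method == "class_variance":
        top = mean.argmax(axis=1)
        return variance[np.arange(len(mean)), top]
    if method == "entropy":
        p = np.clip(mean, 1e-12, 1.0)
        return -(p * np.log(p)).sum(axis=1)
    raise ValueError(f"unknown uncertainty method {method!r}")


_TTA_VIEWS = (
    lambda im: im,
    lambda im: im[:, ::-1],
    lambda im: im[::-1],
    lambda im: im[::-1, ::-1],
)


def tta_predict(pipe: LesionPipeline, image: np.ndarray, T: int,
                seed: int) -> MCPrediction:
    """MC dropout averaged over 4 deterministic flip views; the T passes per
    view are stacked before moment computation (4T rows total)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    pipe.classifier.eval()
    rows = []
    for view in _TTA_VIEWS:
        img = np.ascontiguousarray(view(image))
        x = pipe.prepare([img])
        masks = pipe.predict_soft_masks(x)
        for _ in range(T):
            rows.append(pipe.forward_batch(
                x, masks=masks, dropout_rng=rng)["probs"][0])
    samples = np.stack(rows)
    mean, var = predictive_moments(samples)
    return MCPrediction(samples=samples, mean=mean, variance=var,
                        T=len(rows)).validate()
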