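"""Local surrogate explanation of fingerprint classifiers (LIME-style).

For one molecule's bit vector *x* the explainer (1) samples a neighbourhood
by redrawing each bit independently from its training-set Bernoulli
frequency, (2) weights each perturbed sample by an exponential proximity
kernel on the *interpretable* representation (1 where the perturbed bit
equals the instance's bit, 0 otherwise), (3) scores the black-box model's
class-1 probability on the perturbed rows, (4) pre-fits a proximity-weighted
ridge regression on all bits and keeps the ``num_features``
largest-magnitude coefficients, and (5) refits the weighted ridge on the
selected bits.  The refit coefficients, clipped to [−1, 1], are the
per-bit contribution weights: +1 pushes the prediction toward disruption,
−1 away from it, 0 is no influence.  The surrogate's proximity-weighted R²
is reported as local fit quality.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import Ridge

from .featurize import BitFingerprint

logger = logging.getLogger(__name__)


@dataclass
class ExplainerConfig:
    """Neighbourhood and surrogate parameters.

    ``kernel_width`` defaults to 0.75·√d for d interpretable features —
    the conventional width for this kernel.  ``num_samples`` defaults to
    5000, at which neighbourhood bit-frequency moments are stable;
    ``num_explanations`` is the number of labels explained per molecule
    (1 = the predicted class only).
    """

    num_features: int = 100
    num_samples: int = 5000
    kernel_width: float | None = None
    num_explanations: int = 1
    seed: int = 0
    ridge_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.num_features < 1:
            raise ValueError("num_features must be >= 1")
        if self.num_samples < 100:
            raise ValueError("num_samples must be >= 100")
        if self.kernel_width is not None and self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")

    def width_for(self, n_dims: int) -> float:
        return self.kernel_width if self.kernel_width is not None else 0.75 * math.sqrt(n_dims)


@dataclass
class LocalExplanation:
    """Per-molecule surrogate result: sparse signed bit weights in [−1, 1]."""

    mol_id: str
    model_probability: float
    weights: list[tuple[int, float]]
    surrogate_fit_quality: float
    degenerate: bool = False  # constant model output in the neighbourhood

    def weight_map(self) -> dict[int, float]:
        return dict(self.weights)

    def to_json_dict(self, config: ExplainerConfig | None = None) -> dict:
        d = {
            "mol_id": self.mol_id,
            "model_probability": self.model_probability,
            "weights": [[int(b), float(w)] for b, w in self.weights],
            "surrogate_fit_quality": self.surrogate_fit_quality,
            "degenerate": self.degenerate,
        }
        if config is not None:
            d["config"] = {
                "num_features": config.num_features,
                "num_samples": config.num_samples,
                "kernel_width": config.width_for(1024) if config.kernel_width is None
                else config.kernel_width,
                "num_explanations": config.num_explanations,
                "seed": config.seed,
            }
        return d


def sample_neighborhood(x: np.ndarray, train_bit_frequencies: np.ndarray,
                        cfg: ExplainerConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Perturbation neighbourhood around one bit vector.

    Returns ``(perturbed, interpretable, proximity)``: ``perturbed`` holds
    ``num_samples`` rows drawn bit-wise from the training Bernoulli
    frequencies (row 0 is *x* itself), ``interpretable[i, j] = 1`` iff
    ``perturbed[i, j] == x[j]``, and ``proximity = exp(−D²/σ²)`` with D the
    Euclidean distance of the interpretable row from the all-ones row of
    the instance itself (so row 0 has proximity 1).
    """
    x = np.asarray(x).astype(np.uint8).ravel()
    freqs = np.asarray(train_bit_frequencies, dtype=float).ravel()
    if x.shape != freqs.shape:
        raise ValueError("instance and frequency vector lengths differ")
    if not freqs.any():
        raise ValueError("all-zero training bit frequencies: nothing to perturb")
    rng = rng or np.random.default_rng(cfg.seed)
    Z = (rng.random((cfg.num_samples, x.size)) < freqs).astype(np.uint8)
    Z[0] = x
    interpretable = (Z == x).astype(np.uint8)
    mismatches = (interpretable == 0).sum(axis=1).astype(float)
    sigma = cfg.width_for(x.size)
    proximity = np.exp(-mismatches / sigma**2)  # D² = mismatch count for binary rows
    return Z, interpretable, proximity


def _weighted_r2(y: np.ndarray, y_hat: np.ndarray, w: np.ndarray) -> float:
    mu = np.average(y, weights=w)
    ss_res = np.average((y - y_hat) ** 2, weights=w)
    ss_tot = np.average((y - mu) ** 2, weights=w)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - ss_res / ss_tot)


def explain(predict_proba1: Callable[[np.ndarray], np.ndarray] | "object",
            x: BitFingerprint | np.ndarray,
            train_bit_frequencies: np.ndarray,
            cfg: ExplainerConfig,
            mol_id: str = "") -> LocalExplanation:
    """Explain one prediction with a locally fitted sparse linear surrogate.

    ``predict_proba1`` is either a callable mapping an (n, d) bit matrix to
    class-1 probabilities or a fitted ModelHandle.  Weights are reported on
    the *bit* scale: positive means the bit's observed state pushes the
    model toward class 1.
    """
    if hasattr(predict_proba1, "predict_proba1"):
        model = predict_proba1
        predict_proba1 = model.predict_proba1
    if isinstance(x, BitFingerprint):
        mol_id = mol_id or x.smiles
        x_vec = x.bits
    else:
        x_vec = np.asarray(x)
    x_vec = x_vec.astype(np.uint8).ravel()

    rng = np.random.default_rng(cfg.seed)
    Z, interp, prox = sample_neighborhood(x_vec, train_bit_frequencies, cfg, rng)
    f = np.asarray(predict_proba1(Z), dtype=float)
    probability = float(f[0])

    if np.ptp(f) == 0.0:
        logger.warning("constant model output around %s; all-zero weights", mol_id or "<instance>")
        return LocalExplanation(mol_id=mol_id, model_probability=probability,
                                weights=[], surrogate_fit_quality=0.0, degenerate=True)

    # interpretable feature j = "bit j kept its observed state"; a positive
    # coefficient therefore means the observed state supports class 1
    pre = Ridge(alpha=cfg.ridge_alpha)
    pre.fit(interp, f, sample_weight=prox)
    order = np.argsort(-np.abs(pre.coef_))
    selected = np.sort(order[: cfg.num_features])

    surrogate = Ridge(alpha=cfg.ridge_alpha)
    surrogate.fit(interp[:, selected], f, sample_weight=prox)
    fit_quality = _weighted_r2(f, surrogate.predict(interp[:, selected]), prox)

    weights = [(int(b), float(np.clip(c, -1.0, 1.0)))
               for b, c in zip(selected, surrogate.coef_)]
    weights.sort(key=lambda bw: -abs(bw[1]))
    return LocalExplanation(mol_id=mol_id, model_probability=probability,
                            weights=weights, surrogate_fit_quality=fit_quality)


def explanations_to_json(explanations: Sequence[LocalExplanation], path: str | Path,
                         config: ExplainerConfig | None = None) -> None:
    payload = [e.to_json_dict(config) for e in explanations]
    Path(path).write_text(json.dumps(payload, indent=1))
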