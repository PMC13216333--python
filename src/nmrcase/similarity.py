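"""Spectral similarity: Euclidean vector distance for fast screening and
optimal-assignment set similarity for precise scoring.

Set similarity between multisets X (size m) and Y (size n) is

    S(X, Y) = max_P  sum_{(i,j) in P} f(x_i, y_j) / sqrt(m n)

over all one-to-one partial matchings P, with the Gaussian kernel
f(x, y) = exp(-(x-y)^2 / (2 sigma^2)).  The optimum is found with the
Kuhn–Munkres algorithm (scipy's linear_sum_assignment); because the
kernel is strictly positive, maximizing over full min(m, n)-matchings is
equivalent to allowing unmatched elements.  S lies in [0, 1], reaches 1
exactly when m = n and a perfect-kernel matching exists, and is bounded
above by sqrt(min(m, n) / max(m, n)) for unequal sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import SpectrumConfig
from .spectra import ShiftMultiset

__all__ = [
    "MatchResult",
    "kernel",
    "multiplicity_weight",
    "set_similarity",
    "vector_distance",
    "combined_score",
]


def kernel(x: float, y: float, sigma: float) -> float:
    """Gaussian pairwise-compatibility kernel, in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return math.exp(-((x - y) ** 2) / (2.0 * sigma**2))


def multiplicity_weight(tag_x: str | None, tag_y: str | None,
                        penalty: float = 0.5) -> float:
    """Default multiplicity-weighting hook.

    Missing tags and the catch-all multiplet 'm' are compatible with
    everything (weight 1); contradictory defined tags get ``penalty``.
    """
    if tag_x is None or tag_y is None or tag_x == "m" or tag_y == "m":
        return 1.0
    return 1.0 if tag_x == tag_y else penalty


@dataclass(frozen=True)
class MatchResult:
    """Outcome of an optimal set-similarity alignment."""

    score: float
    matching: tuple[tuple[int, int], ...]
    pair_kernels: tuple[float, ...]
    empty_input: bool = False

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "matching": [list(p) for p in self.matching],
            "pair_kernels": list(self.pair_kernels),
            "empty_input": self.empty_input,
        }


def set_similarity(
    x: ShiftMultiset,
    y: ShiftMultiset,
    sigma: float,
    weight_fn: Callable[[str | None, str | None], float] | None = None,
) -> MatchResult:
    """Optimal one-to-one kernel matching between two shift multisets.

    When ``weight_fn`` is given, each pairwise kernel is multiplied by
    ``weight_fn(tag_x, tag_y)`` before optimization (multiplicity
    weighting).  Either multiset being empty scores 0 by convention
    (with a warning: the 1/sqrt(mn) normalization is undefined there).
    """
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        warnings.warn("set_similarity of an empty multiset is 0 by convention",
                      stacklevel=2)
        return MatchResult(0.0, (), (), empty_input=True)

    xv = np.asarray(x.shifts, dtype=float)
    yv = np.asarray(y.shifts, dtype=float)
    gain = np.exp(-((xv[:, None] - yv[None, :]) ** 2) / (2.0 * sigma**2))
    if weight_fn is not None:
        tx = x.tags or (None,) * m
        ty = y.tags or (None,) * n
        w = np.array([[weight_fn(a, b) for b in ty] for a in tx], dtype=float)
        gain = gain * w

    rows, cols = linear_sum_assignment(gain, maximize=True)
    pair_kernels = tuple(float(gain[i, j]) for i, j in zip(rows, cols))
    score = float(sum(pair_kernels)) / math.sqrt(m * n)
    matching = tuple(zip(map(int, rows), map(int, cols)))
    return MatchResult(min(score, 1.0), matching, pair_kernels)


def vector_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """Euclidean (L2) distance between two encoded spectra."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"length mismatch: {v1.shape} vs {v2.shape}")
    return float(np.linalg.norm(v1 - v2))


def combined_score(
    target: tuple[ShiftMultiset | None, ShiftMultiset | None],
    candidate: tuple[ShiftMultiset | None, ShiftMultiset | None],
    cfg: SpectrumConfig,
    weight_fn: Callable[[str | None, str | None], float] | None = None,
) -> tuple[float, dict[str, float]]:
    """Weighted mean of per-nucleus set similarities.

    Weights are renormalized over the nuclei present in *both* spectra;
    no common nucleus is an error.  Returns ``(score, parts)`` with the
    per-nucleus scores for reporting.
    """
    t_h, t_c = target
    c_h, c_c = candidate
    if weight_fn is None and cfg.use_multiplicity_weights:
        weight_fn = lambda a, b: multiplicity_weight(a, b, cfg.multiplicity_penalty)

    scores: dict[str, float] = {}
    weights: dict[str, float] = {}
    if t_h is not None and c_h is not None and len(t_h) and len(c_h):
        scores["1H"] = set_similarity(t_h, c_h, cfg.sigma_match_h, weight_fn).score
        weights["1H"] = cfg.weight_h
    if t_c is not None and c_c is not None and len(t_c) and len(c_c):
        scores["13C"] = set_similarity(t_c, c_c, cfg.sigma_match_c).score
        weights["13C"] = cfg.weight_c
    if not scores:
        raise ValueError("target and candidate share no non-empty nucleus")
    total_w = sum(weights.values())
    combined = sum(scores[k] * weights[k] for k in scores) / total_w
    return combined, scores
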