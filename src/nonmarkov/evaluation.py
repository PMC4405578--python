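"""Learning-curve construction, residuals and AICc model comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LearningCurve",
    "ModelFit",
    "sliding_proportion_correct",
    "sliding_window_curve",
    "episode_length_curve",
    "rss",
    "aicc",
    "compare_models",
]


@dataclass
class LearningCurve:
    """A performance trace: per-point mean and SEM over runs.

    ``x`` is 1-based for reporting (trial/episode number); ``y`` holds
    proportion correct (in [0, 1]) or episode length (>= task minimum).
    """

    x: np.ndarray
    y: np.ndarray
    sem: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_runs: int = 1

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y, dtype=float)
        if self.sem is None:
            self.sem = np.zeros_like(self.y)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.sem)):
            raise ValueError("x, y and sem must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": self.x, "value": self.y, "sem": self.sem, "n_runs": self.n_runs}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LearningCurve":
        df = pd.read_csv(path)
        return cls(
            x=df["index"].to_numpy(),
            y=df["value"].to_numpy(),
            sem=df["sem"].to_numpy(),
            n_runs=int(df["n_runs"].iloc[0]) if len(df) else 1,
        )


def _sliding_mean(seq: np.ndarray, window: int, mode: str) -> np.ndarray:
    kernel = np.ones(window) / window
    if mode == "valid":
        return np.convolve(seq, kernel, mode="valid")
    if mode == "trailing":
        # trailing window: point t averages trials max(0, t-window+1) .. t
        csum = np.cumsum(np.insert(seq, 0, 0.0))
        out = np.empty(len(seq))
        for t in range(len(seq)):
            lo = max(0, t - window + 1)
            out[t] = (csum[t + 1] - csum[lo]) / (t + 1 - lo)
        return out
    raise ValueError("mode must be 'valid' or 'trailing'")


def sliding_proportion_correct(
    correctness, window: int = 10, mode: str = "valid"
) -> LearningCurve:
    """Moving average of a binary correctness sequence (10-trial kernel).

    ``correctness`` may be a single sequence or a 2-D array (runs x trials);
    with multiple runs the curve carries the across-run SEM.  In the default
    'valid' mode the first output point corresponds to trial ``window``.
    """
    arr = np.atleast_2d(np.asarray(correctness, dtype=float))
    if window < 1:
        raise ValueError("window must be >= 1")
    if arr.shape[1] < window:
        raise ValueError("sequence shorter than the averaging window")
    per_run = np.stack([_sliding_mean(row, window, mode) for row in arr])
    n_runs = arr.shape[0]
    y = per_run.mean(axis=0)
    sem = (
        per_run.std(axis=0, ddof=1) / math.sqrt(n_runs)
        if n_runs > 1
        else np.zeros_like(y)
    )
    offset = window if mode == "valid" else 1
    x = np.arange(len(y)) + offset
    return LearningCurve(x=x, y=y, sem=sem, n_runs=n_runs)


# Alias used where the sequence is not a correctness trace (e.g. lengths).
sliding_window_curve = sliding_proportion_correct


def episode_length_curve(lengths) -> LearningCurve:
    """Per-episode step counts, averaged over runs if 2-D (runs x episodes)."""
    arr = np.atleast_2d(np.asarray(lengths, dtype=float))
    if arr.shape[1] < 1:
        raise ValueError("need at least one episode")
    n_runs = arr.shape[0]
    y = arr.mean(axis=0)
    sem = (
        arr.std(axis=0, ddof=1) / math.sqrt(n_runs) if n_runs > 1 else np.zeros_like(y)
    )
    return LearningCurve(x=np.arange(1, arr.shape[1] + 1), y=y, sem=sem, n_runs=n_runs)


def rss(curve_a, curve_b) -> float:
    """Sum of squared residuals over the common support of two curves."""
    a = curve_a.y if isinstance(curve_a, LearningCurve) else np.asarray(curve_a, float)
    b = curve_b.y if isinstance(curve_b, LearningCurve) else np.asarray(curve_b, float)
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("curves have empty overlap")
    return float(np.sum((a[:n] - b[:n]) ** 2))


def aicc(rss_value: float, n: int, k: int) -> float:
    """Finite-sample-corrected Akaike information criterion.

    Gaussian-residual form: ``n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)``.
    """
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    if rss_value <= 0:
        raise ValueError("rss must be positive (identical curves have no AICc)")
    return n * math.log(rss_value / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelFit:
    model: str
    k: int
    rss: float
    n: int
    aicc: float
    tied: bool = False


def compare_models(
    reference: LearningCurve,
    model_curves: dict[str, LearningCurve],
    k_values: dict[str, int],
) -> pd.DataFrame:
    """Rank models against a reference curve by AICc (ascending).

    Returns a frame with columns model, k, rss, n, aicc, tied.  A model
    whose curve matches the reference exactly (RSS 0) is ranked first with
    AICc reported as -inf.
    """
    if len(model_curves) < 2:
        raise ValueError("need at least two models to compare")
    fits = []
    for name, curve in model_curves.items():
        k = int(k_values[name])
        n = min(len(reference), len(curve))
        r = rss(reference, curve)
        a = -math.inf if r == 0 else aicc(r, n, k)
        fits.append(ModelFit(model=name, k=k, rss=r, n=n, aicc=a))
    fits.sort(key=lambda f: (f.aicc, f.model))
    aiccs = [f.aicc for f in fits]
    for f in fits:
        f.tied = aiccs.count(f.aicc) > 1
    return pd.DataFrame(
        [
            {
                "model": f.model,
                "k": f.k,
                "rss": f.rss,
                "n": f.n,
                "aicc": f.aicc,
                "tied": f.tied,
            }
            for f in fits
        ]
    )
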