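"""Stratified validation design and area-adjusted accuracy estimation.

Map accuracy is assessed with a stratified random sample whose size follows
the standard design formula

    n = ( Σ_i W_i · sqrt(U_i (1 − U_i)) / S )²

where W_i is the mapped area proportion of class i, U_i the target user's
accuracy and S the target standard error of overall accuracy.  Sites are
allocated equally across classes (class-proportional allocation would leave
the rare WUI classes almost unsampled) and drawn uniformly without
replacement within each stratum.  Accuracies are then estimated
area-adjusted: sample confusion proportions are reweighted by the mapped
class-area proportions, so the dominant non-WUI class carries its true
weight in overall accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Raster

__all__ = [
    "AccuracyEstimate",
    "ValidationDesign",
    "allocate_equal",
    "area_adjusted_accuracy",
    "collapse_classes",
    "draw_stratified_sample",
    "sample_size",
]


def sample_size(W: np.ndarray, U: np.ndarray, S: float) -> int:
    """Number of validation sites for the stratified design.

    Evaluates the design formula and rounds up; a 1e-9 guard is subtracted
    before the ceiling so that analytically integer results (for example
    0.1875 / 0.0001 = 1875 with uniform U = 0.75, S = 0.01) are not bumped
    to the next integer by floating-point noise.
    """
    W = np.asarray(W, dtype=float)
    U = np.asarray(U, dtype=float)
    if S <= 0:
        raise ValueError(f"target standard error must be > 0, got {S}")
    if np.any((U <= 0) | (U >= 1)):
        raise ValueError("target user's accuracies must lie strictly in (0, 1)")
    if abs(W.sum() - 1.0) > 1e-9:
        raise ValueError(f"mapped area proportions must sum to 1, got {W.sum()}")
    total = float(np.sum(W * np.sqrt(U * (1.0 - U))))
    return int(math.ceil((total / S) ** 2 - 1e-9))


def allocate_equal(n: int, k: int) -> np.ndarray:
    """Split ``n`` sites over ``k`` classes as evenly as possible.

    Each class receives ⌊n/k⌋ or ⌈n/k⌉ sites; the extra sites go to the
    lowest class indices, so the allocation is deterministic and sums to n.
    """
    if k < 1 or n < k:
        raise ValueError(f"need n >= k >= 1, got n={n}, k={k}")
    base, extra = divmod(n, k)
    return np.array([base + (1 if i < extra else 0) for i in range(k)], dtype=int)


@dataclass(frozen=True)
class ValidationDesign:
    """A complete stratified sampling design."""

    W: np.ndarray
    U: np.ndarray
    S: float
    n: int
    allocation: np.ndarray

    @classmethod
    def build(
        cls, W, U, S: float, n: int | None = None
    ) -> "ValidationDesign":
        """Design from targets; ``n`` may be overridden (the formula's n is
        used otherwise)."""
        W = np.asarray(W, dtype=float)
        U = np.asarray(U, dtype=float)
        n_eff = sample_size(W, U, S) if n is None else int(n)
        return cls(W=W, U=U, S=S, n=n_eff, allocation=allocate_equal(n_eff, len(W)))


def draw_stratified_sample(
    class_raster: Raster, allocation: np.ndarray, seed: int
) -> pd.DataFrame:
    """Uniform without-replacement sample within each stratum.

    Strata are the sorted distinct non-nodata codes of ``class_raster``;
    ``allocation[i]`` sites are drawn from stratum i.  Reproducible under a
    fixed seed.  Returns a table of (row, col, x, y, map_class).
    """
    rng = np.random.default_rng(seed)
    values = class_raster.values
    strata = sorted(int(c) for c in np.unique(values[class_raster.valid]))
    if len(strata) != len(allocation):
        raise ValueError(
            f"allocation has {len(allocation)} entries but raster has "
            f"{len(strata)} strata"
        )
    g = class_raster.grid
    frames = []
    for code, count in zip(strata, allocation):
        flat = np.flatnonzero(values.ravel() == code)
        if flat.size < count:
            raise ValueError(
                f"stratum {code} has only {flat.size} pixel(s), cannot draw {count}"
            )
        pick = rng.choice(flat, size=int(count), replace=False)
        rows, cols = np.unravel_index(pick, values.shape)
        frames.append(
            pd.DataFrame(
                {
                    "row": rows,
                    "col": cols,
                    "x": g.origin_x + (cols + 0.5) * g.pixel_size,
                    "y": g.origin_y - (rows + 0.5) * g.pixel_size,
                    "map_class": code,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class AccuracyEstimate:
    """Area-adjusted confusion statistics.

    ``p`` holds the estimated population cell proportions
    p_ij = W_i · n_ij / n_i· (map class i, reference class j); they sum
    to 1.  ``overall`` is Σ_i p_ii; ``users``/``producers`` are per-class
    accuracies; ``naive_overall`` ignores the area weights.
    """

    counts: np.ndarray
    W: np.ndarray
    p: np.ndarray
    overall: float
    users: np.ndarray
    producers: np.ndarray
    naive_overall: float


def area_adjusted_accuracy(counts: np.ndarray, W: np.ndarray) -> AccuracyEstimate:
    """Area-adjusted overall, user's and producer's accuracies.

    Rows of ``counts`` are map classes, columns reference classes.  Classes
    with positive mapped proportion must have sampled rows.
    """
    counts = np.asarray(counts, dtype=float)
    W = np.asarray(W, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if counts.shape[0] != W.size:
        raise ValueError("W length must match the confusion matrix size")
    if abs(W.sum() - 1.0) > 1e-9:
        raise ValueError("mapped area proportions must sum to 1")
    row_sums = counts.sum(axis=1)
    bad = (row_sums == 0) & (W > 0)
    if bad.any():
        raise ValueError(
            f"class(es) {np.flatnonzero(bad).tolist()} have mapped area but no samples"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = W[:, None] * counts / np.where(row_sums[:, None] > 0, row_sums[:, None], 1.0)
        overall = float(np.trace(p))
        p_row = p.sum(axis=1)
        p_col = p.sum(axis=0)
        users = np.where(p_row > 0, np.diag(p) / p_row, np.nan)
        producers = np.where(p_col > 0, np.diag(p) / p_col, np.nan)
    naive = float(np.trace(counts) / counts.sum()) if counts.sum() else float("nan")
    return AccuracyEstimate(
        counts=counts, W=W, p=p, overall=overall,
        users=users, producers=producers, naive_overall=naive,
    )


def collapse_classes(
    counts: np.ndarray, W: np.ndarray, mapping: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge classes of a confusion matrix (for example five → WUI vs non-WUI).

    ``mapping[i]`` is the group index of original class i and must be a
    surjection onto 0..k−1.  Counts and area proportions are summed within
    groups; the estimators then apply unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    W = np.asarray(W, dtype=float)
    mapping = np.asarray(mapping, dtype=int)
    if mapping.size != counts.shape[0]:
        raise ValueError("mapping length must match the number of classes")
    k = mapping.max() + 1
    if set(mapping.tolist()) != set(range(k)):
        raise ValueError(f"mapping must be a surjection onto 0..{k - 1}")
    out = np.zeros((k, k))
    w_out = np.zeros(k)
    for i in range(counts.shape[0]):
        w_out[mapping[i]] += W[i]
        for j in range(counts.shape[1]):
            out[mapping[i], mapping[j]] += counts[i, j]
    return out, w_out


WUI_BINARY_MAPPING = np.array([0, 1, 1, 1, 1])
"""Five classes (non-WUI first) collapsed to non-WUI vs WUI."""
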