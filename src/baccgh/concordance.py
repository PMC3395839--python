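"""Weighted Pearson concordance between two aCGH profiles.

Unweighted Pearson correlation between genomic profiles is dominated by how
many clones deviate from normal at all; weighting each position by its own
and its neighbour's deviation from the profile median emphasizes the clones
that actually carry signal. With x_ref = median(x) and y_ref = median(y)
over the n shared autosomal clones, position i (i = 1..n-1) gets weight

    w_i = 1/2 * [ median_{j in {i, i+1}} |x_j - x_ref|
                + median_{j in {i, i+1}} |y_j - y_ref| ]

(the median of two numbers being their midpoint), and

    r_w = cov(x, y; w) / sqrt(cov(x, x; w) * cov(y, y; w))

with weighted covariances over observations 1..n-1 normalized by sum(w).
The coefficient is bucketed into the qualitative bins [0, 0.2) uncorrelated,
[0.2, 0.4) lowly, [0.4, 0.6) fairly, [0.6, 0.8) moderately, [0.8, 1]
highly correlated; negative values are labelled anticorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .preprocess import Profile

CATEGORIES = ["uncorrelated", "lowly", "fairly", "moderately", "highly"]


@dataclass(frozen=True)
class AlignedPair:
    """Two samples' mean log2 vectors over their shared autosomal,
    QC-passing-in-both clones, in genome order."""

    clone_ids: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return len(self.clone_ids)


@dataclass(frozen=True)
class ConcordanceResult:
    r_w: float  # NaN when weights are degenerate
    category: str | None
    n_clones: int
    weights_degenerate: bool


def clone_weights(x, y) -> np.ndarray:
    """Spatially informed clone weights (length n-1), all >= 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InvalidInputError("x and y must have equal length")
    if len(x) < 3:
        raise InvalidInputError("need at least 3 clones")
    dx = np.abs(x - np.median(x))
    dy = np.abs(y - np.median(y))
    # median of the pair {i, i+1} = midpoint of the two deviations
    return 0.5 * ((dx[:-1] + dx[1:]) / 2.0 + (dy[:-1] + dy[1:]) / 2.0)


def categorize_correlation(r_w: float) -> str:
    """Qualitative bin for a correlation in [-1, 1]."""
    if not -1.0 <= r_w <= 1.0:
        raise InvalidInputError(f"correlation {r_w} outside [-1, 1]")
    if r_w < 0.0:
        return "anticorrelated"
    idx = min(int(r_w / 0.2), 4)
    return CATEGORIES[idx]


def weighted_pearson(x, y) -> ConcordanceResult:
    """Weighted Pearson correlation of two log2-ratio vectors.

    The weighted sums run over observations 1..n-1 (position n carries no
    weight). All-zero weights or a zero weighted variance make the
    correlation undefined: ``r_w`` is NaN, ``weights_degenerate`` is set and
    the category is omitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = clone_weights(x, y)
    xs, ys = x[:-1], y[:-1]
    wsum = w.sum()
    if wsum <= 0.0:
        return ConcordanceResult(float("nan"), None, len(x), True)
    xm = float(np.dot(w, xs) / wsum)
    ym = float(np.dot(w, ys) / wsum)
    cov_xy = float(np.dot(w, (xs - xm) * (ys - ym)) / wsum)
    var_x = float(np.dot(w, (xs - xm) ** 2) / wsum)
    var_y = float(np.dot(w, (ys - ym) ** 2) / wsum)
    if var_x <= 0.0 or var_y <= 0.0:
        return ConcordanceResult(float("nan"), None, len(x), True)
    r = cov_xy / np.sqrt(var_x * var_y)
    r = float(np.clip(r, -1.0, 1.0))
    return ConcordanceResult(r, categorize_correlation(r), len(x), False)


def align_profiles(a: Profile, b: Profile) -> AlignedPair:
    """Shared autosomal clones passing QC in both samples, genome order."""
    sex_chroms = {"X", "Y"}
    da = a.clones[a.clones["qc_pass"]
                  & ~a.clones["chrom"].isin(sex_chroms)]
    db = b.clones[b.clones["qc_pass"]
                  & ~b.clones["chrom"].isin(sex_chroms)]
    merged = da.merge(db, on="clone_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise InvalidInputError(
            f"only {len(merged)} shared autosomal QC-passing clones (need >= 3)"
        )
    return AlignedPair(
        clone_ids=tuple(merged["clone_id"]),
        x=merged["mean_log2_a"].to_numpy(dtype=float),
        y=merged["mean_log2_b"].to_numpy(dtype=float),
    )


def profile_concordance(a: Profile, b: Profile) -> ConcordanceResult:
    """End-to-end pairwise concordance between two profiles."""
    pair = align_profiles(a, b)
    return weighted_pearson(pair.x, pair.y)
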