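"""Five-state copy-number calling with sex-mismatch X baseline adjustment.

Segment means are thresholded into HIGH_GAIN / GAIN / NEUTRAL / LOSS /
HOMOZYGOUS_LOSS. For sex-mismatched hybridizations (e.g. male test DNA
against a female reference) the copy-number-neutral expectation on
chromosome X is log2(1/2) = -1 rather than 0; subtracting this baseline
before thresholding is equivalent to shifting all four thresholds, so a
normal male X is called NEUTRAL instead of a sweep of losses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (InvalidInputError, InvalidParameterError,
                     MissingCoverageError)
from .segmentation import Segment


class CallState(enum.IntEnum):
    """Copy-number states ordered from deepest loss to highest gain."""

    HOMOZYGOUS_LOSS = -2
    LOSS = -1
    NEUTRAL = 0
    GAIN = 1
    HIGH_GAIN = 2

    @property
    def extremity(self) -> int:
        """0 for NEUTRAL, 1 for single-level, 2 for high-level states."""
        return abs(int(self))


@dataclass(frozen=True)
class CallingConfig:
    """Log2-ratio thresholds for the five states (strict inequalities)."""

    gain_thr: float = 0.2
    loss_thr: float = -0.2
    high_gain_thr: float = 0.6
    homdel_thr: float = -0.6
    strict: bool = True

    def __post_init__(self):
        if not (self.homdel_thr < self.loss_thr < 0.0
                < self.gain_thr < self.high_gain_thr):
            raise InvalidParameterError(
                "thresholds must satisfy homdel < loss < 0 < gain < high_gain"
            )


@dataclass(frozen=True)
class CopyNumberCall:
    segment: Segment
    state: CallState
    adjusted_mean: float


@dataclass(frozen=True)
class LocusQuery:
    """A named genomic interval, e.g. the AR locus on Xq."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise InvalidParameterError("locus start > end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def x_baseline(test_sex: str, reference_sex: str) -> float:
    """Copy-number-neutral log2 expectation on chromosome X.

    log2(test X copies / reference X copies): -1 for male vs. female,
    +1 for female vs. male, 0 for matched sexes.
    """
    copies = {"male": 1, "female": 2}
    try:
        return float(np.log2(copies[test_sex] / copies[reference_sex]))
    except KeyError as exc:
        raise InvalidParameterError(f"unknown sex {exc.args[0]!r}") from None


def classify_value(adjusted_mean: float, config: CallingConfig) -> CallState:
    """Map a baseline-adjusted log2 mean to a state (strict thresholds)."""
    if adjusted_mean > config.high_gain_thr:
        return CallState.HIGH_GAIN
    if adjusted_mean > config.gain_thr:
        return CallState.GAIN
    if adjusted_mean < config.homdel_thr:
        return CallState.HOMOZYGOUS_LOSS
    if adjusted_mean < config.loss_thr:
        return CallState.LOSS
    return CallState.NEUTRAL


def call_segments(segments: list[Segment], config: CallingConfig,
                  test_sex: str, reference_sex: str,
                  adjust_x: bool = True) -> list[CopyNumberCall]:
    """Call every segment; X segments are baseline-adjusted before
    thresholding (disable with ``adjust_x=False`` to see the unadjusted
    sex-mismatch artefact). Chromosome Y must have been dropped upstream."""
    baseline = x_baseline(test_sex, reference_sex) if adjust_x else 0.0
    calls = []
    for seg in segments:
        if seg.chromosome == "Y":
            raise InvalidInputError(
                "chromosome Y segments are excluded from calling"
            )
        adj = seg.mean_log2 - (baseline if seg.chromosome == "X" else 0.0)
        calls.append(CopyNumberCall(seg, classify_value(adj, config), adj))
    return calls


def call_locus(calls: list[CopyNumberCall], query: LocusQuery) -> CallState:
    """State at a locus: the segment overlapping the query midpoint, or, when
    the query spans several segments, the most extreme state (high-level
    beats single-level beats neutral; |adjusted mean| breaks gain-vs-loss
    ties)."""
    overlapping = [
        c for c in calls
        if c.segment.chromosome == query.chromosome
        and c.segment.start_bp <= query.end
        and c.segment.end_bp >= query.start
    ]
    if not overlapping:
        raise MissingCoverageError(
            f"no segment covers {query.name} "
            f"({query.chromosome}:{query.start}-{query.end})"
        )
    if len(overlapping) == 1:
        return overlapping[0].state
    return max(
        overlapping,
        key=lambda c: (c.state.extremity, abs(c.adjusted_mean)),
    ).state


def calls_to_frame(calls: list[CopyNumberCall]) -> pd.DataFrame:
    """BED-compatible call table (0-based half-open coordinates)."""
    return pd.DataFrame(
        {
            "chrom": [c.segment.chromosome for c in calls],
            "start": [c.segment.start_bp - 1 for c in calls],
            "end": [c.segment.end_bp for c in calls],
            "state": [c.state.name for c in calls],
            "adjusted_mean": [c.adjusted_mean for c in calls],
            "n_clones": [c.segment.n_clones for c in calls],
        }
    )


def write_calls(calls: list[CopyNumberCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False,
                                 float_format="%.6f")


def read_calls(path) -> list[CopyNumberCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    calls = []
    for r in df.itertuples():
        seg = Segment(str(r.chrom), 0, int(r.n_clones) - 1,
                      int(r.start) + 1, int(r.end),
                      float(r.adjusted_mean), int(r.n_clones))
        calls.append(CopyNumberCall(seg, CallState[r.state],
                                    float(r.adjusted_mean)))
    return calls


def parse_locus(spec_str: str) -> LocusQuery:
    """Parse ``NAME:CHROM:START-END`` (e.g. ``AR:X:66700000-66950000``)."""
    try:
        name, chrom, span = spec_str.split(":")
        start, end = span.split("-")
        return LocusQuery(name, chrom, int(start), int(end))
    except (ValueError, TypeError):
        raise InvalidParameterError(
            f"cannot parse locus {spec_str!r}; expected NAME:CHROM:START-END"
        ) from None
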