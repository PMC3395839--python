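"""Cohort-level recurrence of copy-number aberrations.

Per-sample calls are projected back onto the shared array design (one state
per clone per sample, missing where a clone failed QC), gain/loss
frequencies are computed over non-missing samples, and maximal runs of
clones exceeding the recurrence threshold (default: present in more than
50% of samples) are reported as recurrent regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CallState, CopyNumberCall
from .errors import InvalidInputError, InvalidParameterError
from .preprocess import sort_genome_order
from .synthetic_data import ArrayDesign

#: Recurrence threshold: aberration present in more than this fraction.
DEFAULT_RECURRENCE_THRESHOLD = 0.5

_GAIN_STATES = {CallState.GAIN.name, CallState.HIGH_GAIN.name}
_LOSS_STATES = {CallState.LOSS.name, CallState.HOMOZYGOUS_LOSS.name}


@dataclass
class CohortMatrix:
    """sample x clone grid of call-state names (NaN = missing via QC).

    ``states`` is a DataFrame indexed by sample_id with one column per
    clone_id in design order; ``clone_info`` carries chrom/start/end per
    clone for downstream interval reporting.
    """

    states: pd.DataFrame
    clone_info: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.states.index)


def _assign_states(calls: list[CopyNumberCall],
                   design: ArrayDesign) -> pd.Series:
    """State per design clone for one sample; NaN where no segment covers
    the clone. Calls carrying clone membership assign exactly their member
    clones; calls read back from BED fall back to midpoint containment."""
    out = pd.Series(np.nan, index=[c.id for c in design.clones], dtype=object)
    have_ids = all(c.segment.clone_ids for c in calls)
    if have_ids and calls:
        for call in calls:
            for cid in call.segment.clone_ids:
                out[cid] = call.state.name
        return out
    for clone in design.clones:
        for call in calls:
            seg = call.segment
            if (seg.chromosome == clone.chromosome
                    and seg.start_bp <= clone.midpoint <= seg.end_bp):
                out[clone.id] = call.state.name
                break
    return out


def build_cohort(call_sets: list[tuple[str, list[CopyNumberCall]]],
                 design: ArrayDesign) -> CohortMatrix:
    """Stack per-sample calls into a sample x clone state matrix."""
    if not call_sets:
        raise InvalidInputError("need at least one sample")
    ids = [sid for sid, _ in call_sets]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate sample_id in cohort")
    rows = {sid: _assign_states(calls, design) for sid, calls in call_sets}
    states = pd.DataFrame(rows).T.loc[ids, [c.id for c in design.clones]]
    return CohortMatrix(states=states, clone_info=design.to_frame())


def aberration_frequency(matrix: CohortMatrix) -> pd.DataFrame:
    """Gain/loss frequency per clone over non-missing samples.

    Clones missing in every sample are excluded. Returns a genome-ordered
    DataFrame with columns ``clone_id, chrom, start, end, gain_freq,
    loss_freq, n_samples``.
    """
    states = matrix.states
    if states.empty:
        return pd.DataFrame(columns=["clone_id", "chrom", "start", "end",
                                     "gain_freq", "loss_freq", "n_samples"])
    present = states.notna()
    n_obs = present.sum(axis=0)
    gains = states.isin(_GAIN_STATES).sum(axis=0)
    losses = states.isin(_LOSS_STATES).sum(axis=0)
    keep = n_obs > 0
    with np.errstate(invalid="ignore"):
        track = pd.DataFrame(
            {
                "clone_id": states.columns,
                "gain_freq": (gains / n_obs).to_numpy(),
                "loss_freq": (losses / n_obs).to_numpy(),
                "n_samples": n_obs.to_numpy(),
            }
        )[keep.to_numpy()]
    track = track.merge(matrix.clone_info, on="clone_id", how="left")
    track = sort_genome_order(track)
    return track[["clone_id", "chrom", "start", "end",
                  "gain_freq", "loss_freq", "n_samples"]]


def recurrent_regions(track: pd.DataFrame,
                      threshold: float = DEFAULT_RECURRENCE_THRESHOLD
                      ) -> pd.DataFrame:
    """Maximal runs of consecutive clones with frequency strictly above
    ``threshold``, per direction.

    Returns a DataFrame with columns ``chrom, start_bp, end_bp, n_clones,
    direction`` (direction in {gain, loss}), clone-resolution bounds.
    """
    if not 0.0 <= threshold < 1.0:
        raise InvalidParameterError("threshold must be in [0, 1)")
    regions = []
    for direction, col in (("gain", "gain_freq"), ("loss", "loss_freq")):
        for chrom, sub in track.groupby("chrom", sort=False):
            sub = sub.reset_index(drop=True)
            hot = (sub[col] > threshold).to_numpy()
            edges = np.flatnonzero(np.diff(np.r_[0, hot.astype(int), 0]))
            for a, b in zip(edges[::2], edges[1::2]):
                regions.append(
                    (chrom, int(sub["start"].iloc[a]),
                     int(sub["end"].iloc[b - 1]), int(b - a), direction)
                )
    df = pd.DataFrame(regions, columns=["chrom", "start_bp", "end_bp",
                                        "n_clones", "direction"])
    if len(df):
        df["start"] = df["start_bp"]
        df = sort_genome_order(df).drop(columns="start")
    return df.reset_index(drop=True)


def write_frequency_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_regions(regions: pd.DataFrame, path) -> None:
    out = regions.copy()
    if len(out):
        out["start_bp"] = out["start_bp"] - 1  # BED 0-based half-open
    out.to_csv(path, sep="\t", index=False)
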