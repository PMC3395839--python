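"""Replicate-spot summarization, QC filtering, and profile I/O.

A spot table (one row per printed spot) is reduced to one mean and sample
standard deviation per clone; clones whose replicate SD exceeds the QC cutoff
(default 0.2) are flagged and skipped by all downstream stages, and
chromosome Y is dropped before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EmptyProfileError, InvalidParameterError, MissingDataError
from .synthetic_data import ArrayDesign, chromosome_rank

#: Replicate-SD cutoff above which a clone is excluded from analysis.
DEFAULT_SD_MAX = 0.2

PROFILE_COLUMNS = ["clone_id", "chrom", "start", "end", "mean_log2",
                   "sd_log2", "n_spots", "qc_pass"]


@dataclass
class Profile:
    """Per-sample ordered clone summaries.

    ``clones`` is a DataFrame with columns ``clone_id, chrom, start, end,
    mean_log2, sd_log2, n_spots, qc_pass`` sorted in genome order.
    """

    sample_id: str
    test_sex: str
    reference_sex: str
    clones: pd.DataFrame

    def passing(self) -> pd.DataFrame:
        """QC-passing clones only."""
        return self.clones[self.clones["qc_pass"]].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        df = self.clones.copy()
        df["qc_pass"] = df["qc_pass"].astype(int)
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, sample_id: str = "sample",
                 test_sex: str = "male",
                 reference_sex: str = "female") -> "Profile":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["qc_pass"] = df["qc_pass"].astype(bool)
        return cls(sample_id, test_sex, reference_sex, df[PROFILE_COLUMNS])


def summarize_replicates(spots: pd.DataFrame, design: ArrayDesign,
                         sample_id: str = "sample",
                         test_sex: str = "male",
                         reference_sex: str = "female") -> Profile:
    """Mean and sample SD (n-1 denominator) of log2 ratios per clone.

    Every clone of the design must appear in the spot table; clones with a
    single spot get sd_log2 = 0. Clones are emitted in genome order with
    qc_pass initialized to True (apply :func:`qc_filter` next).
    """
    grouped = spots.groupby("clone_id")["log2_ratio"]
    means = grouped.mean()
    sds = grouped.std(ddof=1).fillna(0.0)
    counts = grouped.size()
    rows = []
    missing = [c.id for c in design.clones if c.id not in means.index]
    if missing:
        raise MissingDataError(
            f"no spots for clone(s): {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    for clone in design.clones:
        rows.append(
            (clone.id, clone.chromosome, clone.start, clone.end,
             float(means[clone.id]), float(sds[clone.id]),
             int(counts[clone.id]), True)
        )
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return Profile(sample_id, test_sex, reference_sex, df)


def qc_filter(profile: Profile, sd_max: float = DEFAULT_SD_MAX) -> Profile:
    """Flag clones with replicate SD strictly greater than ``sd_max``.

    Clones are flagged, never removed, so concordance can later intersect
    QC-passing clones across samples. Idempotent.
    """
    if sd_max < 0:
        raise InvalidParameterError("sd_max must be >= 0")
    df = profile.clones.copy()
    df["qc_pass"] = df["sd_log2"] <= sd_max
    if not df["qc_pass"].any():
        raise EmptyProfileError(
            f"all {len(df)} clones fail QC at sd_max={sd_max}"
        )
    return replace(profile, clones=df)


def drop_chromosome(profile: Profile, name: str = "Y") -> Profile:
    """Remove all clones on the named chromosome (no-op if absent)."""
    df = profile.clones[profile.clones["chrom"] != name].reset_index(drop=True)
    return replace(profile, clones=df)


def sort_genome_order(df: pd.DataFrame) -> pd.DataFrame:
    """Stable sort of a clone table by (chromosome order, start)."""
    rank = df["chrom"].map(chromosome_rank)
    order = np.lexsort((df["start"].to_numpy(), rank.to_numpy()))
    return df.iloc[order].reset_index(drop=True)
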