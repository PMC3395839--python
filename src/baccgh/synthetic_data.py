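"""Synthetic BAC-array CGH data generation.

Emulates a genome-wide BAC array (default 2,464 clones printed in triplicate)
hybridized in a sex-mismatched design (male test vs. female reference), with
integer copy-number ground truth, leukocyte-contamination attenuation of the
log2 ratios, clone- and spot-level Gaussian noise, and occasional outlier
spots. Every downstream stage of the pipeline is testable against the ground
truth carried by :class:`TruthProfile`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

#: Canonical chromosome ordering used throughout the package.
CHROMOSOME_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_RANK = {name: i for i, name in enumerate(CHROMOSOME_ORDER)}

# Approximate human chromosome lengths (bp). Only relative sizes matter for
# clone placement and segmentation; no particular genome build is implied.
_CHROM_LENGTHS = {
    "1": 249_250_000, "2": 243_199_000, "3": 198_022_000, "4": 191_154_000,
    "5": 180_915_000, "6": 171_115_000, "7": 159_138_000, "8": 146_364_000,
    "9": 141_213_000, "10": 135_534_000, "11": 135_006_000, "12": 133_851_000,
    "13": 115_169_000, "14": 107_349_000, "15": 102_531_000, "16": 90_354_000,
    "17": 81_195_000, "18": 78_077_000, "19": 59_128_000, "20": 63_025_000,
    "21": 48_129_000, "22": 51_304_000, "X": 155_270_000, "Y": 59_373_000,
}

#: Default number of clones on the array.
DEFAULT_N_CLONES = 2464

#: Nominal BAC insert size used for clone intervals (bp).
_CLONE_WIDTH = 150_000


def chromosome_rank(name: str) -> int:
    """Position of a chromosome in canonical genome order."""
    try:
        return _CHROM_RANK[str(name)]
    except KeyError:
        raise InvalidParameterError(f"unknown chromosome {name!r}") from None


@dataclass(frozen=True)
class GenomeModel:
    """Coordinate space: ordered (chromosome name, length in bp) pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidParameterError("chromosome names must be unique")
        if "X" not in names:
            raise InvalidParameterError("chromosome X must be present")
        if any(length <= 0 for _, length in self.chromosomes):
            raise InvalidParameterError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]


def make_genome_model(include_y: bool = True) -> GenomeModel:
    """Built-in human genome model: 22 autosomes + X, optionally + Y."""
    names = CHROMOSOME_ORDER if include_y else CHROMOSOME_ORDER[:-1]
    return GenomeModel(tuple((c, _CHROM_LENGTHS[c]) for c in names))


@dataclass(frozen=True)
class Clone:
    """A BAC probe: a genomic interval measured in replicate spots.

    Coordinates are 1-based inclusive.
    """

    id: str
    chromosome: str
    start: int
    end: int
    replicate_count: int = 3

    def __post_init__(self):
        if self.start > self.end:
            raise InvalidParameterError(f"clone {self.id}: start > end")
        if self.replicate_count < 1:
            raise InvalidParameterError(f"clone {self.id}: replicate_count < 1")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ArrayDesign:
    """Ordered BAC probes; `clones` is sorted by (chromosome order, start)."""

    clones: list[Clone]

    def __post_init__(self):
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("clone ids must be unique")
        key = [(chromosome_rank(c.chromosome), c.start) for c in self.clones]
        if key != sorted(key):
            raise InvalidParameterError("clones must be sorted in genome order")

    def __len__(self) -> int:
        return len(self.clones)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": [c.id for c in self.clones],
                "chrom": [c.chromosome for c in self.clones],
                "start": [c.start for c in self.clones],
                "end": [c.end for c in self.clones],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, replicate_count: int = 3) -> "ArrayDesign":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        clones = [
            Clone(str(r.clone_id), str(r.chrom), int(r.start), int(r.end),
                  replicate_count)
            for r in df.itertuples()
        ]
        return cls(clones)


def generate_array_design(
    genome: GenomeModel, n_clones: int = DEFAULT_N_CLONES, seed: int = 0
) -> ArrayDesign:
    """Lay out ``n_clones`` probes across the genome.

    Clones are allocated to chromosomes proportionally to length (largest
    remainder, at least one per chromosome) and placed at evenly spaced
    midpoints. Placement is deterministic; ``seed`` is accepted for interface
    stability.
    """
    n_chrom = len(genome.chromosomes)
    if n_clones < n_chrom:
        raise InvalidParameterError(
            f"n_clones={n_clones} < chromosome count {n_chrom}"
        )
    lengths = np.array([length for _, length in genome.chromosomes], dtype=float)
    quota = n_clones * lengths / lengths.sum()
    counts = np.maximum(np.floor(quota).astype(int), 1)
    # largest-remainder top-up / trim to hit n_clones exactly
    while counts.sum() < n_clones:
        counts[np.argmax(quota - counts)] += 1
    while counts.sum() > n_clones:
        order = np.argsort(quota - counts)
        for k in order[::-1]:
            if counts[k] > 1:
                counts[k] -= 1
                break
    clones: list[Clone] = []
    for (name, length), count in zip(genome.chromosomes, counts):
        mids = (np.arange(count) + 0.5) / count * length
        for k, mid in enumerate(mids):
            start = max(1, int(mid) - _CLONE_WIDTH // 2)
            end = min(length, start + _CLONE_WIDTH - 1)
            clones.append(Clone(f"BAC_{name}_{k + 1:04d}", name, start, end))
    return ArrayDesign(clones)


@dataclass(frozen=True)
class Aberration:
    """A ground-truth copy-number interval (1-based inclusive)."""

    chromosome: str
    start: int
    end: int
    tumor_copy_number: int

    def __post_init__(self):
        if self.start > self.end:
            raise InvalidParameterError("aberration start > end")
        if self.tumor_copy_number < 0:
            raise InvalidParameterError("tumor copy number must be >= 0")


@dataclass
class TruthProfile:
    """Ground truth: sample sexes, aberrations, and tumor purity.

    ``tumor_fraction`` is the proportion of tumor-derived DNA; admixed normal
    (leukocyte) DNA pulls the measured log2 ratio toward the normal-cell
    baseline, dampening the dynamic range.
    """

    test_sex: str = "male"
    reference_sex: str = "female"
    aberrations: list[Aberration] = field(default_factory=list)
    tumor_fraction: float = 1.0

    def __post_init__(self):
        for sex in (self.test_sex, self.reference_sex):
            if sex not in ("male", "female"):
                raise InvalidParameterError(f"unknown sex {sex!r}")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise InvalidParameterError("tumor_fraction must be in [0, 1]")
        by_chrom: dict[str, list[Aberration]] = {}
        for ab in self.aberrations:
            by_chrom.setdefault(ab.chromosome, []).append(ab)
        for chrom, abs_ in by_chrom.items():
            abs_.sort(key=lambda a: a.start)
            for a, b in zip(abs_, abs_[1:]):
                if b.start <= a.end:
                    raise InvalidParameterError(
                        f"overlapping aberrations on chromosome {chrom}"
                    )

    def copy_number_at(self, chromosome: str, position: float) -> int | None:
        """Tumor copy number of the aberration containing ``position``, else None."""
        for ab in self.aberrations:
            if ab.chromosome == chromosome and ab.start <= position <= ab.end:
                return ab.tumor_copy_number
        return None


@dataclass(frozen=True)
class NoiseParams:
    """Measurement model for the array.

    sigma_clone : SD of a per-clone offset shared by its replicate spots
                  (probe-specific bias, e.g. WGA representation differences).
    sigma_spot  : SD of independent per-spot noise.
    outlier_prob: probability a spot receives an additional outlier deviation.
    outlier_sigma: SD of that outlier deviation; large values push the
                  triplicate SD past the QC cutoff, exercising the filter.
    floor_copies: small positive copy number used in place of 0 so a
                  homozygous deletion maps to a deep finite ratio (array
                  dynamic-range floor) rather than -inf.
    """

    sigma_clone: float = 0.08
    sigma_spot: float = 0.05
    outlier_prob: float = 0.01
    outlier_sigma: float = 1.0
    floor_copies: float = 0.05

    def __post_init__(self):
        if min(self.sigma_clone, self.sigma_spot, self.outlier_sigma) < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise InvalidParameterError("outlier_prob must be in [0, 1]")
        if self.floor_copies <= 0:
            raise InvalidParameterError("floor_copies must be > 0")

    @classmethod
    def from_json(cls, path) -> "NoiseParams":
        with open(path) as fh:
            raw = json.load(fh)
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise InvalidParameterError(f"unknown noise keys: {sorted(unknown)}")
        return cls(**raw)


ZERO_NOISE = NoiseParams(sigma_clone=0.0, sigma_spot=0.0, outlier_prob=0.0,
                         outlier_sigma=0.0, floor_copies=0.05)


def _germline_copies(chromosome: str, sex: str) -> int:
    if chromosome == "X":
        return 1 if sex == "male" else 2
    if chromosome == "Y":
        return 1 if sex == "male" else 0
    return 2


def expected_log2(clone: Clone, truth: TruthProfile,
                  noise: NoiseParams = ZERO_NOISE) -> float:
    """Noise-free log2 ratio for one clone under the mixture model.

    The hybridized test DNA is a mixture of tumor cells at copy number ``c``
    and contaminating normal cells at germline copy number ``g``::

        mix = tf * c + (1 - tf) * g
        log2 ratio = log2(max(mix, floor) / max(r, floor))

    with ``r`` the reference germline copy number. At tumor_fraction 0 the
    ratio is the pure sex-mismatch baseline (0 on autosomes, -1 on X for a
    male test against a female reference).
    """
    g = _germline_copies(clone.chromosome, truth.test_sex)
    r = _germline_copies(clone.chromosome, truth.reference_sex)
    c = truth.copy_number_at(clone.chromosome, clone.midpoint)
    if c is None:
        c = g
    tf = truth.tumor_fraction
    mix = tf * c + (1.0 - tf) * g
    return float(np.log2(max(mix, noise.floor_copies)
                         / max(r, noise.floor_copies)))


def expected_log2_vector(design: ArrayDesign, truth: TruthProfile,
                         noise: NoiseParams = ZERO_NOISE) -> np.ndarray:
    """``expected_log2`` for every clone of a design, in design order."""
    return np.array([expected_log2(c, truth, noise) for c in design.clones])


def simulate_spot_table(
    design: ArrayDesign,
    truth: TruthProfile,
    noise: NoiseParams,
    seed: int,
) -> pd.DataFrame:
    """Draw a spot-level log2-ratio table.

    For each clone one clone-offset ~ N(0, sigma_clone^2) is drawn, then each
    of its ``replicate_count`` spots adds independent N(0, sigma_spot^2)
    noise, and with probability ``outlier_prob`` an extra N(0, outlier_sigma^2)
    outlier deviation. Byte-identical output under a fixed seed.

    Returns a DataFrame with columns ``clone_id, replicate, log2_ratio``
    (replicate indices 1-based).
    """
    rng = np.random.default_rng(seed)
    mu = expected_log2_vector(design, truth, noise)
    reps = np.array([c.replicate_count for c in design.clones])
    clone_offset = rng.normal(0.0, noise.sigma_clone, size=len(design))
    n_rows = int(reps.sum())
    per_clone_mu = np.repeat(mu + clone_offset, reps)
    values = per_clone_mu + rng.normal(0.0, noise.sigma_spot, size=n_rows)
    is_outlier = rng.random(n_rows) < noise.outlier_prob
    values = values + is_outlier * rng.normal(0.0, noise.outlier_sigma,
                                              size=n_rows)
    return pd.DataFrame(
        {
            "clone_id": np.repeat([c.id for c in design.clones], reps),
            "replicate": np.concatenate([np.arange(1, r + 1) for r in reps]),
            "log2_ratio": values,
        }
    )


def write_spot_table(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_spot_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# Fixed truth presets. Copy-number landscapes follow the well-characterized
# aberrations of the prostate lines they are named after (8p loss / 8q gain
# common to all; high-level X gain over the AR region in the VCaP-like and
# patient-like profiles; PTEN-region 10q loss in the PC3-like profile; 11q13
# focal amplification in the patient-like profile). All presets are male test
# vs. female reference at tumor_fraction 1.
_PRESETS: dict[str, list[Aberration]] = {
    "vcap_like": [
        Aberration("8", 1, 43_000_000, 1),
        Aberration("8", 48_000_000, 146_364_000, 4),
        Aberration("X", 63_000_000, 70_000_000, 8),
    ],
    "pc3_like": [
        Aberration("8", 1, 40_000_000, 1),
        Aberration("8", 50_000_000, 146_364_000, 4),
        Aberration("10", 60_000_000, 135_534_000, 1),
    ],
    "lncap_like": [
        Aberration("6", 62_000_000, 171_115_000, 1),
        Aberration("10", 85_000_000, 95_000_000, 1),
        Aberration("13", 40_000_000, 115_169_000, 1),
    ],
    "patient9_like": [
        Aberration("8", 1, 43_000_000, 1),
        Aberration("8", 48_000_000, 146_364_000, 3),
        Aberration("11", 67_500_000, 72_500_000, 6),
        Aberration("X", 63_000_000, 70_000_000, 8),
    ],
    "normal_male_leukocyte": [],
}

#: Androgen receptor region on Xq used by the presets and the default query.
AR_LOCUS = ("X", 66_700_000, 66_950_000)


def preset_truth(name: str, tumor_fraction: float = 1.0) -> TruthProfile:
    """A fixed, documented truth profile by name.

    Valid names: ``vcap_like, pc3_like, lncap_like, patient9_like,
    normal_male_leukocyte``.
    """
    if name not in _PRESETS:
        raise InvalidParameterError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    return TruthProfile(
        test_sex="male",
        reference_sex="female",
        aberrations=list(_PRESETS[name]),
        tumor_fraction=tumor_fraction,
    )


def truth_states(design: ArrayDesign, truth: TruthProfile,
                 noise: NoiseParams = ZERO_NOISE,
                 calling_config=None) -> pd.Series:
    """Per-clone ground-truth call state (chromosome Y excluded).

    The truth state of a clone is the state its noise-free, sex-baseline-
    adjusted log2 ratio maps to under the calling thresholds, so a perfect
    pipeline run reproduces it exactly.
    """
    from .calling import CallingConfig, classify_value, x_baseline

    config = calling_config or CallingConfig()
    baseline = x_baseline(truth.test_sex, truth.reference_sex)
    out = {}
    for clone in design.clones:
        if clone.chromosome == "Y":
            continue
        value = expected_log2(clone, truth, noise)
        if clone.chromosome == "X":
            value -= baseline
        out[clone.id] = classify_value(value, config).name
    return pd.Series(out, name="state")
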