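"""Conditional information profiles and their segmentation.

Profiling a target ``x`` against a model trained on a reference ``y``
yields one code length per target position: the number of bits needed to
represent that symbol using exclusively information from the reference.
Stretches that share information with the reference drop far below the
2-bit ceiling of the 4-symbol alphabet; novel or unsequenced (randomised)
stretches stay near it.  Regions of interest are maximal runs where a
smoothed version of the profile falls below a threshold T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcm import FCModel, context_codes
from .sequence_io import Sequence, _intervals_from_mask

DIRECT = "direct"
INVERTED = "inverted"

#: code length assigned to the first k positions, which lack a full
#: context: the uniform-model fallback of 2 bits.
NO_CONTEXT_BITS = 2.0


@dataclass
class InformationProfile:
    """Per-position code lengths (bits) of a target under one model."""

    values: np.ndarray
    source_target: str = ""
    source_model: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SegmentationParams:
    """Parameters of the smooth-and-threshold segmentation.

    threshold:
        T, in bits; positions with smoothed information strictly below T
        are low-information.  Admissible range [0, 2] (alphabet ceiling).
    window:
        Length of the centred moving-average smoothing window, in
        positions.
    min_block:
        Minimum reported region length; shorter matched runs are
        discarded (default 20 kb).
    merge_gap:
        Below-threshold runs separated by a gap of at most this many
        positions are merged before length filtering.
    """

    threshold: float = 1.5
    window: int = 1000
    min_block: int = 20000
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 2.0):
            raise ValueError(f"threshold must be in [0,2] bits, got {self.threshold}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.min_block < 1:
            raise ValueError(f"min_block must be >= 1, got {self.min_block}")
        if self.merge_gap < 0:
            raise ValueError(f"merge_gap must be >= 0, got {self.merge_gap}")


@dataclass
class Region:
    """A half-open interval on a named sequence, with orientation."""

    sequence_name: str
    start: int
    end: int
    orientation: str = DIRECT
    mean_bits: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start},{self.end})")
        if self.orientation not in (DIRECT, INVERTED):
            raise ValueError(f"orientation must be direct|inverted, got {self.orientation}")

    @property
    def length(self) -> int:
        return self.end - self.start


def information_profile(model: FCModel, x: Sequence) -> InformationProfile:
    """Code length of every target symbol under the reference model.

    Positions ``i < k`` have no full context and get the 2-bit uniform
    fallback, so the profile always has exactly ``len(x)`` values.
    """
    codes = x.codes()
    k = model.k
    values = np.full(len(codes), NO_CONTEXT_BITS, dtype=np.float64)
    ctx, sym = context_codes(codes, k)
    if len(ctx):
        values[k:] = model.code_lengths(ctx, sym)
    return InformationProfile(
        values=values,
        source_target=x.name,
        source_model={
            "reference_name": model.reference_name,
            "k": model.k,
            "alpha": model.alpha,
        },
    )


def smooth(profile: InformationProfile, window: int) -> InformationProfile:
    """Centred moving average, window truncated at the boundaries.

    Position i averages values[i-(w-1)//2 : i+w//2+1] clipped to the
    array; constant profiles are fixed points and window 1 is the
    identity.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    v = profile.values
    n = len(v)
    if window == 1 or n == 0:
        out = v.copy()
    else:
        left = (window - 1) // 2
        right = window // 2
        csum = np.concatenate(([0.0], np.cumsum(v)))
        idx = np.arange(n)
        lo = np.maximum(idx - left, 0)
        hi = np.minimum(idx + right + 1, n)
        out = (csum[hi] - csum[lo]) / (hi - lo)
    meta = dict(profile.source_model)
    meta["smoothing_window"] = window
    return InformationProfile(out, profile.source_target, meta)


def segment(
    smoothed: InformationProfile,
    params: SegmentationParams,
    orientation: str = DIRECT,
) -> list[Region]:
    """Maximal runs of positions with smoothed information < T.

    Runs separated by gaps of at most ``merge_gap`` are merged; runs
    shorter than ``min_block`` are discarded.  Each returned region
    carries the mean smoothed information inside it.
    """
    v = smoothed.values
    below = v < params.threshold
    runs = _intervals_from_mask(below)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    name = smoothed.source_target
    return [
        Region(name, s, e, orientation, mean_bits=float(v[s:e].mean()))
        for s, e in merged
        if e - s >= params.min_block
    ]


def write_profile_tsv(profile: InformationProfile, path: str) -> None:
    """Two-column TSV (0-based position, bits) for external inspection."""
    with open(path, "w") as fh:
        fh.write("position\tbits\n")
        for i, b in enumerate(profile.values):
            fh.write(f"{i}\t{b:.6g}\n")


def write_profile_wig(profile: InformationProfile, path: str, span: int = 1) -> None:
    """Fixed-step wiggle text (1-based, as genome browsers expect)."""
    with open(path, "w") as fh:
        fh.write(
            f"fixedStep chrom={profile.source_target or 'seq'} start=1 step={span} span={span}\n"
        )
        for b in profile.values[::span]:
            fh.write(f"{b:.6g}\n")
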