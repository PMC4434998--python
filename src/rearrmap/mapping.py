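"""Two-sided rearrangement mapping between a reference and a target.

The procedure runs in two passes.  Forward pass: the target is profiled
against a model of the reference (direct orientation) and against a model
of the reverse-complemented reference (inverted orientation); each
smoothed profile is segmented into low-information regions.  A position
low in exactly one orientation keeps it; low in both, the whole disputed
run goes to the orientation with smaller mean smoothed information; high
in both, the position is left unmarked (unique or unsequenced sequence).
Localisation pass: each surviving target region is in turn treated as a
reference — a model is trained on it (reverse-complemented first for
inverted regions) and the original reference is profiled and segmented
against it, yielding the associated reference region(s).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .fcm import DEFAULT_ALPHA, train_fcm
from .profile import (
    DIRECT,
    INVERTED,
    InformationProfile,
    Region,
    SegmentationParams,
    information_profile,
    segment,
    smooth,
)
from .sequence_io import Sequence, reverse_complement

logger = logging.getLogger("rearrmap")

_MAP_VERSION = 1


@dataclass
class RegionPair:
    """One target region and the reference region(s) it shares
    information with, drawn in the same hue."""

    target_region: Region
    reference_regions: list[Region]
    orientation: str
    colour_hue: float = 0.0


@dataclass
class RearrangementMap:
    """The complete result of one run: all pairs plus the parameter
    record needed to reproduce it."""

    reference_name: str
    target_name: str
    reference_length: int
    target_length: int
    pairs: list[RegionPair] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _target_profiles(
    y: Sequence, x: Sequence, k: int, params: SegmentationParams, alpha: float
) -> tuple[InformationProfile, InformationProfile]:
    """Smoothed profiles of x under the direct and inverted models of y."""
    sm_d = smooth(information_profile(train_fcm(y, k, alpha), x), params.window)
    model_i = train_fcm(reverse_complement(y), k, alpha)
    sm_i = smooth(information_profile(model_i, x), params.window)
    sm_i.source_model["orientation"] = INVERTED
    sm_d.source_model["orientation"] = DIRECT
    return sm_d, sm_i


def find_target_regions(
    y: Sequence,
    x: Sequence,
    k: int,
    params: SegmentationParams,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[Region], list[Region]]:
    """Segment the target in both orientations against the reference."""
    sm_d, sm_i = _target_profiles(y, x, k, params, alpha)
    return segment(sm_d, params, DIRECT), segment(sm_i, params, INVERTED)


def _coverage(regions: list[Region], n: int) -> np.ndarray:
    cov = np.zeros(n, dtype=bool)
    for r in regions:
        cov[r.start : r.end] = True
    return cov


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(diff == 1).tolist(), np.flatnonzero(diff == -1).tolist()))


def resolve_overlaps(
    direct: list[Region],
    inverted: list[Region],
    smoothed_direct: InformationProfile,
    smoothed_inverted: InformationProfile,
    params: SegmentationParams,
) -> list[Region]:
    """Merge the two orientation scans into disjoint oriented regions.

    Positions covered by exactly one scan keep that orientation.  For a
    run covered by both, the orientation with the smaller mean smoothed
    information over the run wins (ties go to direct).  Positions in
    neither scan stay unmarked.  The result is re-filtered by
    ``min_block``.
    """
    n = len(smoothed_direct.values)
    cov_d = _coverage(direct, n)
    cov_i = _coverage(inverted, n)
    orient = np.zeros(n, dtype=np.int8)
    orient[cov_d & ~cov_i] = 1
    orient[cov_i & ~cov_d] = 2
    for s, e in _runs(cov_d & cov_i):
        md = smoothed_direct.values[s:e].mean()
        mi = smoothed_inverted.values[s:e].mean()
        orient[s:e] = 1 if md <= mi else 2
    name = smoothed_direct.source_target
    out: list[Region] = []
    for code, tag, prof in ((1, DIRECT, smoothed_direct), (2, INVERTED, smoothed_inverted)):
        for s, e in _runs(orient == code):
            if e - s >= params.min_block:
                out.append(Region(name, s, e, tag, float(prof.values[s:e].mean())))
    out.sort(key=lambda r: r.start)
    return out


def locate_in_reference(
    region: Region,
    x: Sequence,
    y: Sequence,
    k: int,
    params: SegmentationParams,
    alpha: float = DEFAULT_ALPHA,
) -> list[Region]:
    """Find the reference region(s) associated with one target region.

    The target region now plays the reference role: a model is trained on
    x[region] (reverse-complemented first when the region is inverted)
    and y is profiled and segmented against it, with the same parameters
    as the forward pass.
    """
    sub = Sequence(name=f"{x.name}:{region.start}-{region.end}",
                   symbols=x.symbols[region.start : region.end])
    if region.orientation == INVERTED:
        sub = reverse_complement(sub)
    model = train_fcm(sub, k, alpha)
    sm = smooth(information_profile(model, y), params.window)
    return segment(sm, params, region.orientation)


def build_map(
    y: Sequence,
    x: Sequence,
    k: int,
    params: SegmentationParams,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 1,
    include_inverted: bool = True,
) -> RearrangementMap:
    """Run the full pipeline and assemble the rearrangement map.

    Hues are spread uniformly around the HSV circle in target-position
    order.  A target region whose localisation in the reference comes
    back empty (asymmetric threshold effects) is dropped with a warning.
    With ``include_inverted=False`` the reverse-complement pass is
    skipped and only direct homologies are reported.
    """
    from .viz import assign_hues  # local import to avoid cycle

    if include_inverted:
        sm_d, sm_i = _target_profiles(y, x, k, params, alpha)
    else:
        sm_d = smooth(information_profile(train_fcm(y, k, alpha), x), params.window)
        # a flat 2-bit profile: nothing is ever low in the inverted sense
        sm_i = InformationProfile(np.full(len(x), 2.0), x.name,
                                  {"orientation": INVERTED, "skipped": True})
    direct = segment(sm_d, params, DIRECT)
    inverted = segment(sm_i, params, INVERTED)
    resolved = resolve_overlaps(direct, inverted, sm_d, sm_i, params)

    pairs: list[RegionPair] = []
    for region in resolved:
        refs = locate_in_reference(region, x, y, k, params, alpha)
        if not refs:
            logger.warning(
                "target region [%d,%d) %s: no reference region found; pair dropped",
                region.start, region.end, region.orientation,
            )
            continue
        pairs.append(RegionPair(region, refs, region.orientation))

    for pair, hue in zip(pairs, assign_hues(len(pairs))):
        pair.colour_hue = hue

    return RearrangementMap(
        reference_name=y.name,
        target_name=x.name,
        reference_length=len(y),
        target_length=len(x),
        pairs=pairs,
        params={
            "k": k,
            "alpha": alpha,
            "threshold": params.threshold,
            "window": params.window,
            "min_block": params.min_block,
            "merge_gap": params.merge_gap,
            "seed": seed,
        },
    )


# -- export / import ---------------------------------------------------------


def _region_dict(r: Region) -> dict:
    return {
        "sequence_name": r.sequence_name,
        "start": r.start,
        "end": r.end,
        "orientation": r.orientation,
        "mean_bits": r.mean_bits,
    }


def map_to_dict(m: RearrangementMap) -> dict:
    return {
        "format": "rearrmap-map",
        "version": _MAP_VERSION,
        "reference_name": m.reference_name,
        "target_name": m.target_name,
        "reference_length": m.reference_length,
        "target_length": m.target_length,
        "params": m.params,
        "pairs": [
            {
                "target_region": _region_dict(p.target_region),
                "reference_regions": [_region_dict(r) for r in p.reference_regions],
                "orientation": p.orientation,
                "colour_hue": p.colour_hue,
            }
            for p in m.pairs
        ],
    }


def write_map_json(m: RearrangementMap, path: str) -> None:
    """The unit of reproducibility: the full map including parameters."""
    with open(path, "w") as fh:
        json.dump(map_to_dict(m), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _region_from_dict(d: dict) -> Region:
    return Region(d["sequence_name"], d["start"], d["end"], d["orientation"], d["mean_bits"])


def read_map_json(path: str) -> RearrangementMap:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "rearrmap-map" or doc.get("version") != _MAP_VERSION:
        raise ValueError(f"{path}: not a version-{_MAP_VERSION} map file")
    pairs = [
        RegionPair(
            _region_from_dict(p["target_region"]),
            [_region_from_dict(r) for r in p["reference_regions"]],
            p["orientation"],
            p["colour_hue"],
        )
        for p in doc["pairs"]
    ]
    return RearrangementMap(
        doc["reference_name"], doc["target_name"],
        doc["reference_length"], doc["target_length"],
        pairs, doc["params"],
    )


def write_map_bed(m: RearrangementMap, target_path: str, reference_path: str) -> None:
    """BED-like 6-column TSVs, one file per side.

    Columns: chrom, start, end, pair id, mean_bits, strand (inverted
    regions get "-").  Coordinates are 0-based half-open as in BED.
    """
    def strand(r: Region) -> str:
        return "-" if r.orientation == INVERTED else "+"

    with open(target_path, "w") as fh:
        for i, p in enumerate(m.pairs):
            r = p.target_region
            fh.write(f"{r.sequence_name}\t{r.start}\t{r.end}\tpair{i}\t{r.mean_bits!r}\t{strand(r)}\n")
    with open(reference_path, "w") as fh:
        for i, p in enumerate(m.pairs):
            for r in p.reference_regions:
                fh.write(f"{r.sequence_name}\t{r.start}\t{r.end}\tpair{i}\t{r.mean_bits!r}\t{strand(r)}\n")
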