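"""Marker selection and binning.

Reliable markers are the unambiguously biallelic (heterozygous-in-pool)
positions: the alternative-allele frequency in the control (wild-type)
pool must sit inside a window around 0.5 and the control-pool depth
inside a sequencing-depth window.  Only the control pool is consulted —
the mutant pool is the signal being tested and may legitimately be
fixed near the causal locus.

Binning pools the allele counts of runs of consecutive markers, turning
per-marker counts into a proxy for local haplotype frequencies and
boosting the count support (hence test power) per data point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, MarkerTrack

#: control-pool selection defaults
DEFAULT_FREQ_MIN = 0.15
DEFAULT_FREQ_MAX = 0.85
DEFAULT_DEPTH_MIN = 20
DEFAULT_DEPTH_MAX = 120
DEFAULT_BIN_SIZE = 10


@dataclass(frozen=True)
class Bin:
    """``bin_size`` consecutive markers with their allele counts pooled."""

    chrom: str
    start_pos: int
    end_pos: int
    representative_pos: int
    wt_ref: int
    wt_alt: int
    mut_ref: int
    mut_alt: int
    size: int


def select_markers(
    track: MarkerTrack,
    freq_min: float = DEFAULT_FREQ_MIN,
    freq_max: float = DEFAULT_FREQ_MAX,
    depth_min: int = DEFAULT_DEPTH_MIN,
    depth_max: int = DEFAULT_DEPTH_MAX,
) -> MarkerTrack:
    """Keep markers passing the control-pool frequency/depth windows.

    Bounds are inclusive.  Markers with zero control-pool depth never
    pass (their frequency is undefined).
    """
    if not (0 <= freq_min < freq_max <= 1):
        raise ValueError(f"need 0 <= freq_min < freq_max <= 1, got {freq_min}, {freq_max}")
    if not (0 < depth_min <= depth_max):
        raise ValueError(f"need 0 < depth_min <= depth_max, got {depth_min}, {depth_max}")
    depth = track.wt_depth
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, track.wt_alt / np.maximum(depth, 1), np.nan)
    keep = (
        (depth >= depth_min)
        & (depth <= depth_max)
        & (freq >= freq_min)
        & (freq <= freq_max)
    )
    return track.take(keep)


def bin_markers(track: MarkerTrack, bin_size: int = DEFAULT_BIN_SIZE) -> list[Bin]:
    """Pool counts over non-overlapping runs of ``bin_size`` markers.

    Exactly ``floor(n / bin_size)`` bins are produced; a trailing
    remainder shorter than ``bin_size`` is discarded so every bin has
    the same marker support.  The representative position is the
    ceil(bin_size/2)-th member's position, matching window anchoring.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    n = len(track)
    n_bins = n // bin_size
    mid = -(-bin_size // 2) - 1  # 0-based index of the ceil(k/2)-th member
    bins: list[Bin] = []
    for b in range(n_bins):
        i, j = b * bin_size, (b + 1) * bin_size
        bins.append(
            Bin(
                chrom=track.chrom,
                start_pos=int(track.pos[i]),
                end_pos=int(track.pos[j - 1]),
                representative_pos=int(track.pos[i + mid]),
                wt_ref=int(track.wt_ref[i:j].sum()),
                wt_alt=int(track.wt_alt[i:j].sum()),
                mut_ref=int(track.mut_ref[i:j].sum()),
                mut_alt=int(track.mut_alt[i:j].sum()),
                size=bin_size,
            )
        )
    return bins


def binned_track(track: MarkerTrack, bin_size: int = DEFAULT_BIN_SIZE) -> MarkerTrack:
    """Binned counts repackaged as a MarkerTrack for the downstream scan.

    Each bin keeps the ref/alt bases of its representative marker (the
    bases are irrelevant to the count-based statistics).
    """
    if bin_size == 1:
        return track
    bins = bin_markers(track, bin_size)
    if not bins:
        return track.take(np.zeros(len(track), dtype=bool))
    mid = -(-bin_size // 2) - 1
    rep_idx = np.array([b * bin_size + mid for b in range(len(bins))])
    return MarkerTrack(
        track.chrom,
        np.array([b.representative_pos for b in bins]),
        track.ref[rep_idx],
        track.alt[rep_idx],
        np.array([b.wt_ref for b in bins]),
        np.array([b.wt_alt for b in bins]),
        np.array([b.mut_ref for b in bins]),
        np.array([b.mut_alt for b in bins]),
    )
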