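"""Binned metaprofiles around anchors and over scaled feature bodies.

Three flavours cover the figures the analysis draws:

* ``feature_count_profile`` — mean number of features (e.g. TEs) overlapping
  each 50-bp bin in a +/-2 kb window around peak centers.
* ``signal_profile`` — mean per-base signal (ATAC coverage, conservation
  score) in the same window layout.
* ``scaled_body_profile`` — feature bodies rescaled to a fixed number of
  bins with fixed-width flanks, for TE-body methylation metaplots.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Acr, GenomicInterval

logger = logging.getLogger("teacr")


@dataclass
class Profile:
    bin_edges: np.ndarray  # offsets in bp relative to the anchor
    values: np.ndarray     # per-bin mean signal / count
    n_anchors: int
    normalization: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values must have one entry per bin")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "value": self.values,
                "n": self.n_anchors,
            }
        )


def anchor_center(feature) -> tuple[str, int]:
    """Anchor point: the summit for peaks that carry one, else the midpoint."""
    if isinstance(feature, Acr):
        return feature.interval.chrom, feature.summit
    return feature.chrom, feature.midpoint


def feature_count_profile(
    anchors, features, flank: int = 2000, bin_size: int = 50
) -> Profile:
    """Per-bin count of features overlapping the bin, averaged over anchors
    ("normalized feature number")."""
    if (2 * flank) % bin_size:
        raise ValueError("bin size must divide the window")
    anchors = list(anchors)
    if not anchors:
        raise ValueError("no anchors supplied")
    edges = np.arange(-flank, flank + bin_size, bin_size)
    n_bins = len(edges) - 1
    # per-chrom sorted starts/ends allow overlap counting by two searches:
    # #overlapping [a,b) = #(start < b) - #(end <= a)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    feats = list(features)
    for chrom in {f.chrom for f in feats}:
        sub = [f for f in feats if f.chrom == chrom]
        by_chrom[chrom] = (
            np.sort([f.start for f in sub]),
            np.sort([f.end for f in sub]),
        )
    totals = np.zeros(n_bins)
    for anchor in anchors:
        chrom, center = anchor_center(anchor)
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends = entry
        bin_starts = center + edges[:-1]
        bin_ends = center + edges[1:]
        totals += np.searchsorted(starts, bin_ends, side="left") - np.searchsorted(
            ends, bin_starts, side="right"
        )
    return Profile(edges, totals / len(anchors), len(anchors), "per_anchor_mean")


def signal_profile(
    anchors,
    signal: dict[str, np.ndarray],
    flank: int = 2000,
    bin_size: int = 50,
) -> Profile:
    """Mean per-base signal in fixed bins around anchor centers.

    Bins truncated by a chromosome edge contribute only their covered bp.
    NaN positions in the arrays count as unscored and are skipped (build
    score tracks with ``fill=nan`` to distinguish "no score" from 0, and
    coverage tracks with ``fill=0``); a bin with no scored bp reports NaN.
    """
    if (2 * flank) % bin_size:
        raise ValueError("bin size must divide the window")
    edges = np.arange(-flank, flank + bin_size, bin_size)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    anchors = list(anchors)
    for anchor in anchors:
        chrom, center = anchor_center(anchor)
        arr = signal.get(chrom)
        if arr is None:
            continue
        lo, hi = center - flank, center + flank
        window = np.full(2 * flank, np.nan)
        src_lo, src_hi = max(0, lo), min(len(arr), hi)
        if src_hi > src_lo:
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        window = window.reshape(n_bins, bin_size)
        valid = ~np.isnan(window)
        sums += np.where(valid, window, 0.0).sum(axis=1)
        counts += valid.sum(axis=1)
    values = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    return Profile(edges, values, len(anchors), "per_bp_mean")


def scaled_body_profile(
    features,
    signal: dict[str, np.ndarray],
    flank: int = 2000,
    body_bins: int = 40,
    flank_bin: int = 50,
    skip_nan: bool = True,
) -> Profile:
    """Metaplot over features with bodies rescaled to ``body_bins`` bins.

    Flanks use fixed ``flank_bin``-bp bins; minus-strand features are
    reversed so the left flank is always biologically upstream. Features
    shorter than ``body_bins`` bp are excluded (logged). In the returned
    edges the body occupies [0, body_bins*flank_bin) pseudo-bp.
    """
    if flank % flank_bin:
        raise ValueError("flank bin size must divide the flank")
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    body_span = body_bins * flank_bin  # pseudo-bp for plotting
    edges = np.concatenate(
        [
            np.arange(-flank, 0, flank_bin, dtype=float),
            np.linspace(0, body_span, body_bins + 1),
            body_span + np.arange(flank_bin, flank + flank_bin, flank_bin, dtype=float),
        ]
    )
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    n_used = 0
    n_short = 0
    for feat in features:
        iv = feat if isinstance(feat, GenomicInterval) else feat.interval
        if iv.length < body_bins:
            n_short += 1
            continue
        arr = signal.get(iv.chrom)
        if arr is None:
            continue
        n_used += 1
        bin_vals = np.full(n_bins, np.nan)
        # flanks
        left = np.full(flank, np.nan)
        lo = max(0, iv.start - flank)
        if iv.start > 0:
            left[lo - (iv.start - flank) :] = arr[lo : iv.start]
        right = np.full(flank, np.nan)
        hi = min(len(arr), iv.end + flank)
        if hi > iv.end:
            right[: hi - iv.end] = arr[iv.end : hi]
        body = arr[iv.start : iv.end].astype(float)
        # body rescale: equal-fraction index boundaries
        bounds = np.floor(np.arange(body_bins + 1) * iv.length / body_bins).astype(int)
        body_means = np.array(
            [
                np.nanmean(body[bounds[i] : bounds[i + 1]])
                if np.any(~np.isnan(body[bounds[i] : bounds[i + 1]]))
                else np.nan
                for i in range(body_bins)
            ]
        )
        left_means = _fixed_bin_means(left, flank_bin)
        right_means = _fixed_bin_means(right, flank_bin)
        bin_vals[:n_flank] = left_means
        bin_vals[n_flank : n_flank + body_bins] = body_means
        bin_vals[n_flank + body_bins :] = right_means
        if iv.strand == "-":
            bin_vals = bin_vals[::-1]
        valid = ~np.isnan(bin_vals)
        sums[valid] += bin_vals[valid]
        counts[valid] += 1
    if n_short:
        logger.info("scaled_body_profile: excluded %d features shorter than %d bp",
                    n_short, body_bins)
    values = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    return Profile(edges, values, n_used, "scaled_body_mean")


def _fixed_bin_means(arr: np.ndarray, bin_size: int) -> np.ndarray:
    mat = arr.reshape(-1, bin_size)
    with np.errstate(invalid="ignore"):
        out = np.full(mat.shape[0], np.nan)
        any_valid = np.any(~np.isnan(mat), axis=1)
        out[any_valid] = np.nanmean(mat[any_valid], axis=1)
    return out


def plot_profile(profile: Profile, path: str, title: str = "") -> None:
    """Minimal TSV-companion rendering of a profile curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(centers, profile.values)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(profile.normalization)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
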