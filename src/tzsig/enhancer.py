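"""Enhancer-level ChIP-signal ratio analysis.

High-confidence peaks (MACS −log10 p strictly above a threshold, default 9)
are assigned to genes whose TSS lies within a window (default 150 kb,
inclusive, distance measured TSS to peak midpoint).  Per peak, the log2
ratio of the mean normalized track signal between the resistant (A) and
sensitive (B) conditions is computed, and per gene × mark the median of
those ratios summarizes the local chromatin shift.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, Peak, SignalTrack, FormatError

log = logging.getLogger("tzsig")


@dataclass
class EnhancerConfig:
    """Peak filtering and gene-assignment parameters.

    p_threshold_neglog10 = 9 keeps peaks with p < 1e-9 (strict);
    window_bp is the TSS-to-midpoint distance cutoff (inclusive);
    signal_pseudocount guards log ratios against zero-coverage peaks.
    """

    p_threshold_neglog10: float = 9.0
    window_bp: int = 150_000
    signal_pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.signal_pseudocount <= 0:
            raise ValueError("signal_pseudocount must be positive")


@dataclass
class EnhancerGeneSummary:
    gene_id: str
    mark: str
    peak_ratios: list
    median_log2_ratio: float


def normalize_track(track: SignalTrack) -> SignalTrack:
    """Divide every value by the length-weighted mean over all covered
    bases, so the output track has length-weighted mean 1."""
    mean = track.weighted_mean()
    if mean <= 0:
        raise FormatError("cannot normalize a track with non-positive mean signal")
    return track.scale(1.0 / mean)


def track_mean(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Length-weighted mean track value over [start, end); uncovered bases
    contribute zero signal but full weight."""
    if start >= end:
        raise ValueError("empty interval")
    if chrom not in track.chroms:
        return 0.0
    starts, ends, values = track.chroms[chrom]
    i = np.searchsorted(ends, start, side="right")
    j = np.searchsorted(starts, end, side="left")
    if i >= j:
        return 0.0
    ov = np.minimum(ends[i:j], end) - np.maximum(starts[i:j], start)
    return float((ov * values[i:j]).sum() / (end - start))


def attach_signals(peaks: list[Peak], track_a: SignalTrack,
                   track_b: SignalTrack) -> list[Peak]:
    """Fill each peak's per-condition signal with the mean track value over
    the peak interval (A = resistant, B = sensitive)."""
    return [
        Peak(chrom=p.chrom, start=p.start, end=p.end, mark=p.mark,
             neg_log10_p=p.neg_log10_p,
             signal_a=track_mean(track_a, p.chrom, p.start, p.end),
             signal_b=track_mean(track_b, p.chrom, p.start, p.end))
        for p in peaks
    ]


def filter_peaks(peaks: list[Peak], cfg: EnhancerConfig) -> list[Peak]:
    """Keep high-confidence peaks: −log10(p) strictly above the threshold."""
    return [p for p in peaks if p.neg_log10_p > cfg.p_threshold_neglog10]


def assign_peaks(peaks: list[Peak], annotation: GeneAnnotation,
                 gene_ids, cfg: EnhancerConfig) -> dict:
    """Map each requested gene to the peaks within the TSS window.

    A peak is assigned iff it lies on the gene's chromosome and
    |midpoint − TSS| <= window_bp (inclusive).  A peak may be assigned to
    several genes.
    """
    missing = [g for g in gene_ids if g not in annotation]
    if missing:
        raise FormatError(f"gene id(s) absent from annotation: {missing}")

    by_chrom: dict[str, tuple[list[int], list[Peak]]] = {}
    for p in sorted(peaks, key=lambda p: (p.chrom, p.midpoint, p.start)):
        mids, plist = by_chrom.setdefault(p.chrom, ([], []))
        mids.append(p.midpoint)
        plist.append(p)

    out: dict[str, list[Peak]] = {}
    for g in gene_ids:
        row = annotation.table.loc[g]
        chrom, tss = row["chrom"], int(row["tss"])
        mids, plist = by_chrom.get(chrom, ([], []))
        lo = bisect.bisect_left(mids, tss - cfg.window_bp)
        hi = bisect.bisect_right(mids, tss + cfg.window_bp)
        out[g] = plist[lo:hi]
    return out


def peak_log2_ratio(peak: Peak, cfg: EnhancerConfig) -> float:
    """log2((signal_A + pc) / (signal_B + pc)), resistant over sensitive."""
    if peak.signal_a is None or peak.signal_b is None:
        raise ValueError(f"peak {peak.chrom}:{peak.start}-{peak.end} has no signals attached")
    return float(np.log2((peak.signal_a + cfg.signal_pseudocount)
                         / (peak.signal_b + cfg.signal_pseudocount)))


def summarize_gene(gene_id: str, mark: str, assigned_peaks: list[Peak],
                   cfg: EnhancerConfig):
    """Median per-peak log2 ratio for one gene and one mark.

    Peaks of other marks are excluded.  With zero matching peaks the
    summary is omitted (None) with a logged notice — never NaN.
    """
    ratios = [peak_log2_ratio(p, cfg) for p in assigned_peaks if p.mark == mark]
    if not ratios:
        log.info("gene %s: no %s peaks in window; summary omitted", gene_id, mark)
        return None
    return EnhancerGeneSummary(
        gene_id=gene_id, mark=mark, peak_ratios=ratios,
        median_log2_ratio=float(np.median(ratios)),
    )


def summarize_all(assigned: dict, marks, cfg: EnhancerConfig) -> pd.DataFrame:
    """Per gene × mark summary table: gene_id, mark, n_peaks, median_log2_ratio."""
    rows = []
    for gene_id, peaks in assigned.items():
        for mark in marks:
            s = summarize_gene(gene_id, mark, peaks, cfg)
            if s is not None:
                rows.append((s.gene_id, s.mark, len(s.peak_ratios), s.median_log2_ratio))
    return pd.DataFrame(rows, columns=["gene_id", "mark", "n_peaks", "median_log2_ratio"])


def peak_table(assigned: dict, cfg: EnhancerConfig) -> pd.DataFrame:
    """Long-format per-peak table behind the dot plot: one row per
    (gene, assigned peak) with its log2 ratio."""
    rows = []
    for gene_id, peaks in assigned.items():
        for p in peaks:
            rows.append((gene_id, p.mark, p.chrom, p.start, p.end,
                         peak_log2_ratio(p, cfg)))
    return pd.DataFrame(rows, columns=["gene_id", "mark", "chrom", "start", "end",
                                       "log2_ratio"])
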