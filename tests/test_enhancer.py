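import numpy as np
import pandas as pd
import pytest

from tzsig import (
    EnhancerConfig, GeneAnnotation, Peak, SignalTrack, FormatError,
    normalize_track, track_mean, attach_signals, filter_peaks, assign_peaks,
    peak_log2_ratio, summarize_gene, summarize_all,
)


def track(chrom="chr1", ivs=((0, 10, 4.0),)):
    t = SignalTrack()
    starts, ends, values = zip(*ivs)
    t.add_chrom(chrom, starts, ends, values)
    return t


def annotation(genes):
    # genes: {gene_id: (chrom, tss)}
    return GeneAnnotation(table=pd.DataFrame(
        {"chrom": [v[0] for v in genes.values()],
         "tss": [v[1] for v in genes.values()],
         "strand": "+", "biotype": "mRNA"},
        index=pd.Index(list(genes), name="gene_id")))


# -- normalization -----------------------------------------------------------

def test_normalize_single_interval():
    out = normalize_track(track(ivs=[(0, 10, 4.0)]))
    assert list(out.chroms["chr1"][2]) == [1.0]


def test_normalize_length_weighted():
    out = normalize_track(track(ivs=[(0, 10, 1.0), (10, 20, 3.0)]))
    np.testing.assert_allclose(out.chroms["chr1"][2], [0.5, 1.5])


def test_normalize_zero_track_rejected():
    with pytest.raises(FormatError, match="normalize"):
        normalize_track(track(ivs=[(0, 10, 0.0)]))


def test_normalized_mean_is_one(rng):
    for _ in range(20):
        n = int(rng.integers(1, 30))
        bounds = np.sort(rng.choice(10_000, size=2 * n, replace=False))
        ivs = [(int(bounds[2 * i]), int(bounds[2 * i + 1]),
                float(rng.uniform(0.1, 9))) for i in range(n)]
        out = normalize_track(track(ivs=ivs))
        assert out.weighted_mean() == pytest.approx(1.0, rel=1e-12)


def test_track_mean_counts_uncovered_bases_as_zero():
    t = track(ivs=[(0, 10, 2.0)])
    # half the query interval is uncovered
    assert track_mean(t, "chr1", 0, 20) == pytest.approx(1.0)
    assert track_mean(t, "chr2", 0, 20) == 0.0


# -- filtering ---------------------------------------------------------------

def test_filter_is_strict_at_threshold():
    cfg = EnhancerConfig()
    peaks = [Peak("chr1", 0, 10, "H3K27ac", 12.0),
             Peak("chr1", 20, 30, "H3K27ac", 9.0)]
    kept = filter_peaks(peaks, cfg)
    assert [p.neg_log10_p for p in kept] == [12.0]
    assert filter_peaks([], cfg) == []


def test_filter_threshold_zero_keeps_positive_scores():
    cfg = EnhancerConfig(p_threshold_neglog10=0.0)
    peaks = [Peak("chr1", 0, 10, "H3K27ac", 0.0),
             Peak("chr1", 20, 30, "H3K27ac", 0.5)]
    assert [p.neg_log10_p for p in filter_peaks(peaks, cfg)] == [0.5]


# -- assignment --------------------------------------------------------------

def test_assign_window_boundary_inclusive():
    ann = annotation({"g": ("chr1", 500_000)})
    peak = Peak("chr1", 640_000, 660_000, "H3K27ac", 20.0)  # midpoint 650,000
    out = assign_peaks([peak], ann, ["g"], EnhancerConfig())
    assert out["g"] == [peak]  # distance exactly 150,000


def test_assign_requires_same_chromosome():
    ann = annotation({"g": ("chr1", 500_000)})
    peak = Peak("chr2", 500_000, 500_100, "H3K27ac", 20.0)
    assert assign_peaks([peak], ann, ["g"], EnhancerConfig())["g"] == []


def test_assign_unknown_gene_named_in_error():
    ann = annotation({"g": ("chr1", 500_000)})
    with pytest.raises(FormatError, match="ghost"):
        assign_peaks([], ann, ["ghost"], EnhancerConfig())


def brute_force_assign(peaks, ann, gene_ids, cfg):
    out = {}
    for g in gene_ids:
        chrom, tss = ann.table.loc[g, "chrom"], int(ann.table.loc[g, "tss"])
        out[g] = [p for p in peaks
                  if p.chrom == chrom and abs(p.midpoint - tss) <= cfg.window_bp]
    return out


def test_assign_matches_all_pairs_scan(rng):
    cfg = EnhancerConfig(window_bp=50_000)
    for _ in range(25):
        chroms = ["c1", "c2"]
        genes = {f"g{i}": (chroms[int(rng.integers(2))],
                           int(rng.integers(0, 1_000_000)))
                 for i in range(int(rng.integers(1, 15)))}
        ann = annotation(genes)
        peaks = []
        for _ in range(int(rng.integers(0, 60))):
            s = int(rng.integers(0, 1_000_000))
            peaks.append(Peak(chroms[int(rng.integers(2))], s,
                              s + int(rng.integers(1, 5_000)), "H3K27ac",
                              float(rng.uniform(0, 40))))
        fast = assign_peaks(peaks, ann, list(genes), cfg)
        slow = brute_force_assign(peaks, ann, list(genes), cfg)
        for g in genes:
            key = lambda p: (p.chrom, p.start, p.end)
            assert sorted(fast[g], key=key) == sorted(slow[g], key=key)


# -- ratios and summaries ----------------------------------------------------

def test_peak_log2_ratio_and_antisymmetry():
    cfg = EnhancerConfig(signal_pseudocount=1e-300)
    fwd = Peak("chr1", 0, 10, "H3K27ac", 20.0, signal_a=4.0, signal_b=1.0)
    rev = Peak("chr1", 0, 10, "H3K27ac", 20.0, signal_a=1.0, signal_b=4.0)
    assert peak_log2_ratio(fwd, cfg) == pytest.approx(2.0)
    assert peak_log2_ratio(rev, cfg) == pytest.approx(-2.0)
    same = Peak("chr1", 0, 10, "H3K27ac", 20.0, signal_a=3.0, signal_b=3.0)
    assert peak_log2_ratio(same, EnhancerConfig()) == 0.0


def make_peaks(ratios, mark="H3K27ac"):
    cfg = EnhancerConfig(signal_pseudocount=1e-300)
    return [Peak("chr1", i * 100, i * 100 + 10, mark, 20.0,
                 signal_a=2.0 ** r, signal_b=1.0) for i, r in enumerate(ratios)], cfg


@pytest.mark.parametrize("ratios,expected", [
    ([1.0, 2.0, 3.0], 2.0),
    ([1.0, 3.0], 2.0),   # even count: mean of middles
    ([5.0], 5.0),
])
def test_summarize_median(ratios, expected):
    peaks, cfg = make_peaks(ratios)
    s = summarize_gene("g", "H3K27ac", peaks, cfg)
    assert s.median_log2_ratio == pytest.approx(expected)
    np.testing.assert_allclose(s.peak_ratios, ratios)


def test_summarize_excludes_other_marks_and_omits_empty():
    peaks, cfg = make_peaks([1.0, 9.0])
    peaks[1].mark = "H3K4me1"
    s = summarize_gene("g", "H3K27ac", peaks, cfg)
    assert s.peak_ratios == [pytest.approx(1.0)]
    assert summarize_gene("g", "H3K27ac", [peaks[1]], cfg) is None
    df = summarize_all({"g": [peaks[1]]}, ["H3K27ac"], cfg)
    assert df.empty and not df["median_log2_ratio"].isna().any()


def test_common_scaling_cancels_after_normalization():
    ivs = [(0, 100, 2.0), (100, 300, 6.0), (400, 500, 1.0)]
    a, b = track(ivs=ivs), track(ivs=[(s, e, v * 1.7) for s, e, v in ivs])
    peaks = [Peak("chr1", 50, 150, "H3K27ac", 20.0)]
    cfg = EnhancerConfig()
    base = attach_signals(peaks, normalize_track(a), normalize_track(b))
    scaled = attach_signals(peaks, normalize_track(a.scale(13.0)),
                            normalize_track(b.scale(0.2)))
    assert peak_log2_ratio(base[0], cfg) == \
           pytest.approx(peak_log2_ratio(scaled[0], cfg), rel=1e-12)
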