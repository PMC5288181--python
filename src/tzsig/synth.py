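"""Synthetic study generator with planted ground truth.

Emulates the full input bundle of the resistance-signature analysis on one
synthetic chromosome:

* a tumor cohort of 11 trastuzumab responders (TzS) vs 2 non-responders
  (TzR), so the in-vivo comparison runs in the fold-change-only regime;
* paired TzS/TzR cell-line replicates sharing a per-pair batch offset, so
  a paired t-test has something to gain over an unpaired one;
* a mock vs 48-h-treated short-term contrast on sensitive cells;
* per-mark (H3K4me1, H3K27ac) peak sets and bedGraph signal tracks where
  peaks near planted signature genes carry a resistant-condition shift.

FPKM values are lognormal: 2^(baseline + planted effect · condition +
Normal(0, noise_sigma)), the standard approximation for FPKM noise.
lincRNA baselines are drawn lower than mRNA baselines so both gating
thresholds are exercised.  One seed yields one bundle, byte-identical on
disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix, GeneAnnotation, Peak, SignalTrack, MARKS,
    write_expression, write_annotation, write_peaks, write_bedgraph,
)
from .signature import SignatureSet

CONDITIONS = ("resistant", "sensitive")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic bundle.

    Cohort sizes mirror the clinical design (11 responders vs 2
    non-responders) and a 3-pair isogenic cell-line design.  Planted gene
    sets are mutually disjoint; `planted_log2fc` is the magnitude, signs
    are drawn per gene (concordant genes share their sign between the
    tumor and cell-line datasets).
    """

    n_genes: int = 2000
    frac_lincrna: float = 0.15
    n_responders: int = 11
    n_nonresponders: int = 2
    n_cellline_pairs: int = 3
    n_shortterm_pairs: int = 3
    n_concordant: int = 30
    n_invivo_only: int = 20
    n_invitro_only: int = 20
    n_shortterm: int = 15
    planted_log2fc: float = 2.0
    baseline_log2_fpkm_mean: float = 5.0
    baseline_log2_fpkm_sd: float = 2.0
    lincrna_baseline_shift: float = -2.0
    noise_sigma: float = 0.2
    batch_sigma: float = 0.3
    # chromatin side
    chrom: str = "chrS"
    chrom_length: int = 0  # 0 -> derived from gene spacing
    gene_spacing: int = 400_000
    peaks_per_gene: int = 8
    peak_width: int = 1_000
    peak_signal_shift: float = 2.0
    peak_noise_sigma: float = 0.1
    peak_height_log2_mean: float = 6.0
    peak_height_log2_sd: float = 0.5
    track_baseline: float = 1.0
    n_enhancer_background_genes: int = 30
    n_background_peaks: int = 40
    seed: int = 1

    def __post_init__(self) -> None:
        planted = (self.n_concordant + self.n_invivo_only
                   + self.n_invitro_only + self.n_shortterm)
        if planted > self.n_genes:
            raise ValueError("planted set counts exceed n_genes")
        if self.chrom_length == 0:
            self.chrom_length = self.gene_spacing * (self.n_genes + 1)
        if self.gene_spacing < 2 * 150_000 + self.peak_width:
            raise ValueError("gene_spacing too small: enhancer windows would overlap")


@dataclass
class GroundTruth:
    """Planted memberships per gene and planted shift factors per peak."""

    genes: pd.DataFrame  # index gene_id; biotype, concordant, invivo_only,
    #                      invitro_only, shortterm, direction, enhancer_background
    peak_shift: dict = field(default_factory=dict)  # mark -> np.ndarray

    @property
    def concordant_ids(self) -> list:
        return list(self.genes.index[self.genes["concordant"]])

    @property
    def enhancer_background_ids(self) -> list:
        return list(self.genes.index[self.genes["enhancer_background"]])


@dataclass
class SimBundle:
    tumor: ExpressionMatrix
    cellline: ExpressionMatrix
    shortterm: ExpressionMatrix
    annotation: GeneAnnotation
    peaks: dict  # mark -> list[Peak]; signal_a resistant, signal_b sensitive
    tracks: dict  # (mark, condition) -> SignalTrack
    truth: GroundTruth


def _expression(rng, cfg: SimConfig, gene_ids, biotype, baseline,
                effect, groups, dataset: str, pair_of=None) -> ExpressionMatrix:
    """One FPKM matrix: log2 FPKM = baseline + effect·1[group B] + noise."""
    samples, conditions = [], []
    is_b = []
    for name, cond, b in groups:
        samples.append(name)
        conditions.append(cond)
        is_b.append(b)
    is_b = np.asarray(is_b, dtype=float)
    log2 = (baseline[:, None] + effect[:, None] * is_b[None, :]
            + rng.normal(0.0, cfg.noise_sigma, size=(len(gene_ids), len(samples))))
    if pair_of is not None:
        offsets = rng.normal(0.0, cfg.batch_sigma, size=len(set(pair_of)))
        pair_index = {p: i for i, p in enumerate(sorted(set(pair_of)))}
        log2 = log2 + offsets[[pair_index[p] for p in pair_of]][None, :]
    values = pd.DataFrame(np.exp2(log2), index=gene_ids, columns=samples)
    sheet = pd.DataFrame({
        "dataset": dataset,
        "condition": conditions,
        "pair_id": pair_of if pair_of is not None else [pd.NA] * len(samples),
    }, index=pd.Index(samples, name="sample"))
    return ExpressionMatrix(values=values, biotype=biotype, sample_sheet=sheet)


def simulate_bundle(cfg: SimConfig) -> SimBundle:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    # biotypes and baselines -------------------------------------------------
    n_linc = int(round(cfg.frac_lincrna * n))
    is_linc = np.zeros(n, dtype=bool)
    is_linc[rng.choice(n, size=n_linc, replace=False)] = True
    biotype = pd.Series(np.where(is_linc, "lincRNA", "mRNA"), index=gene_ids,
                        name="biotype")
    baseline = rng.normal(cfg.baseline_log2_fpkm_mean, cfg.baseline_log2_fpkm_sd, n)
    baseline = baseline + cfg.lincrna_baseline_shift * is_linc

    # planted, mutually disjoint gene sets ----------------------------------
    counts = [cfg.n_concordant, cfg.n_invivo_only, cfg.n_invitro_only, cfg.n_shortterm]
    picked = rng.choice(n, size=sum(counts), replace=False)
    splits = np.split(picked, np.cumsum(counts)[:-1])
    concordant, invivo_only, invitro_only, shortterm = (np.sort(s) for s in splits)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[picked] = True

    sign = np.zeros(n)
    for idx in (concordant, invivo_only, invitro_only, shortterm):
        sign[idx] = rng.choice([-1.0, 1.0], size=len(idx))

    eff_tumor = np.zeros(n)
    eff_tumor[concordant] = sign[concordant] * cfg.planted_log2fc
    eff_tumor[invivo_only] = sign[invivo_only] * cfg.planted_log2fc
    eff_cell = np.zeros(n)
    eff_cell[concordant] = sign[concordant] * cfg.planted_log2fc
    eff_cell[invitro_only] = sign[invitro_only] * cfg.planted_log2fc
    eff_short = np.zeros(n)
    eff_short[shortterm] = sign[shortterm] * cfg.planted_log2fc

    # expression matrices ----------------------------------------------------
    tumor_groups = (
        [(f"R{i + 1:02d}", "TzS", 0) for i in range(cfg.n_responders)]
        + [(f"N{i + 1:02d}", "TzR", 1) for i in range(cfg.n_nonresponders)]
    )
    tumor = _expression(rng, cfg, gene_ids, biotype, baseline, eff_tumor,
                        tumor_groups, "tumor")

    cell_groups, cell_pairs = [], []
    for i in range(cfg.n_cellline_pairs):
        cell_groups.append((f"TzS-p{i + 1}", "TzS", 0))
        cell_pairs.append(f"p{i + 1}")
    for i in range(cfg.n_cellline_pairs):
        cell_groups.append((f"TzR-p{i + 1}", "TzR", 1))
        cell_pairs.append(f"p{i + 1}")
    cellline = _expression(rng, cfg, gene_ids, biotype, baseline, eff_cell,
                           cell_groups, "cellline", pair_of=cell_pairs)

    short_groups, short_pairs = [], []
    for i in range(cfg.n_shortterm_pairs):
        short_groups.append((f"mock-p{i + 1}", "mock", 0))
        short_pairs.append(f"p{i + 1}")
    for i in range(cfg.n_shortterm_pairs):
        short_groups.append((f"tz48h-p{i + 1}", "treated48h", 1))
        short_pairs.append(f"p{i + 1}")
    shortterm_m = _expression(rng, cfg, gene_ids, biotype, baseline, eff_short,
                              short_groups, "shortterm", pair_of=short_pairs)

    # annotation: evenly spaced TSSs on one synthetic chromosome -------------
    tss = (np.arange(n) + 1) * cfg.gene_spacing
    strand = rng.choice(["+", "-"], size=n)
    annotation = GeneAnnotation(table=pd.DataFrame({
        "chrom": cfg.chrom, "tss": tss, "strand": strand,
        "biotype": biotype.to_numpy(),
    }, index=gene_ids))

    # enhancer gene panel: planted concordant + clean background genes -------
    unplanted = np.flatnonzero(~planted_mask)
    background = np.sort(rng.choice(
        unplanted, size=min(cfg.n_enhancer_background_genes, len(unplanted)),
        replace=False))
    panel = np.concatenate([concordant, background])
    panel_shift = np.concatenate([
        np.full(len(concordant), cfg.peak_signal_shift),
        np.ones(len(background)),
    ])

    peaks: dict[str, list[Peak]] = {}
    tracks: dict[tuple, SignalTrack] = {}
    peak_shift: dict[str, np.ndarray] = {}
    gap_choices = rng.choice(n - 1, size=min(cfg.n_background_peaks, n - 1),
                             replace=False)
    for mark in MARKS:
        mark_peaks, shifts = _simulate_mark(rng, cfg, tss, panel, panel_shift,
                                            gap_choices, mark)
        peaks[mark] = mark_peaks
        peak_shift[mark] = shifts
        tracks[(mark, "resistant")] = _track_from_peaks(cfg, mark_peaks, "a")
        tracks[(mark, "sensitive")] = _track_from_peaks(cfg, mark_peaks, "b")

    truth_genes = pd.DataFrame({
        "biotype": biotype.to_numpy(),
        "concordant": np.isin(np.arange(n), concordant),
        "invivo_only": np.isin(np.arange(n), invivo_only),
        "invitro_only": np.isin(np.arange(n), invitro_only),
        "shortterm": np.isin(np.arange(n), shortterm),
        "direction": np.where(sign > 0, "up", np.where(sign < 0, "down", "none")),
        "enhancer_background": np.isin(np.arange(n), background),
    }, index=gene_ids)

    return SimBundle(
        tumor=tumor, cellline=cellline, shortterm=shortterm_m,
        annotation=annotation, peaks=peaks, tracks=tracks,
        truth=GroundTruth(genes=truth_genes, peak_shift=peak_shift),
    )


def _simulate_mark(rng, cfg: SimConfig, tss, panel, panel_shift, gap_choices,
                   mark: str):
    """Peaks for one mark: high-confidence peaks in non-overlapping slots
    within ±120 kb of each panel TSS, one sub-threshold peak per panel gene,
    and unshifted background peaks in intergenic gaps."""
    reach = 120_000
    slot_w = 2 * reach // cfg.peaks_per_gene
    jitter = max(slot_w // 2 - cfg.peak_width, 0)
    half_w = cfg.peak_width // 2

    mids, shifts, neglogp = [], [], []
    for g, sh in zip(panel, panel_shift):
        t = int(tss[g])
        for j in range(cfg.peaks_per_gene):
            center = t - reach + j * slot_w + slot_w // 2
            mids.append(center + int(rng.integers(-jitter, jitter + 1)))
            shifts.append(sh)
            neglogp.append(float(rng.uniform(10.0, 50.0)))
        # one low-confidence peak inside the 150-kb window but outside slots
        mids.append(t - reach - 5_000)
        shifts.append(1.0)
        neglogp.append(float(rng.uniform(1.0, 8.0)))
    for gi in gap_choices:
        center = int(tss[gi]) + cfg.gene_spacing // 2
        mids.append(center + int(rng.integers(-10_000, 10_001)))
        shifts.append(1.0)
        neglogp.append(float(rng.uniform(10.0, 50.0)))

    height = np.exp2(rng.normal(cfg.peak_height_log2_mean,
                                cfg.peak_height_log2_sd, len(mids)))
    noise_a = np.exp2(rng.normal(0.0, cfg.peak_noise_sigma, len(mids)))
    noise_b = np.exp2(rng.normal(0.0, cfg.peak_noise_sigma, len(mids)))
    shifts = np.asarray(shifts)
    sig_a = height * shifts * noise_a
    sig_b = height * noise_b

    order = np.argsort(mids)
    out = []
    for k in order:
        s = mids[k] - half_w
        out.append(Peak(chrom=cfg.chrom, start=s, end=s + cfg.peak_width,
                        mark=mark, neg_log10_p=neglogp[k],
                        signal_a=float(sig_a[k]), signal_b=float(sig_b[k])))
    return out, shifts[order]


def _track_from_peaks(cfg: SimConfig, peaks, which: str) -> SignalTrack:
    """Piecewise-constant coverage: peak values over peak intervals, the
    baseline level everywhere else on the chromosome."""
    starts, ends, values = [], [], []
    prev = 0
    for p in peaks:
        if p.start > prev:
            starts.append(prev)
            ends.append(p.start)
            values.append(cfg.track_baseline)
        starts.append(p.start)
        ends.append(p.end)
        values.append(p.signal_a if which == "a" else p.signal_b)
        prev = p.end
    if prev < cfg.chrom_length:
        starts.append(prev)
        ends.append(cfg.chrom_length)
        values.append(cfg.track_baseline)
    track = SignalTrack()
    track.add_chrom(cfg.chrom, starts, ends, values)
    return track


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------

def truth_report(truth: GroundTruth, called: SignatureSet) -> dict:
    """Confusion summary of a called signature against the planted
    concordant set, overall and per biotype."""
    genes = truth.genes
    called_ids = called.gene_ids

    def _score(sub: pd.DataFrame) -> dict:
        pos = set(sub.index[sub["concordant"]])
        neg = set(sub.index) - pos
        cal = called_ids & set(sub.index)
        tp = len(pos & cal)
        fp = len(cal - pos)
        fn = len(pos - cal)
        tn = len(neg - cal)
        return {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": tp / len(pos) if pos else float("nan"),
            "specificity": tn / len(neg) if neg else float("nan"),
            "fdr": fp / len(cal) if cal else 0.0,
        }

    report = {"overall": _score(genes)}
    for bt, sub in genes.groupby("biotype"):
        report[bt] = _score(sub)
    return report


# ---------------------------------------------------------------------------
# bundle serialization (the formats io_formats reads back)
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "tumor": ("tumor_fpkm.tsv", "tumor_samples.tsv"),
    "cellline": ("cellline_fpkm.tsv", "cellline_samples.tsv"),
    "shortterm": ("shortterm_fpkm.tsv", "shortterm_samples.tsv"),
}


def write_bundle(bundle: SimBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, (expr_file, sheet_file) in BUNDLE_FILES.items():
        write_expression(getattr(bundle, name), outdir / expr_file,
                         outdir / sheet_file)
    write_annotation(bundle.annotation, outdir / "annotation.tsv")
    for mark, peaks in bundle.peaks.items():
        for cond, which in (("resistant", "signal_a"), ("sensitive", "signal_b")):
            cond_peaks = [
                Peak(chrom=p.chrom, start=p.start, end=p.end, mark=p.mark,
                     neg_log10_p=p.neg_log10_p, signal_a=getattr(p, which))
                for p in peaks
            ]
            write_peaks(cond_peaks, outdir / f"peaks_{mark}_{cond}.narrowPeak")
            write_bedgraph(bundle.tracks[(mark, cond)],
                           outdir / f"track_{mark}_{cond}.bedgraph")
    truth = bundle.truth.genes.copy()
    truth.index.name = "gene_id"
    truth.to_csv(outdir / "truth_genes.tsv", sep="\t")
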