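"""Readers, writers and validated in-memory containers for the pipeline's formats.

All genomic intervals are 0-based half-open (BED convention).  A TSS is a
single 0-based base: the annotated gene start on the + strand and the
annotated gene end minus one on the − strand.

Formats handled here:

* expression — TSV ``gene_id<TAB>biotype<TAB><sample>...`` of FPKM values,
  with a companion sample sheet TSV ``sample, dataset, condition, pair_id``;
* annotation — BED-like TSV ``chrom, tss_start, tss_end(=tss_start+1),
  gene_id, biotype, strand``;
* peaks — ENCODE narrowPeak (BED6+4), column 8 read as −log10(p);
* signal — 4-column bedGraph, kept as per-chromosome sorted
  non-overlapping interval arrays;
* signatures — TSV ``gene_id, biotype, direction, log2fc_invivo,
  log2fc_invitro``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger("tzsig")

#: the only biotypes the gating thresholds are defined for; anything else
#: is rejected rather than silently dropped.
BIOTYPES = ("mRNA", "lincRNA")

#: recognised dataset tags in sample sheets.
DATASETS = ("tumor", "cellline", "shortterm")

MARKS = ("H3K4me1", "H3K27ac")


class FormatError(ValueError):
    """Raised when an input file violates a format or an invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """FPKM values (genes × samples) with biotype labels and a sample sheet.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample, non-negative
        FPKM.
    biotype
        Series indexed by gene id with values in :data:`BIOTYPES`.
    sample_sheet
        DataFrame indexed by sample name with columns ``dataset``,
        ``condition`` and ``pair_id`` (pair id may be missing throughout a
        dataset, but if any sample of a dataset carries one, all must, and
        the ids must match 1:1 across the dataset's two conditions).
    """

    values: pd.DataFrame
    biotype: pd.Series
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dups))}")
        if not idx.equals(self.biotype.index):
            raise FormatError("biotype index does not match gene ids")
        bad = set(self.biotype.unique()) - set(BIOTYPES)
        if bad:
            raise FormatError(f"unknown biotype(s): {sorted(bad)}; expected {BIOTYPES}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("non-finite FPKM value")
        if (vals < 0).any():
            raise FormatError("negative FPKM value")
        missing = set(self.sample_sheet.index) - set(self.values.columns)
        if missing:
            raise FormatError(
                f"sample(s) in sheet missing from expression table: {sorted(missing)}"
            )
        if self.sample_sheet.index.has_duplicates:
            raise FormatError("duplicate sample in sheet")
        for ds, sub in self.sample_sheet.groupby("dataset"):
            has_pair = sub["pair_id"].notna()
            if has_pair.any() and not has_pair.all():
                raise FormatError(f"dataset {ds!r}: pair ids present for some samples only")
            if has_pair.all() and len(sub):
                conds = sub["condition"].unique()
                if len(conds) == 2:
                    a = sorted(sub.loc[sub["condition"] == conds[0], "pair_id"])
                    b = sorted(sub.loc[sub["condition"] == conds[1], "pair_id"])
                    if a != b:
                        raise FormatError(
                            f"dataset {ds!r}: pair ids do not match 1:1 across conditions"
                        )

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return [s for s in self.values.columns if s in self.sample_sheet.index]

    def samples_for(self, condition: str) -> list[str]:
        sel = self.sample_sheet.index[self.sample_sheet["condition"] == condition]
        if len(sel) == 0:
            known = sorted(self.sample_sheet["condition"].unique())
            raise FormatError(f"unknown condition {condition!r}; sheet has {known}")
        return list(sel)


@dataclass
class GeneAnnotation:
    """TSS coordinates per gene: chrom, 0-based tss, strand, biotype."""

    table: pd.DataFrame  # index gene_id; columns chrom, tss, strand, biotype

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise FormatError("duplicate gene id in annotation")
        if (t["tss"] < 0).any():
            raise FormatError("negative TSS")
        bad = set(t["strand"].unique()) - {"+", "-"}
        if bad:
            raise FormatError(f"bad strand value(s): {sorted(bad)}")
        badb = set(t["biotype"].unique()) - set(BIOTYPES)
        if badb:
            raise FormatError(f"unknown biotype(s) in annotation: {sorted(badb)}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class Peak:
    """A called ChIP peak: 0-based half-open interval with a mark label,
    a MACS-style −log10(p) enrichment score and, once attached, the mean
    normalized track signal in the two conditions (A = resistant,
    B = sensitive)."""

    chrom: str
    start: int
    end: int
    mark: str
    neg_log10_p: float
    signal_a: Optional[float] = None
    signal_b: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"peak start >= end: {self.chrom}:{self.start}-{self.end}")
        if self.neg_log10_p < 0:
            raise FormatError("negative −log10(p)")
        for s in (self.signal_a, self.signal_b):
            if s is not None and s < 0:
                raise FormatError("negative peak signal")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SignalTrack:
    """Per-chromosome sorted, non-overlapping (start, end, value) intervals."""

    chroms: dict = field(default_factory=dict)
    # chrom -> (starts, ends, values) as numpy arrays

    def add_chrom(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if (starts >= ends).any():
            raise FormatError(f"{chrom}: interval with start >= end")
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise FormatError(
                f"{chrom}: overlapping intervals at "
                f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
            )
        if not np.isfinite(values).all():
            raise FormatError(f"{chrom}: non-finite signal value")
        self.chroms[chrom] = (starts, ends, values)

    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e, _ in self.chroms.values()))

    def weighted_mean(self) -> float:
        """Length-weighted mean value over all covered bases."""
        num = 0.0
        den = 0
        for s, e, v in self.chroms.values():
            w = e - s
            num += float((w * v).sum())
            den += int(w.sum())
        if den == 0:
            raise FormatError("empty signal track")
        return num / den

    def scale(self, factor: float) -> "SignalTrack":
        out = SignalTrack()
        for chrom, (s, e, v) in self.chroms.items():
            out.chroms[chrom] = (s.copy(), e.copy(), v * factor)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self.chroms) != set(other.chroms):
            return False
        return all(
            np.array_equal(self.chroms[c][0], other.chroms[c][0])
            and np.array_equal(self.chroms[c][1], other.chroms[c][1])
            and np.allclose(self.chroms[c][2], other.chroms[c][2], rtol=0, atol=0)
            for c in self.chroms
        )


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "dataset", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing column(s): {sorted(missing)}")
    if "pair_id" not in sheet.columns:
        sheet["pair_id"] = pd.NA
    sheet["pair_id"] = sheet["pair_id"].where(sheet["pair_id"] != "", pd.NA)
    bad = set(sheet["dataset"].unique()) - set(DATASETS)
    if bad:
        raise FormatError(f"unknown dataset tag(s): {sorted(bad)}; expected {DATASETS}")
    return sheet.set_index("sample")[["dataset", "condition", "pair_id"]]


def read_expression(path, sample_sheet_path) -> ExpressionMatrix:
    """Read an FPKM table plus its sample sheet into an `ExpressionMatrix`.

    The table is TSV with header ``gene_id, biotype, <sample>...``.  Samples
    named in the sheet must all be present in the table; extra table columns
    not in the sheet are dropped with a notice.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["gene_id", "biotype"]:
        raise FormatError(
            f"{path}: first two columns must be gene_id, biotype, got {list(df.columns[:2])}"
        )
    sheet = read_sample_sheet(sample_sheet_path)
    df = df.set_index("gene_id")
    biotype = df["biotype"]
    values = df.drop(columns=["biotype"]).astype(float)
    extra = [c for c in values.columns if c not in sheet.index]
    if extra:
        log.info("%s: dropping %d column(s) absent from sample sheet: %s",
                 path, len(extra), extra)
        values = values.drop(columns=extra)
    return ExpressionMatrix(values=values, biotype=biotype, sample_sheet=sheet)


def write_expression(matrix: ExpressionMatrix, path, sample_sheet_path=None) -> None:
    out = matrix.values.copy()
    out.insert(0, "biotype", matrix.biotype)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.sample_sheet, sample_sheet_path)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    out = sheet.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def read_annotation(path) -> GeneAnnotation:
    """Read the BED-like TSS annotation (chrom, tss, tss+1, gene, biotype, strand)."""
    cols = ["chrom", "tss", "tss_end", "gene_id", "biotype", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     dtype={"chrom": str, "gene_id": str})
    if ((df["tss_end"] - df["tss"]) != 1).any():
        raise FormatError(f"{path}: TSS intervals must be single bases (end = start + 1)")
    table = df.set_index("gene_id")[["chrom", "tss", "strand", "biotype"]]
    return GeneAnnotation(table=table)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    t = annotation.table
    out = pd.DataFrame({
        "chrom": t["chrom"],
        "tss": t["tss"],
        "tss_end": t["tss"] + 1,
        "gene_id": t.index,
        "biotype": t["biotype"],
        "strand": t["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def tss_from_gene_bounds(start: int, end: int, strand: str) -> int:
    """TSS of a gene spanning [start, end) — start on +, end − 1 on −."""
    if strand == "+":
        return start
    if strand == "-":
        return end - 1
    raise FormatError(f"bad strand {strand!r}")


# ---------------------------------------------------------------------------
# narrowPeak I/O
# ---------------------------------------------------------------------------

def read_peaks(path, mark: str) -> list[Peak]:
    """Read an ENCODE narrowPeak file.

    The mark label is supplied by the caller (narrowPeak carries none).
    Column 8 (1-based) is the −log10(p) enrichment score.
    """
    if mark not in MARKS:
        raise FormatError(f"unknown mark {mark!r}; expected one of {MARKS}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                neg_log10_p = float(fields[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            try:
                peaks.append(Peak(chrom=fields[0], start=start, end=end,
                                  mark=mark, neg_log10_p=neg_log10_p))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            signal = p.signal_a if p.signal_a is not None else 0.0
            fh.write("\t".join([
                p.chrom, str(p.start), str(p.end), f"peak{i}", "0", ".",
                f"{signal:.6g}", f"{p.neg_log10_p:.6g}", "-1", "-1",
            ]) + "\n")


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph into a `SignalTrack`.

    Input is sorted internally; genuinely overlapping intervals are a hard
    error (the track invariant forbids them).
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            by_chrom.setdefault(fields[0], []).append((start, end, value))
    track = SignalTrack()
    for chrom, ivs in by_chrom.items():
        starts, ends, values = zip(*ivs)
        track.add_chrom(chrom, starts, ends, values)
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            starts, ends, values = track.chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# signature I/O  (the set container itself lives in tzsig.signature)
# ---------------------------------------------------------------------------

SIGNATURE_COLUMNS = ["gene_id", "biotype", "direction", "log2fc_invivo", "log2fc_invitro"]


def read_signature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(SIGNATURE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: signature table missing column(s): {sorted(missing)}")
    bad = set(df["direction"].unique()) - {"up", "down"}
    if bad:
        raise FormatError(f"{path}: bad direction value(s): {sorted(bad)}")
    return df


def write_signature_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in SIGNATURE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[SIGNATURE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")
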