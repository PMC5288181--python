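"""Four-stage analysis orchestration.

Stage order follows the study design: tumor DE → cell-line DE → short-term
subtraction → concordant intersection + Fisher enrichment → enhancer
signal-ratio summary.  The subtraction is applied to the cell-line list
BEFORE intersecting with the in-vivo list.  Output is a pure function of
(inputs, config, seed); a manifest with content hashes makes bit-identical
re-runs checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .io_formats import (
    read_expression, read_annotation, read_peaks, read_bedgraph,
    write_signature_table, MARKS,
)
from .de_calling import DEConfig, call_de, write_de_table
from .signature import SignatureSet, fisher_overlap
from .enhancer import (
    EnhancerConfig, normalize_track, attach_signals, filter_peaks,
    assign_peaks, summarize_all, peak_table,
)

log = logging.getLogger("tzsig")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class DatasetSpec:
    expression: str
    samples: str
    numerator: str
    denominator: str
    de: DEConfig = field(default_factory=DEConfig)


@dataclass
class ChipSpec:
    mark: str
    peaks: dict  # {"resistant": path, "sensitive": path}
    tracks: dict  # {"resistant": path, "sensitive": path}


@dataclass
class PipelineConfig:
    tumor: DatasetSpec
    cellline: DatasetSpec
    shortterm: DatasetSpec
    annotation: str
    chip: list = field(default_factory=list)
    enhancer: EnhancerConfig = field(default_factory=EnhancerConfig)
    fisher_universe: str = "gated_both"  # or "all_genes"
    outdir: str = "run"
    seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def _resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        def _dataset(d, paired_default):
            de_kwargs = dict(d.get("de", {}))
            de_kwargs.setdefault("use_paired_test", paired_default)
            return DatasetSpec(
                expression=_resolve(d["expression"]),
                samples=_resolve(d["samples"]),
                numerator=d["numerator"],
                denominator=d["denominator"],
                de=DEConfig(**de_kwargs),
            )

        chip = [
            ChipSpec(
                mark=c["mark"],
                peaks={k: _resolve(v) for k, v in c["peaks"].items()},
                tracks={k: _resolve(v) for k, v in c["tracks"].items()},
            )
            for c in raw.get("chip", [])
        ]
        return cls(
            tumor=_dataset(raw["tumor"], False),
            cellline=_dataset(raw["cellline"], True),
            shortterm=_dataset(raw["shortterm"], True),
            annotation=_resolve(raw["annotation"]),
            chip=chip,
            enhancer=EnhancerConfig(**raw.get("enhancer", {})),
            fisher_universe=raw.get("fisher_universe", "gated_both"),
            outdir=_resolve(raw.get("outdir", "run")),
            seed=int(raw.get("seed", 1)),
            log_level=raw.get("log_level", "INFO"),
        )

    def canonical_json(self) -> str:
        """Canonical form of the analytic configuration.  The output
        directory and log level are excluded: they do not affect results."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        d.pop("log_level", None)
        return json.dumps(d, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def fisher_summary(tumor_de: pd.DataFrame, cellline_de: pd.DataFrame,
                   set_a: SignatureSet, set_b: SignatureSet,
                   integrated: SignatureSet, policy: str = "gated_both") -> dict:
    """Fisher enrichment of the concordant overlap, pooled and per biotype.

    The universe is the genes passing the expression gate in BOTH the
    tumor and cell-line datasets (policy "gated_both"), or every gene
    shared by the two tables (policy "all_genes") — the paper-analysis
    universe is not stated, so it is a config choice.
    """
    merged = tumor_de[["gene_id", "biotype", "passes_gate"]].merge(
        cellline_de[["gene_id", "passes_gate"]], on="gene_id",
        suffixes=("_tumor", "_cell"))
    if policy == "gated_both":
        universe = merged[merged["passes_gate_tumor"] & merged["passes_gate_cell"]]
    elif policy == "all_genes":
        universe = merged
    else:
        raise ValueError(f"unknown fisher universe policy {policy!r}")

    out = {}
    subsets = {"pooled": universe}
    for bt, sub in universe.groupby("biotype"):
        subsets[bt] = sub
    for name, sub in subsets.items():
        ids = set(sub["gene_id"])
        n_a = len(set_a.gene_ids & ids)
        n_b = len(set_b.gene_ids & ids)
        k = len(integrated.gene_ids & ids)
        res = fisher_overlap(len(ids), n_a, n_b, k)
        out[name] = res.to_dict()
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a dict of the key results and output paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- differential expression -------------------------------------------
    de_tables = {}
    for name in ("tumor", "cellline", "shortterm"):
        ds: DatasetSpec = getattr(cfg, name)
        matrix = _stage(f"read:{name}", read_expression, ds.expression, ds.samples)
        de = _stage(f"de:{name}", call_de, matrix, ds.de, ds.numerator, ds.denominator)
        write_de_table(de, outdir / f"{name}_de.tsv")
        de_tables[name] = de
        log.info("%s: %d/%d genes differential", name,
                 int(de["is_differential"].sum()), len(de))

    # --- set integration ----------------------------------------------------
    tumor_set = SignatureSet.from_de_calls(de_tables["tumor"], "tumor")
    cell_set = SignatureSet.from_de_calls(de_tables["cellline"], "cellline")
    short_set = SignatureSet.from_de_calls(de_tables["shortterm"], "shortterm")

    from .signature import subtract, intersect_concordant
    post_sub = _stage("subtract", subtract, cell_set, short_set)
    write_signature_table(post_sub.to_frame(), outdir / "post_subtraction.tsv")
    integrated = _stage("intersect", intersect_concordant, tumor_set, post_sub)
    write_signature_table(integrated.to_frame(other=post_sub),
                          outdir / "integrated_signature.tsv")
    counts = integrated.count_by_biotype()
    log.info("integrated signature: %d mRNA, %d lincRNA",
             counts.get("mRNA", 0), counts.get("lincRNA", 0))

    fisher = _stage("fisher", fisher_summary, de_tables["tumor"],
                    de_tables["cellline"], tumor_set, post_sub, integrated,
                    cfg.fisher_universe)
    fisher["integrated_counts"] = {bt: counts.get(bt, 0) for bt in ("mRNA", "lincRNA")}
    _json_dump(fisher, outdir / "fisher.json")

    # --- enhancer signal ratios --------------------------------------------
    annotation = _stage("read:annotation", read_annotation, cfg.annotation)
    gene_panel = sorted(g for g in integrated.gene_ids if g in annotation)
    summaries, long_rows = [], []
    for chip in cfg.chip:
        if chip.mark not in MARKS:
            raise PipelineError(f"stage 'enhancer' failed: unknown mark {chip.mark!r}")
        res = _stage(f"enhancer:{chip.mark}", _enhancer_mark, chip, annotation,
                     gene_panel, cfg.enhancer)
        summaries.append(res[0])
        long_rows.append(res[1])
    summary_df = (pd.concat(summaries, ignore_index=True) if summaries
                  else pd.DataFrame(columns=["gene_id", "mark", "n_peaks",
                                             "median_log2_ratio"]))
    long_df = (pd.concat(long_rows, ignore_index=True) if long_rows
               else pd.DataFrame(columns=["gene_id", "mark", "chrom", "start",
                                          "end", "log2_ratio"]))
    summary_df.to_csv(outdir / "enhancer_summary.tsv", sep="\t", index=False,
                      float_format="%.6g")
    long_df.to_csv(outdir / "enhancer_peaks.tsv", sep="\t", index=False,
                   float_format="%.6g")

    # --- manifest -----------------------------------------------------------
    output_files = sorted(p.name for p in outdir.iterdir()
                          if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_sha256": hashlib.sha256(cfg.canonical_json().encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "tzsig": __version__,
        },
        "outputs": {name: _sha256(outdir / name) for name in output_files},
    }
    _json_dump(manifest, outdir / "manifest.json")

    return {
        "outdir": str(outdir),
        "integrated": integrated,
        "post_subtraction": post_sub,
        "tumor_set": tumor_set,
        "cellline_set": cell_set,
        "shortterm_set": short_set,
        "fisher": fisher,
        "enhancer_summary": summary_df,
        "enhancer_peaks": long_df,
        "de_tables": de_tables,
    }


def _enhancer_mark(chip: ChipSpec, annotation, gene_panel, ecfg: EnhancerConfig):
    """One mark: read + union peaks, normalize tracks, attach, filter,
    assign and summarize."""
    peaks_r = read_peaks(chip.peaks["resistant"], chip.mark)
    peaks_s = read_peaks(chip.peaks["sensitive"], chip.mark)
    seen, union = set(), []
    for p in peaks_r + peaks_s:
        key = (p.chrom, p.start, p.end)
        if key not in seen:
            seen.add(key)
            union.append(p)
    track_r = normalize_track(read_bedgraph(chip.tracks["resistant"]))
    track_s = normalize_track(read_bedgraph(chip.tracks["sensitive"]))
    kept = filter_peaks(attach_signals(union, track_r, track_s), ecfg)
    assigned = assign_peaks(kept, annotation, gene_panel, ecfg)
    return summarize_all(assigned, [chip.mark], ecfg), peak_table(assigned, ecfg)


def write_default_config(bundle_dir, path, outdir="run", seed: int = 1) -> None:
    """Emit a pipeline config pointing at a simulated bundle directory."""
    bundle_dir = Path(bundle_dir)
    cfg = {
        "seed": seed,
        "outdir": outdir,
        "annotation": "annotation.tsv",
        "tumor": {
            "expression": "tumor_fpkm.tsv", "samples": "tumor_samples.tsv",
            "numerator": "TzR", "denominator": "TzS",
            "de": {"use_paired_test": False},
        },
        "cellline": {
            "expression": "cellline_fpkm.tsv", "samples": "cellline_samples.tsv",
            "numerator": "TzR", "denominator": "TzS",
            "de": {"use_paired_test": True},
        },
        "shortterm": {
            "expression": "shortterm_fpkm.tsv", "samples": "shortterm_samples.tsv",
            "numerator": "treated48h", "denominator": "mock",
            "de": {"use_paired_test": True},
        },
        "chip": [
            {
                "mark": mark,
                "peaks": {c: f"peaks_{mark}_{c}.narrowPeak" for c in
                          ("resistant", "sensitive")},
                "tracks": {c: f"track_{mark}_{c}.bedgraph" for c in
                           ("resistant", "sensitive")},
            }
            for mark in MARKS
        ],
        "enhancer": {},
        "fisher_universe": "gated_both",
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
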