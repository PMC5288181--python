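"""Expression gating and differential-expression calling.

Two modes mirror the two study designs:

* **tumor mode** (11 responders vs 2 non-responders): a gene is
  differential when the fold change of condition means (resistant /
  sensitive) is ≥ 2.0 or ≤ 0.5 — no p-value is computed, two non-responders
  leave no room for a per-gene test;
* **cell-line mode** (paired replicates): the same fold-change rule plus a
  two-sided paired t-test on log2(FPKM + pseudocount) with p < 0.05.

Both modes first apply the expression gate: a gene is considered expressed
when EVERY sample of at least one of the two conditions has FPKM at or
above the biotype threshold (1.0 for mRNAs, 0.25 for lincRNAs, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, FormatError

DE_COLUMNS = [
    "gene_id", "biotype", "passes_gate", "mean_a", "mean_b",
    "fold_change", "log2fc", "p_value", "is_differential", "direction",
]


@dataclass
class DEConfig:
    """Thresholds for gating and differential calling.

    fc_down defaults to 1/fc_up; the pseudocount stabilizes ratios and log
    transforms against one-sided zero means (the gate makes both-zero
    impossible).  ``fdr_bh`` switches the p criterion to Benjamini–Hochberg
    adjusted p-values; it is off by default, matching a plain per-gene
    p < alpha rule.
    """

    fpkm_min_mrna: float = 1.0
    fpkm_min_lincrna: float = 0.25
    fc_up: float = 2.0
    fc_down: Optional[float] = None
    alpha: float = 0.05
    use_paired_test: bool = False
    pseudocount: float = 0.01
    fdr_bh: bool = False

    def __post_init__(self) -> None:
        if self.fc_down is None:
            self.fc_down = 1.0 / self.fc_up
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.fc_up <= 1 or not 0 < self.fc_down < 1:
            raise ValueError("need fc_up > 1 and 0 < fc_down < 1")


def gate_expression(matrix: ExpressionMatrix, cfg: DEConfig,
                    condition_a: str, condition_b: str) -> pd.Series:
    """Boolean per-gene expression gate.

    A gene passes iff every sample of condition A is at or above its
    biotype threshold, OR every sample of condition B is (comparison is
    inclusive, ``>=``).
    """
    samples_a = matrix.samples_for(condition_a)
    samples_b = matrix.samples_for(condition_b)
    thr = matrix.biotype.map(
        {"mRNA": cfg.fpkm_min_mrna, "lincRNA": cfg.fpkm_min_lincrna}
    ).to_numpy()[:, None]
    pass_a = (matrix.values[samples_a].to_numpy() >= thr).all(axis=1)
    pass_b = (matrix.values[samples_b].to_numpy() >= thr).all(axis=1)
    return pd.Series(pass_a | pass_b, index=matrix.gene_ids, name="passes_gate")


def _paired_log2_diffs(matrix: ExpressionMatrix, cfg: DEConfig,
                       num_cond: str, den_cond: str) -> np.ndarray:
    """Per-gene log2 differences (numerator − denominator) over matched pairs."""
    sheet = matrix.sample_sheet
    num_s = matrix.samples_for(num_cond)
    den_s = matrix.samples_for(den_cond)
    num_pairs = sheet.loc[num_s, "pair_id"]
    den_pairs = sheet.loc[den_s, "pair_id"]
    if num_pairs.isna().any() or den_pairs.isna().any():
        raise FormatError("paired test requested but pair ids are missing")
    num_by_pair = {p: s for s, p in num_pairs.items()}
    den_by_pair = {p: s for s, p in den_pairs.items()}
    if set(num_by_pair) != set(den_by_pair) or len(num_by_pair) != len(num_s):
        raise FormatError("pair ids do not match 1:1 across conditions")
    pair_ids = sorted(num_by_pair)
    if len(pair_ids) < 2:
        raise FormatError(f"paired test needs >= 2 pairs, got {len(pair_ids)}")
    num_m = np.log2(matrix.values[[num_by_pair[p] for p in pair_ids]].to_numpy()
                    + cfg.pseudocount)
    den_m = np.log2(matrix.values[[den_by_pair[p] for p in pair_ids]].to_numpy()
                    + cfg.pseudocount)
    return num_m - den_m


def paired_t_pvalues(diffs: np.ndarray) -> np.ndarray:
    """Two-sided paired t-test p-values from per-gene difference vectors.

    Degenerate genes are resolved explicitly: all differences zero → t = 0,
    p = 1; zero variance with nonzero mean → p = 0.
    """
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    p = np.empty(len(mean))
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p[~zero_sd] = 2.0 * stats.t.sf(np.abs(t[~zero_sd]), df=n - 1)
    p[zero_sd & (mean == 0)] = 1.0
    p[zero_sd & (mean != 0)] = 0.0
    return p


def call_de(matrix: ExpressionMatrix, cfg: DEConfig,
            numerator_condition: str, denominator_condition: str) -> pd.DataFrame:
    """Gate and call differential expression; one row per gene.

    fold_change = (mean_num + pseudocount) / (mean_den + pseudocount) on
    condition means.  In paired mode (cfg.use_paired_test) the p-value is a
    two-sided paired t-test on log2(FPKM + pseudocount) and the differential
    rule additionally requires p < alpha (BH-adjusted across gated genes
    when cfg.fdr_bh).  Returns a DataFrame with :data:`DE_COLUMNS`.
    """
    gate = gate_expression(matrix, cfg, numerator_condition, denominator_condition)
    samples_num = matrix.samples_for(numerator_condition)
    samples_den = matrix.samples_for(denominator_condition)
    mean_a = matrix.values[samples_num].mean(axis=1).to_numpy()
    mean_b = matrix.values[samples_den].mean(axis=1).to_numpy()
    fold_change = (mean_a + cfg.pseudocount) / (mean_b + cfg.pseudocount)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(fold_change)

    p_value = np.full(len(mean_a), np.nan)
    if cfg.use_paired_test:
        diffs = _paired_log2_diffs(matrix, cfg, numerator_condition,
                                   denominator_condition)
        p_value = paired_t_pvalues(diffs)

    fc_hit = (fold_change >= cfg.fc_up) | (fold_change <= cfg.fc_down)
    gate_arr = gate.to_numpy()
    if cfg.use_paired_test:
        p_crit = p_value.copy()
        if cfg.fdr_bh:
            p_crit = np.full_like(p_value, np.nan)
            p_crit[gate_arr] = stats.false_discovery_control(p_value[gate_arr])
        sig = p_crit < cfg.alpha
        is_diff = gate_arr & fc_hit & sig
    else:
        is_diff = gate_arr & fc_hit

    direction = np.where(~is_diff, "none",
                         np.where(fold_change >= cfg.fc_up, "up", "down"))
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "biotype": matrix.biotype.to_numpy(),
        "passes_gate": gate_arr,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "fold_change": fold_change,
        "log2fc": log2fc,
        "p_value": p_value,
        "is_differential": is_diff,
        "direction": direction,
    })


def heatmap_matrix(matrix: ExpressionMatrix, de_calls: pd.DataFrame,
                   pseudocount: float = 0.01) -> pd.DataFrame:
    """Row-standardized log2 expression for the differential genes.

    Each row is z-scored across samples: (x − mean) / sd with the sample
    (n−1) standard deviation, x = log2(FPKM + pseudocount).  Constant rows
    map to all-zeros rather than NaN.
    """
    genes = de_calls.loc[de_calls["is_differential"], "gene_id"]
    sub = np.log2(matrix.values.loc[genes, matrix.samples] + pseudocount)
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(mean, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return z


def ddct_fold_change(ct_target_test: float, ct_ref_test: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_control; the
    reference gene (e.g. GAPDH) cancels amplification efficiency.
    """
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** -ddct)


def write_de_table(de_calls: pd.DataFrame, path) -> None:
    de_calls[DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
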