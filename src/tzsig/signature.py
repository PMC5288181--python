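"""Set-level integration of differential-gene lists.

The resistance signature is built in three set operations: genes responding
to short-term drug exposure are subtracted from the long-term resistant
cell-line list; the remainder is intersected with the in-vivo (tumor) list
requiring concordant direction; and the overlap is tested for enrichment
with a two-tailed Fisher's exact test on a user-defined gene universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import pandas as pd

from .io_formats import SIGNATURE_COLUMNS, read_signature_table

PROVENANCES = ("tumor", "cellline", "shortterm", "integrated")

#: relative tolerance used to treat hypergeometric point probabilities as
#: tied when accumulating the two-tailed p (the convention of standard
#: exact-test implementations).
TIE_RTOL = 1e-7


@dataclass
class SignatureSet:
    """Gene ids with a direction (up/down in the resistant condition)."""

    entries: dict  # gene_id -> "up" | "down"
    biotype: dict = field(default_factory=dict)  # gene_id -> biotype
    provenance: str = "integrated"
    log2fc: dict = field(default_factory=dict)  # gene_id -> observed log2 fold change

    def __post_init__(self) -> None:
        bad = set(self.entries.values()) - {"up", "down"}
        if bad:
            raise ValueError(f"bad direction value(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    @property
    def gene_ids(self) -> set:
        return set(self.entries)

    def count_by_biotype(self) -> dict:
        out: dict[str, int] = {}
        for g in self.entries:
            bt = self.biotype.get(g, "mRNA")
            out[bt] = out.get(bt, 0) + 1
        return out

    def restrict(self, gene_ids) -> "SignatureSet":
        keep = set(gene_ids)
        return SignatureSet(
            entries={g: d for g, d in self.entries.items() if g in keep},
            biotype={g: b for g, b in self.biotype.items() if g in keep},
            provenance=self.provenance,
            log2fc={g: v for g, v in self.log2fc.items() if g in keep},
        )

    @classmethod
    def from_de_calls(cls, de_calls: pd.DataFrame, provenance: str) -> "SignatureSet":
        """Collect the differential genes of a DE table into a set."""
        hits = de_calls[de_calls["is_differential"]]
        return cls(
            entries=dict(zip(hits["gene_id"], hits["direction"])),
            biotype=dict(zip(hits["gene_id"], hits["biotype"])),
            provenance=provenance,
            log2fc=dict(zip(hits["gene_id"], hits["log2fc"])),
        )

    @classmethod
    def from_table(cls, path, provenance: str = "integrated") -> "SignatureSet":
        df = read_signature_table(path)
        log2fc = {}
        for col in ("log2fc_invivo", "log2fc_invitro"):
            if col in df.columns:
                log2fc = dict(zip(df["gene_id"], df[col]))
                break
        return cls(
            entries=dict(zip(df["gene_id"], df["direction"])),
            biotype=dict(zip(df["gene_id"], df["biotype"])),
            provenance=provenance,
            log2fc=log2fc,
        )

    def to_frame(self, other: Optional["SignatureSet"] = None) -> pd.DataFrame:
        """Signature table; when `other` is given its log2fc fills the
        in-vitro column (self fills in-vivo)."""
        genes = sorted(self.entries)
        df = pd.DataFrame({
            "gene_id": genes,
            "biotype": [self.biotype.get(g, "mRNA") for g in genes],
            "direction": [self.entries[g] for g in genes],
            "log2fc_invivo": [self.log2fc.get(g, float("nan")) for g in genes],
            "log2fc_invitro": [
                (other.log2fc.get(g, float("nan")) if other is not None else float("nan"))
                for g in genes
            ],
        })
        return df[SIGNATURE_COLUMNS]


@dataclass
class FisherResult:
    """A 2×2 overlap table and its two-tailed exact test."""

    table: tuple  # (in_both, in_a_only, in_b_only, in_neither)
    p_two_tailed: float
    odds_ratio: float

    def to_dict(self) -> dict:
        a, b, c, d = self.table
        return {
            "universe": a + b + c + d,
            "n_a": a + b,
            "n_b": a + c,
            "overlap": a,
            "p_two_tailed": self.p_two_tailed,
            "odds_ratio": self.odds_ratio,
        }


def subtract(resistance_set: SignatureSet, short_term_set: SignatureSet) -> SignatureSet:
    """Remove every gene present in `short_term_set` regardless of its
    direction there; directions of the survivors are preserved."""
    drop = short_term_set.gene_ids
    return SignatureSet(
        entries={g: d for g, d in resistance_set.entries.items() if g not in drop},
        biotype={g: b for g, b in resistance_set.biotype.items() if g not in drop},
        provenance=resistance_set.provenance,
        log2fc={g: v for g, v in resistance_set.log2fc.items() if g not in drop},
    )


def intersect_concordant(in_vivo: SignatureSet, in_vitro: SignatureSet) -> SignatureSet:
    """Genes present in both sets with the same direction of change."""
    entries = {
        g: d for g, d in in_vivo.entries.items()
        if in_vitro.entries.get(g) == d
    }
    return SignatureSet(
        entries=entries,
        biotype={g: in_vivo.biotype.get(g, in_vitro.biotype.get(g, "mRNA"))
                 for g in entries},
        provenance="integrated",
        log2fc={g: in_vivo.log2fc.get(g, float("nan")) for g in entries},
    )


def fisher_overlap(universe_n: int, n_a: int, n_b: int, n_overlap: int) -> FisherResult:
    """Two-tailed Fisher's exact test of the overlap of two gene sets.

    The p-value is the exact hypergeometric two-tail: the sum, over all
    2×2 tables with the observed margins, of the point probabilities not
    exceeding the observed one (within :data:`TIE_RTOL` relative slack).
    Computed in exact integer arithmetic — no approximation.
    """
    if not (0 <= n_a <= universe_n and 0 <= n_b <= universe_n):
        raise ValueError("set sizes must lie within the universe")
    if not (max(0, n_a + n_b - universe_n) <= n_overlap <= min(n_a, n_b)):
        raise ValueError(
            f"inconsistent counts: overlap {n_overlap} impossible for "
            f"|A|={n_a}, |B|={n_b}, universe {universe_n}"
        )
    a = n_overlap
    b = n_a - n_overlap
    c = n_b - n_overlap
    d = universe_n - n_a - n_b + n_overlap

    lo = max(0, n_a + n_b - universe_n)
    hi = min(n_a, n_b)
    # point-probability numerators over the common denominator C(N, n_b)
    nums = [math.comb(n_a, k) * math.comb(universe_n - n_a, n_b - k)
            for k in range(lo, hi + 1)]
    obs = nums[n_overlap - lo]
    # k is in the tail iff P(k) <= P(obs) * (1 + TIE_RTOL); exact integers
    scale = 10 ** 7
    cutoff = obs * (scale + 1)
    tail = sum(n for n in nums if n * scale <= cutoff)
    p = float(Fraction(tail, math.comb(universe_n, n_b)))
    p = min(p, 1.0)

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(table=(a, b, c, d), p_two_tailed=p, odds_ratio=odds)
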