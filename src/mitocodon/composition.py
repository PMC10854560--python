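"""Base composition, strand skews, and positional GC content.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), the usual
strand-asymmetry summaries; both negate under reverse complementation.
N bases are excluded from the numerators and denominators of skews and
GC metrics. Percentages are serialized to 2 decimals and skews to 4; all
internal values keep full precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .codes import reverse_complement
from .genome_io import MitogenomeRecord, extract_gene_sequence


@dataclass(frozen=True)
class CompositionStats:
    """Exact base counts plus derived content and skew values."""

    length: int
    a: int
    c: int
    g: int
    t: int
    n: int

    @property
    def non_n(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def fractions(self) -> dict[str, float]:
        d = self.non_n
        return {b: getattr(self, b.lower()) / d for b in "ACGT"} if d else {}

    @property
    def at_content(self) -> float:
        """Percent A+T of non-N bases."""
        return 100.0 * (self.a + self.t) / self.non_n if self.non_n else float("nan")

    @property
    def gc_content(self) -> float:
        return 100.0 * (self.g + self.c) / self.non_n if self.non_n else float("nan")

    @property
    def at_skew(self) -> float:
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else float("nan")

    @property
    def gc_skew(self) -> float:
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else float("nan")


@dataclass(frozen=True)
class PositionalGC:
    """GC percent overall and at each codon position."""

    gc_all: float
    gc1: float
    gc2: float
    gc3: float


def base_composition(seq: str) -> CompositionStats:
    """Exact base composition of a DNA string (A/C/G/T/N alphabet)."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    known = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    return CompositionStats(
        length=len(seq),
        a=counts["A"], c=counts["C"], g=counts["G"], t=counts["T"],
        n=len(seq) - known,
    )


def strand_skew_negation_check(seq: str) -> tuple[CompositionStats, CompositionStats]:
    """Stats for a sequence and its reverse complement.

    The skews of the two strands negate exactly (algebraic identity);
    asserted here as a QC guard.
    """
    fwd = base_composition(seq)
    rev = base_composition(reverse_complement(seq))
    for attr in ("at_skew", "gc_skew"):
        x, y = getattr(fwd, attr), getattr(rev, attr)
        if x == x and abs(x + y) > 1e-12:  # NaN-tolerant
            raise AssertionError(f"{attr} does not negate: {x} vs {y}")
    return fwd, rev


def positional_gc(cds: str) -> PositionalGC:
    """Percent G+C at codon positions 1/2/3, over complete codons only."""
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("need at least one complete codon")
    usable = len(cds) - len(cds) % 3
    gc = [0, 0, 0]
    totals = [0, 0, 0]
    for i in range(usable):
        base = cds[i]
        pos = i % 3
        if base in "ACGT":
            totals[pos] += 1
            if base in "GC":
                gc[pos] += 1
    per_pos = [100.0 * g / t if t else float("nan") for g, t in zip(gc, totals)]
    all_total = sum(totals)
    gc_all = 100.0 * sum(gc) / all_total if all_total else float("nan")
    return PositionalGC(gc_all=gc_all, gc1=per_pos[0], gc2=per_pos[1], gc3=per_pos[2])


def composition_table(records: list[MitogenomeRecord]) -> pd.DataFrame:
    """One row per (taxon, gene or "genome") with composition and skew columns.

    PCG rows additionally carry positional GC content.
    """
    rows = []
    for rec in records:
        targets: list[tuple[str, str, bool]] = [("genome", rec.sequence, False)]
        for feat in rec.features:
            if feat.feature_class in ("PCG", "tRNA", "rRNA", "control_region"):
                targets.append(
                    (feat.name, extract_gene_sequence(rec, feat.name), feat.feature_class == "PCG")
                )
        for name, seq, is_pcg in targets:
            stats = base_composition(seq)
            row = {
                "taxon": rec.accession,
                "gene": name,
                "length": stats.length,
                "A": stats.a, "C": stats.c, "G": stats.g, "T": stats.t,
                "AT_pct": round(stats.at_content, 2),
                "AT_skew": round(stats.at_skew, 4),
                "GC_skew": round(stats.gc_skew, 4),
            }
            if is_pcg and len(seq) >= 3:
                pos = positional_gc(seq)
                row.update(
                    GC1=round(pos.gc1, 2), GC2=round(pos.gc2, 2), GC3=round(pos.gc3, 2)
                )
            rows.append(row)
    return pd.DataFrame(rows)
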