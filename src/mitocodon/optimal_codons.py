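"""Optimal-codon screening by the delta-RSCU rule.

Genes are ranked by ENC; the top 10% at each extreme (at least one gene
per group) form the high- and low-expression groups. A codon is called
optimal when, comparing pooled group RSCU values,

    delta RSCU = RSCU(high) - RSCU(low) > 0.08,
    RSCU(high) > 1, and RSCU(low) < 1,

all inequalities strict. The published wording assigns the *highest*-ENC
genes to the high-expression group; the codon-bias literature convention
is the reverse (strong bias, i.e. low ENC, marks high expression). Both
directions are supported; explicit high/low gene overrides bypass the
choice entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .codes import GeneticCode, STANDARD
from .codon_stats import CodonCountTable, RSCUVector, count_codons, enc, rscu
from .genome_io import MitogenomeRecord, extract_gene_sequence

DELTA_RSCU_THRESHOLD = 0.08
GROUP_FRACTION = 0.10


@dataclass(frozen=True)
class ExpressionGroups:
    high_genes: tuple[str, ...]
    low_genes: tuple[str, ...]
    fraction: float
    group_size: int
    direction: str  # "paper" (highest ENC = high expression) or "conventional"


@dataclass
class OptimalCodonReport:
    taxon: str
    groups: ExpressionGroups | None
    table: pd.DataFrame  # codon, amino_acid, rscu_high, rscu_low, delta_rscu, is_optimal

    @property
    def optimal_codons(self) -> tuple[str, ...]:
        return tuple(self.table.loc[self.table["is_optimal"], "codon"])


def select_expression_groups(
    enc_by_gene: dict[str, float],
    fraction: float = GROUP_FRACTION,
    direction: str = "paper",
) -> ExpressionGroups:
    """Pick the extreme-ENC gene groups; ties break by ascending gene name."""
    defined = {g: v for g, v in enc_by_gene.items() if v is not None and not math.isnan(v)}
    if len(defined) < 2:
        raise ValueError("need at least 2 genes with defined ENC")
    if direction not in ("paper", "conventional"):
        raise ValueError(f"unknown direction {direction!r}")
    size = max(1, math.floor(fraction * len(defined)))
    by_enc_asc = sorted(defined, key=lambda g: (defined[g], g))
    by_enc_desc = sorted(defined, key=lambda g: (-defined[g], g))
    top = tuple(by_enc_desc[:size])  # highest ENC
    bottom = tuple(by_enc_asc[:size])  # lowest ENC
    if set(top) & set(bottom):
        raise ValueError("high and low ENC groups overlap; too few genes for fraction")
    high, low = (top, bottom) if direction == "paper" else (bottom, top)
    return ExpressionGroups(
        high_genes=high, low_genes=low, fraction=fraction, group_size=size,
        direction=direction,
    )


def delta_rscu_table(
    high: RSCUVector,
    low: RSCUVector,
    code: GeneticCode = STANDARD,
    delta_threshold: float = DELTA_RSCU_THRESHOLD,
) -> pd.DataFrame:
    """Full per-codon delta-RSCU table (thresholds applied, rows never dropped)."""
    if set(high.values) != set(low.values):
        raise ValueError("high and low RSCU vectors cover different codon sets")
    rows = []
    for codon in sorted(high.values):
        rh, rl = high.values[codon], low.values[codon]
        delta = rh - rl
        rows.append(
            {
                "codon": codon,
                "amino_acid": code.codon_to_aa[codon],
                "rscu_high": rh,
                "rscu_low": rl,
                "delta_rscu": delta,
                "is_optimal": (delta > delta_threshold) and (rh > 1.0) and (rl < 1.0),
            }
        )
    return pd.DataFrame(rows)


def _pooled_counts(
    record: MitogenomeRecord, genes: tuple[str, ...], code: GeneticCode
) -> CodonCountTable:
    pooled = CodonCountTable(source="+".join(genes), code=code)
    for gene in genes:
        pooled = pooled.merged(
            count_codons(extract_gene_sequence(record, gene), code, source=gene),
            source=pooled.source,
        )
    return pooled


def screen_optimal_codons(
    record: MitogenomeRecord,
    code: GeneticCode = STANDARD,
    high: str | tuple[str, ...] | None = None,
    low: str | tuple[str, ...] | None = None,
    fraction: float = GROUP_FRACTION,
    direction: str = "paper",
    delta_threshold: float = DELTA_RSCU_THRESHOLD,
) -> OptimalCodonReport:
    """Run the full screen on one genome.

    Pipeline: extract PCGs -> per-gene ENC -> expression groups (or the
    explicit ``high``/``low`` override) -> pooled codon counts per group
    -> group RSCU -> delta-RSCU rule.
    """
    pcg_names = sorted(f.name for f in record.pcgs)
    if len(pcg_names) < 2:
        raise ValueError(f"{record.accession}: need at least 2 protein-coding genes")

    if (high is None) != (low is None):
        raise ValueError("provide both high and low overrides, or neither")
    if high is not None:
        high_genes = (high,) if isinstance(high, str) else tuple(high)
        low_genes = (low,) if isinstance(low, str) else tuple(low)
        groups = ExpressionGroups(
            high_genes=high_genes, low_genes=low_genes,
            fraction=fraction, group_size=len(high_genes), direction="explicit",
        )
    else:
        enc_by_gene = {
            name: enc(count_codons(extract_gene_sequence(record, name), code, source=name))
            for name in pcg_names
        }
        groups = select_expression_groups(enc_by_gene, fraction=fraction, direction=direction)

    high_rscu = rscu(_pooled_counts(record, groups.high_genes, code))
    low_rscu = rscu(_pooled_counts(record, groups.low_genes, code))
    table = delta_rscu_table(high_rscu, low_rscu, code=code, delta_threshold=delta_threshold)
    return OptimalCodonReport(taxon=record.accession, groups=groups, table=table)
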