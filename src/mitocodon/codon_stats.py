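"""Codon counting and the three codon-usage-bias statistics: RSCU, ENC, CAI.

RSCU(c) = observed count of c times family size, divided by the family
total — 1 means no bias, and RSCU values over a nonzero family sum to the
family size.

ENC is Wright's effective number of codons: per-family homozygosity
F = (n * sum p^2 - 1) / (n - 1) over families with n >= 2 observations,
averaged within degeneracy classes, then
ENC = (#single-codon families) + sum_k N_k / Fbar_k
(2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 for the standard layout). A missing
three-fold average is replaced by the mean of the two- and four-fold
averages, and the result is capped at the uniform-usage maximum (61).

CAI is the geometric mean, over a gene's sense codons in multi-codon
families, of relative adaptiveness w(c) = ref(c) / max over the family of
ref; zero reference counts receive a 0.5 pseudo-count before w.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .codes import ALL_CODONS, GeneticCode


@dataclass
class CodonCountTable:
    """64-entry codon counts for one gene or gene set under a declared code.

    ``counts`` covers all complete ACGT codons scanned (stops included);
    ``skipped`` tallies codons containing non-ACGT characters.
    """

    source: str
    code: GeneticCode
    counts: dict[str, int] = field(default_factory=dict)
    skipped: int = 0

    def __post_init__(self) -> None:
        base = {c: 0 for c in ALL_CODONS}
        base.update(self.counts)
        self.counts = base

    @property
    def total_scanned(self) -> int:
        return sum(self.counts.values()) + self.skipped

    @property
    def sense_counts(self) -> dict[str, int]:
        return {c: n for c, n in self.counts.items() if c not in self.code.stop_codons}

    @property
    def n_sense(self) -> int:
        return sum(self.sense_counts.values())

    def merged(self, other: "CodonCountTable", source: str | None = None) -> "CodonCountTable":
        if other.code is not self.code:
            raise ValueError("cannot merge tables under different codes")
        counts = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCountTable(
            source=source or f"{self.source}+{other.source}",
            code=self.code, counts=counts, skipped=self.skipped + other.skipped,
        )


@dataclass
class RSCUVector:
    """RSCU values over the code's RSCU codon set (59 under the standard layout)."""

    values: dict[str, float]
    n_codons_counted: int
    zero_families: tuple[frozenset, ...] = ()

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


@dataclass(frozen=True)
class BiasScores:
    gene: str
    enc: float | None
    cai: float | None


def count_codons(cds: str, code: GeneticCode, source: str = "") -> CodonCountTable:
    """Count complete codons in frame 0; ambiguous codons go to ``skipped``."""
    cds = cds.upper()
    counts: dict[str, int] = {}
    skipped = 0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in _CODON_SET:
            counts[codon] = counts.get(codon, 0) + 1
        else:
            skipped += 1
    return CodonCountTable(source=source, code=code, counts=counts, skipped=skipped)


_CODON_SET = frozenset(ALL_CODONS)


def rscu(table: CodonCountTable) -> RSCUVector:
    """Relative synonymous codon usage under the table's declared code.

    Families with zero total usage yield RSCU 0 for all members and are
    flagged in ``zero_families``.
    """
    code = table.code
    values: dict[str, float] = {}
    zero: list[frozenset] = []
    counts = table.counts
    for fam in code.families:
        fam_total = sum(counts[c] for c in fam)
        k = len(fam)
        for c in fam:
            values[c] = counts[c] * k / fam_total if fam_total else 0.0
        if fam_total == 0:
            zero.append(fam)
    kept = {c: values[c] for c in code.rscu_codons}
    n_counted = sum(counts[c] for c in code.rscu_codons)
    return RSCUVector(values=kept, n_codons_counted=n_counted, zero_families=tuple(zero))


def _family_homozygosity(counts: list[int]) -> float | None:
    """Wright's F-hat for one family; None when fewer than 2 observations."""
    n = sum(counts)
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in counts)
    return (n * s - 1.0) / (n - 1.0)


def enc(table: CodonCountTable) -> float | None:
    """Wright's effective number of codons; None when undefined."""
    code = table.code
    counts = table.counts
    class_f: dict[int, float] = {}
    n_single = 0
    for size, fams in code.degeneracy_classes.items():
        if size == 1:
            n_single += len(fams)
            continue
        fhats = []
        for fam in fams:
            fh = _family_homozygosity([counts[c] for c in fam])
            if fh is not None:
                fhats.append(fh)
        if fhats:
            class_f[size] = sum(fhats) / len(fhats)

    if 3 not in class_f and 2 in class_f and 4 in class_f and 3 in code.degeneracy_classes:
        class_f[3] = (class_f[2] + class_f[4]) / 2.0

    if not class_f:
        return None
    total = float(n_single)
    for size, fams in code.degeneracy_classes.items():
        if size == 1:
            continue
        fbar = class_f.get(size)
        if fbar is None or fbar <= 0:
            # unobserved or fully heterozygous class: contributes its maximum
            total += len(fams) * size
        else:
            total += min(len(fams) / fbar, len(fams) * size)
    return min(total, code.enc_max)


def cai(table: CodonCountTable, reference: CodonCountTable) -> float | None:
    """Codon adaptation index of a gene against a reference usage table.

    Scale-invariant in the reference; None for an empty gene.
    """
    code = table.code
    if reference.n_sense == 0:
        raise ValueError("empty reference table")
    # relative adaptiveness from the reference, 0.5 pseudo-count for zeros
    w: dict[str, float] = {}
    for fam in code.families:
        if len(fam) < 2:
            continue
        ref = {c: (reference.counts[c] if reference.counts[c] > 0 else 0.5) for c in fam}
        top = max(ref.values())
        for c in fam:
            w[c] = ref[c] / top
    log_sum = 0.0
    n = 0
    for codon, weight in w.items():
        count = table.counts[codon]
        if count:
            log_sum += count * math.log(weight)
            n += count
    if n == 0:
        return None
    return math.exp(log_sum / n)


def bias_scores(
    table: CodonCountTable, reference: CodonCountTable, gene: str | None = None
) -> BiasScores:
    return BiasScores(gene=gene or table.source, enc=enc(table), cai=cai(table, reference))
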