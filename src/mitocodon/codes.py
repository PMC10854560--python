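"""Genetic-code tables and synonymous-family layouts.

Two tables ship by default:

* ``vertebrate_mito`` (NCBI translation table 2) — used for CDS validation
  and translation checks (AGA/AGG are stops, TGA is Trp, ATA is Met).
* ``standard`` (table 1) — the family layout used for RSCU / ENC / CAI
  bookkeeping, matching the conventions of the classic codon-usage tools
  (CodonW, EMBOSS chips/cai) that established the 59-codon RSCU set:
  all 64 codons except ATG, TGG and the three standard stops TAA/TAG/TGA.

Synonymous families partition the sense codons by encoded amino acid;
six-fold degenerate amino acids (Leu, Ser, Arg in the standard layout)
are kept as single six-member families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

from Bio.Data import CodonTable

BASES = "ACGT"
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code plus the synonymous-family layout derived from it.

    ``codon_to_aa`` covers all 64 codons; stop codons map to ``"*"``.
    ``rscu_exclusions`` is the codon set removed before building RSCU
    vectors (59 codons remain under the standard layout).
    """

    table_id: str
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    start_codons: frozenset[str]
    rscu_exclusions: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon_to_aa must cover exactly the 64 codons")

    @cached_property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c in ALL_CODONS if c not in self.stop_codons)

    @cached_property
    def families(self) -> tuple[frozenset[str], ...]:
        """Partition of sense codons into synonymous families."""
        by_aa: dict[str, set[str]] = {}
        for codon in sorted(self.sense_codons):
            by_aa.setdefault(self.codon_to_aa[codon], set()).add(codon)
        return tuple(frozenset(v) for _, v in sorted(by_aa.items()))

    @cached_property
    def family_of(self) -> dict[str, frozenset[str]]:
        return {c: fam for fam in self.families for c in fam}

    @cached_property
    def rscu_codons(self) -> tuple[str, ...]:
        """Codons carrying an RSCU value, alphabetically ordered."""
        return tuple(
            c for c in ALL_CODONS if c not in self.rscu_exclusions and c not in self.stop_codons
        )

    @cached_property
    def degeneracy_classes(self) -> dict[int, tuple[frozenset[str], ...]]:
        """Families grouped by size (ENC degeneracy classes); size-1 kept apart."""
        out: dict[int, list[frozenset[str]]] = {}
        for fam in self.families:
            out.setdefault(len(fam), []).append(fam)
        return {k: tuple(v) for k, v in sorted(out.items())}

    @cached_property
    def enc_max(self) -> float:
        """ENC under perfectly uniform usage: one per size-1 family plus
        family-count/F with F = 1/size for each class (61 for the standard layout)."""
        total = 0.0
        for size, fams in self.degeneracy_classes.items():
            total += len(fams) * (1.0 if size == 1 else size)
        return total

    def translate(self, cds: str) -> str:
        aas = []
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3].upper()
            aas.append(self.codon_to_aa.get(codon, "X"))
        return "".join(aas)


def _from_ncbi(table_id: int, name: str, rscu_exclusions: frozenset[str]) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = {c: "*" for c in table.stop_codons}
    codon_to_aa.update(table.forward_table)
    codon_to_aa = {c: codon_to_aa[c] for c in ALL_CODONS}
    return GeneticCode(
        table_id=name,
        codon_to_aa=codon_to_aa,
        stop_codons=frozenset(table.stop_codons),
        start_codons=frozenset(table.start_codons),
        rscu_exclusions=rscu_exclusions,
    )


#: Standard code (table 1); RSCU drops ATG, TGG and the three stops -> 59 codons.
STANDARD = _from_ncbi(1, "standard", frozenset({"ATG", "TGG", "TAA", "TAG", "TGA"}))

#: Vertebrate mitochondrial code (table 2); stops are TAA/TAG/AGA/AGG.
VERTEBRATE_MITO = _from_ncbi(2, "vertebrate_mito", frozenset({"TAA", "TAG", "AGA", "AGG"}))

CODES: dict[str, GeneticCode] = {
    "standard": STANDARD,
    "vertebrate_mito": VERTEBRATE_MITO,
}


def get_code(name: str) -> GeneticCode:
    try:
        return CODES[name]
    except KeyError:
        raise KeyError(f"unknown genetic code {name!r}; available: {sorted(CODES)}") from None
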