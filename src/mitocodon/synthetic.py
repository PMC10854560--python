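"""Synthetic annotated mitogenomes with known, planted structure.

The generator emulates a ~16.5 kb circular vertebrate mitogenome: 13
protein-coding genes, 22 tRNAs, 2 rRNAs, a control region carrying the
conserved motif blocks (TAS core, CSB-F/E/D, CSB-1/2/3), realistic gene
lengths (atp8 ~55 codons, nad5 ~600), the canonical vertebrate gene
order, and optionally the extra heavy-strand replication origin (OH_1)
between trnE and cob that marks the rearranged genomes, overlapping
trnE by 45 bp.

Codon bias is planted explicitly: within each synonymous family the
designated preferred codon is drawn with weight 1 + bias while every
other member has weight 1, so at bias 0 usage is uniform and at bias b a
two-fold family uses its preferred codon with expected frequency
(1+b)/(2+b). Coding sequences never contain AGA/AGG or standard stops
internally, so every generated PCG translates cleanly under the
vertebrate mitochondrial code while codon statistics use the standard
family layout. Non-coding filler is i.i.d. with base frequencies solved
so the whole genome hits the target A+T content (default 54.5%), with
mild A over T and C over G asymmetry mimicking the heavy strand.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codes import GeneticCode, STANDARD, reverse_complement
from .genome_io import GeneFeature, MitogenomeRecord

# canonical vertebrate mitochondrial gene order, H-strand forward from trnF
CANONICAL_ORDER: tuple[tuple[str, str, str], ...] = (
    ("trnF", "tRNA", "H"), ("rrnS", "rRNA", "H"), ("trnV", "tRNA", "H"),
    ("rrnL", "rRNA", "H"), ("trnL2", "tRNA", "H"), ("nad1", "PCG", "H"),
    ("trnI", "tRNA", "H"), ("trnQ", "tRNA", "L"), ("trnM", "tRNA", "H"),
    ("nad2", "PCG", "H"), ("trnW", "tRNA", "H"), ("trnA", "tRNA", "L"),
    ("trnN", "tRNA", "L"), ("OL", "origin", "H"), ("trnC", "tRNA", "L"),
    ("trnY", "tRNA", "L"), ("cox1", "PCG", "H"), ("trnS2", "tRNA", "L"),
    ("trnD", "tRNA", "H"), ("cox2", "PCG", "H"), ("trnK", "tRNA", "H"),
    ("atp8", "PCG", "H"), ("atp6", "PCG", "H"), ("cox3", "PCG", "H"),
    ("trnG", "tRNA", "H"), ("nad3", "PCG", "H"), ("trnR", "tRNA", "H"),
    ("nad4l", "PCG", "H"), ("nad4", "PCG", "H"), ("trnH", "tRNA", "H"),
    ("trnS1", "tRNA", "H"), ("trnL1", "tRNA", "H"), ("nad5", "PCG", "H"),
    ("nad6", "PCG", "L"), ("trnE", "tRNA", "L"), ("cob", "PCG", "H"),
    ("trnT", "tRNA", "H"), ("trnP", "tRNA", "L"), ("CR", "control_region", "H"),
)

# codon counts include the start codon, exclude the terminal stop
PCG_CODONS: dict[str, int] = {
    "nad1": 324, "nad2": 348, "cox1": 516, "cox2": 230, "atp8": 55,
    "atp6": 227, "cox3": 261, "nad3": 116, "nad4l": 98, "nad4": 459,
    "nad5": 612, "nad6": 173, "cob": 380,
}

_TRNA_72 = {"trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW"}
TRNA_LENGTHS: dict[str, int] = {
    name: (66 if name == "trnC" else 67 if name == "trnS1" else 72 if name in _TRNA_72 else 71)
    for name, cls, _ in CANONICAL_ORDER if cls == "tRNA"
}

REGION_LENGTHS: dict[str, int] = {"rrnS": 954, "rrnL": 1658, "CR": 890, "OL": 32}

# spacer inserted after the named feature (trnN-OL-trnC mirrors the large
# real intergenic region; trnE's spacer hosts the OH_1 extension)
SPACERS: dict[str, int] = {"trnN": 20, "OL": 11, "trnE": 10}

OH_OVERLAP = 45  # bp of OH_1 overlapping the 3' end of trnE on the forward strand
OH_EXTENSION = 10  # bp of OH_1 extending into the trnE-cob spacer

# one preferred codon per multi-codon family (standard layout); includes
# the seven most frequently optimal codons in hillstream-loach mitogenomes
DEFAULT_PLANTED_PREFERRED: dict[str, str] = {
    "L": "CTA", "V": "GTA", "P": "CCA", "Q": "CAA", "E": "GAA",
    "S": "AGC", "G": "GGC", "F": "TTC", "I": "ATC", "T": "ACA",
    "A": "GCA", "Y": "TAC", "H": "CAC", "N": "AAC", "K": "AAA",
    "D": "GAC", "C": "TGC", "R": "CGA",
}

# never emitted inside coding sequence: stops under either code layout
_FORBIDDEN_CODING = frozenset({"TAA", "TAG", "TGA", "AGA", "AGG"})

FILLER_AT_SKEW = 0.08
FILLER_GC_SKEW = -0.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic genome (or a cohort of clones)."""

    seed: int = 0
    n_genomes: int = 1
    genome_at_content: float = 54.5  # percent
    bias_strength: float = 1.5
    gene_bias: dict[str, float] = field(default_factory=dict)  # per-PCG override
    planted_preferred: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_PREFERRED)
    )
    extra_oh: bool = False
    profile_id: str = "profile0"
    code: GeneticCode = STANDARD

    def bias_for(self, gene: str) -> float:
        return self.gene_bias.get(gene, self.bias_strength)


def _coding_pool(code: GeneticCode) -> tuple[str, ...]:
    return tuple(
        c for c in code.rscu_codons if c not in _FORBIDDEN_CODING
    )


def _codon_weights(spec: SyntheticSpec, gene: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Sampling pool and weights: preferred codons carry weight 1 + bias."""
    pool = _coding_pool(spec.code)
    preferred = set(spec.planted_preferred.values())
    bias = spec.bias_for(gene)
    weights = np.array(
        [1.0 + bias if c in preferred else 1.0 for c in pool], dtype=float
    )
    return pool, weights


def _at_per_codon(pool: tuple[str, ...]) -> np.ndarray:
    return np.array([sum(b in "AT" for b in c) for c in pool], dtype=float)


def sample_gene(spec: SyntheticSpec, gene: str, rng: np.random.Generator) -> str:
    """Sample one protein-coding gene (reading direction, stop included).

    The start codon is ATG (GTG for cox1), the terminal stop TAA; internal
    codons are drawn from the weighted pool, so no internal stops arise
    under either code layout.
    """
    if gene not in PCG_CODONS:
        raise KeyError(f"{gene} is not in the protein-coding gene plan")
    pool, weights = _codon_weights(spec, gene)
    probs = weights / weights.sum()
    n_internal = PCG_CODONS[gene] - 1
    draws = rng.choice(len(pool), size=n_internal, p=probs)
    start = "GTG" if gene == "cox1" else "ATG"
    return start + "".join(pool[i] for i in draws) + "TAA"


def _filler_base_probs(at_fraction: float) -> np.ndarray:
    """Base probabilities (A,C,G,T) for non-coding filler at a given A+T fraction."""
    at = min(max(at_fraction, 0.05), 0.95)
    gc = 1.0 - at
    a = at * (1.0 + FILLER_AT_SKEW) / 2.0
    t = at - a
    g = gc * (1.0 + FILLER_GC_SKEW) / 2.0
    c = gc - g
    return np.array([a, c, g, t])


def _sample_filler(n: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    draws = rng.choice(4, size=n, p=probs)
    return "".join("ACGT"[i] for i in draws)


def _expected_coding_at(spec: SyntheticSpec) -> float:
    """Expected number of A+T bases across all coding sequence."""
    total = 0.0
    for gene, n_codons in PCG_CODONS.items():
        pool, weights = _codon_weights(spec, gene)
        probs = weights / weights.sum()
        per_codon = float(probs @ _at_per_codon(pool))
        start = "GTG" if gene == "cox1" else "ATG"
        total += (n_codons - 1) * per_codon
        total += sum(b in "AT" for b in start) + 3  # start codon + TAA
    return total


def _solve_filler_at(spec: SyntheticSpec) -> float:
    """Filler A+T fraction so that the whole genome hits the target content."""
    coding_bp = sum((n + 1) * 3 for n in PCG_CODONS.values())
    filler_bp = (
        sum(TRNA_LENGTHS.values())
        + sum(REGION_LENGTHS.values())
        + sum(SPACERS.values())
    )
    total_bp = coding_bp + filler_bp
    target_at = spec.genome_at_content / 100.0 * total_bp
    return (target_at - _expected_coding_at(spec)) / filler_bp


def build_control_region(
    length: int, probs: np.ndarray, rng: np.random.Generator
) -> str:
    """Assemble a control region with planted TAS core and CSB blocks.

    Layout: 221 bp TAS domain with a TACAT...ATGTA pair, then a 106 bp
    central conserved domain anchored by the CSB-F key sequence and
    carrying CSB-E and CSB-D, then CSB-1/CSB-2/CSB-3 with filler.
    """
    seq = list(_sample_filler(length, probs, rng))

    def plant(pos: int, motif: str) -> None:
        seq[pos : pos + len(motif)] = motif

    plant(10, "TACAT")
    plant(60, "ATGTA")
    plant(213, "ATGTAGTA")  # TAS tail leading into the CSB-F key
    plant(221, "AGAGACCACC")  # CSB-F: central domain starts here
    plant(261, "AGGGACAATAATCGTGGGGGT")  # CSB-E (GTGGG-box)
    plant(312, "TATTACTGGCATCTG")  # CSB-D
    plant(327, "TTCATCATTAAAAGACATA")  # CSB-1: CSB domain starts here
    plant(386, "CAAACCCCCTTACCCCC")  # CSB-2
    plant(443, "TGTCAAACCCCGAAACCA")  # CSB-3
    return "".join(seq)


def build_synthetic_mitogenome(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    accession: str = "SYN0001",
) -> MitogenomeRecord:
    """Generate one fully annotated synthetic mitogenome."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    probs = _filler_base_probs(_solve_filler_at(spec))

    parts: list[str] = []
    features: list[GeneFeature] = []
    cursor = 0
    trn_e_end: int | None = None

    for name, cls, strand in CANONICAL_ORDER:
        if cls == "PCG":
            reading = sample_gene(spec, name, rng)
        elif cls == "tRNA":
            reading = _sample_filler(TRNA_LENGTHS[name], probs, rng)
        elif cls == "control_region":
            reading = build_control_region(REGION_LENGTHS["CR"], probs, rng)
        else:
            reading = _sample_filler(REGION_LENGTHS[name], probs, rng)

        forward = reverse_complement(reading) if strand == "L" else reading
        start, end = cursor, cursor + len(forward)
        parts.append(forward)
        features.append(
            GeneFeature(name=name, feature_class=cls, strand=strand,
                        segments=[(start, end)])
        )
        cursor = end
        if name == "trnE":
            trn_e_end = end
        if name in SPACERS:
            parts.append(_sample_filler(SPACERS[name], probs, rng))
            cursor += SPACERS[name]

    if spec.extra_oh:
        assert trn_e_end is not None
        oh_start = trn_e_end - OH_OVERLAP
        oh_end = trn_e_end + OH_EXTENSION
        features.append(
            GeneFeature(name="OH_1", feature_class="origin", strand="H",
                        segments=[(oh_start, oh_end)])
        )

    features.sort(key=lambda f: f.start)
    return MitogenomeRecord(
        accession=accession,
        organism=f"synthetic mitogenome ({spec.profile_id})",
        sequence="".join(parts),
        features=features,
    )


def build_cohort(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> list[MitogenomeRecord]:
    """n_genomes independent genomes sharing one spec (one usage profile)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return [
        build_synthetic_mitogenome(spec, rng, accession=f"SYN-{spec.profile_id}-{i:02d}")
        for i in range(spec.n_genomes)
    ]


def planted_truth_report(
    spec: SyntheticSpec,
    high_genes: tuple[str, ...] | None = None,
    low_genes: tuple[str, ...] | None = None,
) -> dict:
    """Ground truth for comparing pipeline output against the generator.

    The true optimal-codon set is the planted preferred codons whenever
    the high-expression genes carry strictly more bias than the
    low-expression genes; with no bias differential it is empty.
    """
    if high_genes and low_genes:
        bias_high = min(spec.bias_for(g) for g in high_genes)
        bias_low = max(spec.bias_for(g) for g in low_genes)
        differential = bias_high > bias_low
    else:
        biases = {spec.bias_for(g) for g in PCG_CODONS}
        differential = len(biases) > 1 and max(biases) > 0
    preferred = tuple(sorted(set(spec.planted_preferred.values())))
    return {
        "profile_id": spec.profile_id,
        "planted_preferred": dict(spec.planted_preferred),
        "true_optimal_codons": preferred if differential else (),
        "extra_oh": spec.extra_oh,
        "gene_bias": {g: spec.bias_for(g) for g in PCG_CODONS},
    }


def two_profile_specs(
    seed: int, n_per_profile: int = 6, bias: float = 3.0
) -> tuple[SyntheticSpec, SyntheticSpec]:
    """Two cohorts with divergent planted codon preferences (cluster tests).

    Profile B prefers a different member in every family that has one
    (the alphabetically next codon), giving RSCU separation proportional
    to the bias.
    """
    base = SyntheticSpec(seed=seed, n_genomes=n_per_profile, bias_strength=bias,
                         profile_id="profileA")
    pool = set(_coding_pool(base.code))
    alt: dict[str, str] = {}
    for aa, codon in DEFAULT_PLANTED_PREFERRED.items():
        family = sorted(c for c in base.code.family_of[codon] if c in pool)
        idx = family.index(codon)
        alt[aa] = family[(idx + 1) % len(family)]
    other = replace(base, seed=seed + 1, planted_preferred=alt, profile_id="profileB")
    return base, other
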