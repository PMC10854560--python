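"""Control-region motif scanning and domain partitioning.

The vertebrate mitochondrial control region divides into three domains:
the termination-associated sequence (TAS, carrying the TACAT core and
its reverse complement ATGTA), the central conserved domain (CSB-F,
CSB-E with its GTGGG-box, CSB-D), and the conserved sequence block
domain (CSB-1/2/3). CSB-F and CSB-1 anchor the domain boundaries.

Default motif patterns are the consensus key sequences for these blocks
in hillstream-loach mitogenomes; mismatch allowances reflect the
reported inter-species variants (2 for CSB-E, 1 for CSB-2, 0 elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    pattern: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern.upper()) - set("ACGT"):
            raise ValueError(f"motif {self.name}: pattern must be non-empty over ACGT")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 0-based offset in the scanned region
    mismatches: int
    matched_seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_seq)


@dataclass(frozen=True)
class TASPair:
    tacat_start: int
    atgta_start: int

    @property
    def distance(self) -> int:
        """Bases between the end of TACAT and the start of ATGTA."""
        return self.atgta_start - (self.tacat_start + 5)


@dataclass(frozen=True)
class CRPartition:
    """Contiguous [start, end) domains tiling the control region."""

    tas: tuple[int, int]
    central: tuple[int, int]
    csb: tuple[int, int]

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        return (self.tas, self.central, self.csb)


class PartitionError(ValueError):
    """Raised when a boundary-anchor motif is absent."""


DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("CSB-F", "AGAGACCACC", 0),
    MotifDefinition("CSB-E", "AGGGACAATAATCGTGGGGGT", 2),  # GTGGG-box, species variants
    MotifDefinition("CSB-D", "TATTACTGGCATCTG", 0),
    MotifDefinition("CSB-1", "TTCATCATTAAAAGACATA", 0),
    MotifDefinition("CSB-2", "CAAACCCCCTTACCCCC", 1),
    MotifDefinition("CSB-3", "TGTCAAACCCCGAAACCA", 0),
)


def load_motifs_tsv(path: str | Path) -> tuple[MotifDefinition, ...]:
    """Load motif definitions from a TSV with columns name, pattern, max_mismatch."""
    motifs = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            motifs.append(MotifDefinition(fields[0], fields[1].upper(), int(fields[2])))
    return tuple(motifs)


def scan_motif(region: str, motif: MotifDefinition) -> list[MotifHit]:
    """All Hamming-distance hits of a motif, sorted by (mismatches, start).

    A pattern longer than the region yields an empty result.
    """
    if not region:
        raise ValueError("empty region")
    region = region.upper()
    pattern = motif.pattern.upper()
    m = len(pattern)
    hits = []
    for start in range(len(region) - m + 1):
        window = region[start : start + m]
        mismatches = sum(1 for a, b in zip(window, pattern) if a != b)
        if mismatches <= motif.max_mismatch:
            hits.append(MotifHit(motif.name, start, mismatches, window))
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def find_tas_core(region: str) -> list[TASPair]:
    """All (TACAT, ATGTA) pairs with TACAT upstream of ATGTA."""
    region = region.upper()
    tacats = [i for i in range(len(region) - 4) if region[i : i + 5] == "TACAT"]
    atgtas = [i for i in range(len(region) - 4) if region[i : i + 5] == "ATGTA"]
    return [
        TASPair(t, a) for t in tacats for a in atgtas if a >= t + 5
    ]


def _best_hit(region: str, motifs: dict[str, MotifDefinition], name: str) -> MotifHit:
    if name not in motifs:
        raise PartitionError(f"no definition for anchor motif {name}")
    hits = scan_motif(region, motifs[name])
    if not hits:
        raise PartitionError(f"anchor motif {name} not found in control region")
    return hits[0]  # fewest mismatches, then leftmost


def partition_control_region(
    region: str, motifs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS
) -> CRPartition:
    """Partition a control region at its CSB-F and CSB-1 anchors.

    TAS = [0, CSB-F start); central = [CSB-F start, CSB-1 start);
    CSB = [CSB-1 start, end). The intervals tile the region exactly.
    """
    by_name = {m.name: m for m in motifs}
    csb_f = _best_hit(region, by_name, "CSB-F")
    csb_1 = _best_hit(region, by_name, "CSB-1")
    if csb_1.start < csb_f.start:
        raise PartitionError("CSB-1 hit precedes CSB-F hit; region not partitionable")
    return CRPartition(
        tas=(0, csb_f.start),
        central=(csb_f.start, csb_1.start),
        csb=(csb_1.start, len(region)),
    )


def hits_to_bed(hits: list[MotifHit], region_name: str = "CR") -> str:
    """BED-like TSV (0-based half-open, relative to the control region)."""
    lines = ["#region\tstart\tend\tmotif\tmismatches"]
    for hit in hits:
        lines.append(f"{region_name}\t{hit.start}\t{hit.end}\t{hit.motif}\t{hit.mismatches}")
    return "\n".join(lines) + "\n"
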