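"""Reading and writing annotated mitogenomes.

Internal coordinates are 0-based half-open on the forward strand; GenBank
I/O stays 1-based inclusive (Biopython performs the conversion). Features
wrapping the circular origin are represented as two segments; sequence
access never wraps implicitly.

Gene labels are normalized to a canonical vocabulary (nad1..nad6, nad4l,
cox1-3, atp6, atp8, cob, trnX with trnL1/trnL2/trnS1/trnS2 split by
codon family, rrnS, rrnL, CR, OL, OH_1). The two leucine / serine tRNAs
follow the vertebrate convention: trnL2 = Leu(UUR) (between rrnL and
nad1), trnL1 = Leu(CUN); trnS1 = Ser(AGY) (the D-arm-less one),
trnS2 = Ser(UCN).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codes import GeneticCode, reverse_complement

PCG_NAMES = (
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cob",
)
TRNA_NAMES = (
    "trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA",
    "trnN", "trnC", "trnY", "trnS2", "trnD", "trnK", "trnG", "trnR",
    "trnH", "trnS1", "trnL1", "trnE", "trnT", "trnP",
)
RRNA_NAMES = ("rrnS", "rrnL")

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control_region", "origin", "other")


class ParseError(ValueError):
    """Raised when an annotation file cannot be read."""


class MissingFeatureError(KeyError):
    """Raised when a named feature is absent from a record."""


@dataclass
class GeneFeature:
    """One annotated gene or region.

    ``segments`` is an ordered list of [start, end) intervals on the
    forward strand; strand ``"L"`` means the biological sequence is the
    reverse complement of the concatenated forward slice.
    """

    name: str
    feature_class: str
    strand: str
    segments: list[tuple[int, int]]
    raw_name: str | None = None
    mapped: bool = True

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"feature {self.name}: segments must be non-empty")
        if self.strand not in ("H", "L"):
            raise ValueError(f"feature {self.name}: strand must be H or L")
        for start, end in self.segments:
            if not 0 <= start < end:
                raise ValueError(f"feature {self.name}: bad interval [{start}, {end})")

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass
class MitogenomeRecord:
    """One annotated circular mitochondrial genome."""

    accession: str
    organism: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for feat in self.features:
            if feat.end > n:
                raise ValueError(
                    f"feature {feat.name} extends past genome length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def get_feature(self, name: str) -> GeneFeature:
        for feat in self.features:
            if feat.name == name:
                return feat
        raise MissingFeatureError(f"no feature named {name!r} in {self.accession}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def features_of_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.features_of_class("PCG")


# --- gene-name canonicalization -------------------------------------------

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

_PCG_ALIASES = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad4l": "nad4l", "nad5": "nad5", "nad6": "nad6",
    "nadh1": "nad1", "nadh2": "nad2", "nadh3": "nad3", "nadh4": "nad4",
    "nadh4l": "nad4l", "nadh5": "nad5", "nadh6": "nad6",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "cytb": "cob", "cyb": "cob", "cob": "cob", "cytochromeb": "cob",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
}

_MISC_ALIASES = {
    "12s": "rrnS", "12srrna": "rrnS", "12sribosomalrna": "rrnS",
    "rrn12": "rrnS", "srrna": "rrnS", "rrns": "rrnS",
    "smallsubunitribosomalrna": "rrnS",
    "16s": "rrnL", "16srrna": "rrnL", "16sribosomalrna": "rrnL",
    "rrn16": "rrnL", "lrrna": "rrnL", "rrnl": "rrnL",
    "largesubunitribosomalrna": "rrnL",
    "dloop": "CR", "controlregion": "CR", "cr": "CR",
    "ol": "OL", "oril": "OL", "originoflstrandreplication": "OL",
    "lstrandorigin": "OL", "replicationoriginl": "OL",
    "oh": "OH", "orih": "OH", "hstrandorigin": "OH",
    "originofhstrandreplication": "OH", "replicationoriginh": "OH",
}

# spellings used for full-gene-name CDS products in deposited records
_PRODUCT_ALIASES = {
    "cytochromecoxidasesubuniti": "cox1",
    "cytochromecoxidasesubunitii": "cox2",
    "cytochromecoxidasesubunitiii": "cox3",
    "cytochromecoxidasesubunit1": "cox1",
    "cytochromecoxidasesubunit2": "cox2",
    "cytochromecoxidasesubunit3": "cox3",
    "cytochromeb": "cob",
    "atpsynthasef0subunit6": "atp6",
    "atpsynthasef0subunit8": "atp8",
    "nadhdehydrogenasesubunit1": "nad1",
    "nadhdehydrogenasesubunit2": "nad2",
    "nadhdehydrogenasesubunit3": "nad3",
    "nadhdehydrogenasesubunit4": "nad4",
    "nadhdehydrogenasesubunit4l": "nad4l",
    "nadhdehydrogenasesubunit5": "nad5",
    "nadhdehydrogenasesubunit6": "nad6",
}

_TRNA_RE = re.compile(
    r"^(?:trn|trna)[\s\-_]*([a-z]{1,3})\s*([12])?\s*(?:\(([a-z]{3,4})\))?$"
)


def _leu_isoform(hint: str | None, anticodon_or_codon: str | None) -> str:
    tag = (anticodon_or_codon or "").lower()
    if hint == "1" or tag in ("cun", "tag"):
        return "trnL1"
    if hint == "2" or tag in ("uur", "taa", "uaa"):
        return "trnL2"
    return "trnL2"  # ambiguous Leu defaults to the rrnL-adjacent copy


def _ser_isoform(hint: str | None, anticodon_or_codon: str | None) -> str:
    tag = (anticodon_or_codon or "").lower()
    if hint == "1" or tag in ("agy", "gct", "gcu"):
        return "trnS1"
    if hint == "2" or tag in ("ucn", "tga", "uga"):
        return "trnS2"
    return "trnS2"


def canonicalize_gene_name(raw_label: str, feature_class: str | None = None) -> tuple[str, bool]:
    """Map a raw annotation label to the canonical vocabulary.

    Returns ``(name, mapped)``; unknown labels come back unchanged with
    ``mapped=False`` (lossless fallback).
    """
    label = raw_label.strip()
    squashed = re.sub(r"[\s\-_()'.]", "", label).lower()

    if feature_class in (None, "tRNA"):
        m = _TRNA_RE.match(label.strip().lower().replace("_", "-"))
        if m:
            aa, hint, tag = m.groups()
            one = _AA3_TO_1.get(aa, aa.upper() if len(aa) == 1 else None)
            if one == "L":
                return _leu_isoform(hint, tag), True
            if one == "S":
                return _ser_isoform(hint, tag), True
            if one in _AA3_TO_1.values():
                return f"trn{one}", True

    for table in (_PCG_ALIASES, _MISC_ALIASES, _PRODUCT_ALIASES):
        if squashed in table:
            return table[squashed], True
    return raw_label, False


# --- GenBank / FASTA parsing ----------------------------------------------

_GENBANK_TYPE_TO_CLASS = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
    "rep_origin": "origin",
}


def _feature_label(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def _location_segments(feat: SeqFeature) -> list[tuple[int, int]]:
    parts = feat.location.parts if isinstance(feat.location, CompoundLocation) else [feat.location]
    return [(int(p.start), int(p.end)) for p in parts]


def _classify_misc(feat: SeqFeature) -> str | None:
    text = " ".join(str(v[0]) for v in feat.qualifiers.values() if v).lower()
    if "control region" in text or "d-loop" in text:
        return "control_region"
    if "origin" in text:
        return "origin"
    return None


def _unique_names(features: list[GeneFeature]) -> list[GeneFeature]:
    """Enforce unique names; replication origins named OH are suffixed _1, _2, ..."""
    seen: dict[str, int] = {}
    out = []
    for feat in features:
        base = feat.name
        if base == "OH":
            seen[base] = seen.get(base, 0) + 1
            feat.name = f"OH_{seen[base]}"
        elif base in seen:
            seen[base] += 1
            feat.name = f"{base}_{seen[base]}"
        else:
            seen[base] = 1
        out.append(feat)
    return out


def parse_genbank_record(path: str | Path) -> MitogenomeRecord:
    """Read a GenBank flat file into a :class:`MitogenomeRecord`.

    Gene/CDS pairs are deduplicated (the typed feature wins); unmapped
    labels trigger a warning and are kept under their raw name.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise ParseError(f"{path}: malformed GenBank file ({exc})") from exc

    features: list[GeneFeature] = []
    for feat in rec.features:
        cls = _GENBANK_TYPE_TO_CLASS.get(feat.type)
        if cls is None and feat.type == "misc_feature":
            cls = _classify_misc(feat)
        if cls is None:
            continue
        raw = _feature_label(feat)
        name, mapped = canonicalize_gene_name(raw, cls)
        if cls == "control_region":
            name, mapped = "CR", True
        if not mapped:
            warnings.warn(f"{path.name}: unmapped gene label {raw!r} kept as-is")
        features.append(
            GeneFeature(
                name=name,
                feature_class=cls,
                strand="L" if feat.location.strand == -1 else "H",
                segments=_location_segments(feat),
                raw_name=raw,
                mapped=mapped,
            )
        )

    organism = rec.annotations.get("organism", rec.description or rec.id)
    return MitogenomeRecord(
        accession=rec.id or path.stem,
        organism=organism,
        sequence=str(rec.seq),
        features=_unique_names(features),
    )


def read_fasta_with_features(fasta_path: str | Path, table_path: str | Path) -> MitogenomeRecord:
    """Read the FASTA + feature-table dialect.

    The table is tab-separated with columns name, class, strand, start,
    end (1-based inclusive); a header line is permitted.
    """
    fasta_path, table_path = Path(fasta_path), Path(table_path)
    try:
        rec = SeqIO.read(str(fasta_path), "fasta")
    except Exception as exc:
        raise ParseError(f"{fasta_path}: malformed FASTA ({exc})") from exc

    features: list[GeneFeature] = []
    with open(table_path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["name", "class"]:
                continue
            if len(fields) < 5:
                raise ParseError(f"{table_path}:{lineno}: expected 5 columns, got {len(fields)}")
            name, cls, strand, start, end = fields[:5]
            try:
                seg = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
            except ValueError as exc:
                raise ParseError(f"{table_path}:{lineno}: non-integer coordinate") from exc
            canon, mapped = canonicalize_gene_name(name, cls)
            features.append(
                GeneFeature(name=canon, feature_class=cls, strand=strand,
                            segments=[seg], raw_name=name, mapped=mapped)
            )
    return MitogenomeRecord(
        accession=rec.id, organism=rec.description, sequence=str(rec.seq),
        features=_unique_names(features),
    )


def write_feature_table(record: MitogenomeRecord, path: str | Path) -> None:
    """Write the normalized feature table as TSV (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        handle.write("name\tclass\tstrand\tstart\tend\n")
        for feat in record.features:
            for start, end in feat.segments:
                handle.write(
                    f"{feat.name}\t{feat.feature_class}\t{feat.strand}\t{start + 1}\t{end}\n"
                )


def to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    """Convert back to a Biopython SeqRecord (for GenBank export)."""
    _CLASS_TO_TYPE = {
        "PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
        "control_region": "D-loop", "origin": "rep_origin", "other": "misc_feature",
    }
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=record.organism,
        annotations={"molecule_type": "DNA", "topology": "circular",
                     "organism": record.organism},
    )
    for feat in record.features:
        strand = -1 if feat.strand == "L" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in feat.segments]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        label = feat.name.split("_")[0] if feat.name.startswith("OH_") else feat.name
        rec.features.append(
            SeqFeature(location, type=_CLASS_TO_TYPE[feat.feature_class],
                       qualifiers={"gene": [label]})
        )
    return rec


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    SeqIO.write(to_seqrecord(record), str(path), "genbank")


# --- sequence access and CDS validation -----------------------------------

def extract_gene_sequence(record: MitogenomeRecord, name: str) -> str:
    """Reading-direction sequence of a named feature.

    Segments are concatenated in order; L-strand features are returned as
    the reverse complement of the concatenated forward slice.
    """
    feat = record.get_feature(name)
    forward = "".join(record.sequence[s:e] for s, e in feat.segments)
    return reverse_complement(forward) if feat.strand == "L" else forward


@dataclass
class CdsValidation:
    """Report from :func:`validate_cds`."""

    start_codon: str
    stop_type: str  # TAA / TAG / AGA / AGG / "T--" / "TA-" / "none"
    internal_stops: int
    trailing_partial: int
    length: int
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.internal_stops == 0 and self.stop_type != "none" and not self.flags


def validate_cds(cds: str, code: GeneticCode) -> CdsValidation:
    """Classify start/stop codons and count in-frame internal stops.

    Incomplete terminal stops (length mod 3 of 1 or 2 ending in T / TA)
    are reported as ``"T--"`` / ``"TA-"``, the polyadenylation-completed
    stops typical of vertebrate mitochondrial CDS annotations.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    flags: list[str] = []
    remainder = len(cds) % 3
    start = cds[:3]
    if start not in code.start_codons:
        flags.append(f"unusual start codon {start}")

    complete = [cds[i : i + 3] for i in range(0, len(cds) - remainder, 3)]
    if remainder == 0:
        last = complete[-1]
        stop_type = last if last in code.stop_codons else "none"
        internal_codons = complete[1:-1]  # between start and terminal position
    else:
        tail = cds[-remainder:]
        if remainder == 1 and tail == "T":
            stop_type = "T--"
        elif remainder == 2 and tail == "TA":
            stop_type = "TA-"
        else:
            stop_type = "none"
            flags.append(f"trailing {remainder} base(s) {tail!r} not a partial stop")
        internal_codons = complete[1:]

    internal = sum(1 for c in internal_codons if c in code.stop_codons)
    if stop_type == "none":
        flags.append("no terminal stop codon")
    return CdsValidation(
        start_codon=start,
        stop_type=stop_type,
        internal_stops=internal,
        trailing_partial=remainder,
        length=len(cds),
        flags=flags,
    )
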