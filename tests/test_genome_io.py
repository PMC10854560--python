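import pytest
from hypothesis import given, settings, strategies as st

from mitocodon.codes import VERTEBRATE_MITO, reverse_complement
from mitocodon.genome_io import (
    GeneFeature, MissingFeatureError, MitogenomeRecord, ParseError,
    canonicalize_gene_name, extract_gene_sequence, parse_genbank_record,
    read_fasta_with_features, validate_cds, write_feature_table, write_genbank,
)

MINIMAL_GENBANK = """\
LOCUS       TEST1                     30 bp    DNA     circular VRT 01-JAN-2024
DEFINITION  toy record.
ACCESSION   TEST1
FEATURES             Location/Qualifiers
     CDS             1..6
                     /gene="ND1"
     tRNA            complement(10..20)
                     /product="tRNA-Phe"
ORIGIN
        1 atgaaataaa cgtacgtacg tacgtacgta
//
"""


def test_genbank_coordinate_convention(tmp_path):
    """1-based inclusive GenBank spans become 0-based half-open segments;
    complement locations yield strand L."""
    path = tmp_path / "toy.gb"
    path.write_text(MINIMAL_GENBANK)
    rec = parse_genbank_record(path)
    nd1 = rec.get_feature("nad1")
    assert nd1.segments == [(0, 6)]
    assert nd1.strand == "H"
    trnf = rec.get_feature("trnF")
    assert trnf.segments == [(9, 20)]
    assert trnf.strand == "L"


def test_malformed_genbank_raises_parse_error(tmp_path):
    path = tmp_path / "bad.gb"
    path.write_text("this is not a genbank file\n")
    with pytest.raises(ParseError, match="bad.gb"):
        parse_genbank_record(path)


def test_genbank_round_trip_preserves_annotation(default_record, tmp_path):
    """Write -> parse returns the identical coordinates, strands and names."""
    path = tmp_path / "syn.gb"
    write_genbank(default_record, path)
    reread = parse_genbank_record(path)
    assert len(reread) == len(default_record)
    assert reread.sequence == default_record.sequence
    original = {(f.name, f.strand, tuple(f.segments)) for f in default_record.features}
    parsed = {(f.name, f.strand, tuple(f.segments)) for f in reread.features}
    assert parsed == original


def test_fasta_feature_table_round_trip(default_record, tmp_path):
    fasta = tmp_path / "syn.fa"
    table = tmp_path / "syn.tsv"
    fasta.write_text(f">{default_record.accession} synthetic\n{default_record.sequence}\n")
    write_feature_table(default_record, table)
    reread = read_fasta_with_features(fasta, table)
    assert reread.sequence == default_record.sequence
    assert {f.name for f in reread.features} == {f.name for f in default_record.features}


@pytest.mark.parametrize(
    "raw,cls,expected,mapped",
    [
        ("ND4L", "PCG", "nad4l", True),
        ("CYTB", "PCG", "cob", True),
        ("cytochrome b", "PCG", "cob", True),
        ("COI", "PCG", "cox1", True),
        ("ATPase6", "PCG", "atp6", True),
        ("tRNA-Leu(UUR)", "tRNA", "trnL2", True),
        ("tRNA-Leu(CUN)", "tRNA", "trnL1", True),
        ("trnL(tag)", "tRNA", "trnL1", True),
        ("tRNA-Ser(AGY)", "tRNA", "trnS1", True),
        ("trnS(tga)", "tRNA", "trnS2", True),
        ("tRNA-Phe", "tRNA", "trnF", True),
        ("12S ribosomal RNA", "rRNA", "rrnS", True),
        ("16S", "rRNA", "rrnL", True),
        ("D-loop", "control_region", "CR", True),
        ("OriL", "origin", "OL", True),
        ("mystery gene", "PCG", "mystery gene", False),
    ],
)
def test_canonicalize_gene_name(raw, cls, expected, mapped):
    assert canonicalize_gene_name(raw, cls) == (expected, mapped)


def test_extract_gene_sequence_by_strand(toy_record):
    assert extract_gene_sequence(toy_record, "geneA") == "ATGCCC"
    # L strand: reverse complement of the forward slice GGGTTT
    assert extract_gene_sequence(toy_record, "geneB") == "AAACCC"
    with pytest.raises(MissingFeatureError):
        extract_gene_sequence(toy_record, "geneC")


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    seq=st.text(alphabet="ACGT", min_size=10, max_size=80),
    data=st.data(),
)
def test_l_strand_extraction_is_reverse_complement(seq, data):
    """For any interval, L-strand extraction equals revcomp of the slice."""
    start = data.draw(st.integers(0, len(seq) - 2))
    end = data.draw(st.integers(start + 1, len(seq)))
    rec = MitogenomeRecord(
        accession="X", organism="x", sequence=seq,
        features=[GeneFeature("g", "other", "L", [(start, end)])],
    )
    assert extract_gene_sequence(rec, "g") == reverse_complement(seq[start:end])


@pytest.mark.parametrize(
    "cds,start,stop,internal,partial",
    [
        ("ATGAAATAA", "ATG", "TAA", 0, 0),
        ("ATGAAATAG", "ATG", "TAG", 0, 0),
        ("ATGAAAT", "ATG", "T--", 0, 1),
        ("ATGAAATA", "ATG", "TA-", 0, 2),
        ("GTGAAATAA", "GTG", "TAA", 0, 0),
        ("ATGTAAAAATAA", "ATG", "TAA", 1, 0),  # one in-frame internal stop
        ("ATGAGAAAATAA", "ATG", "TAA", 1, 0),  # AGA is a stop in vertebrate mito
        ("ATGAAACCC", "ATG", "none", 0, 0),
    ],
)
def test_validate_cds(cds, start, stop, internal, partial):
    report = validate_cds(cds, VERTEBRATE_MITO)
    assert report.start_codon == start
    assert report.stop_type == stop
    assert report.internal_stops == internal
    assert report.trailing_partial == partial


def test_validate_cds_rejects_subcodon_input():
    with pytest.raises(ValueError):
        validate_cds("AT", VERTEBRATE_MITO)


def test_all_synthetic_pcgs_validate_cleanly(default_record):
    """Every generated PCG translates without internal stops under the
    vertebrate mito code; cox1 starts with GTG, the rest with ATG."""
    for feat in default_record.pcgs:
        cds = extract_gene_sequence(default_record, feat.name)
        report = validate_cds(cds, VERTEBRATE_MITO)
        assert report.internal_stops == 0
        assert report.stop_type == "TAA"
        expected_start = "GTG" if feat.name == "cox1" else "ATG"
        assert report.start_codon == expected_start
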