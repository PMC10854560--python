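import numpy as np
import pytest

from mitocodon.genome_io import extract_gene_sequence
from mitocodon.motifs import (
    DEFAULT_MOTIFS, CRPartition, MotifDefinition, PartitionError, find_tas_core,
    hits_to_bed, load_motifs_tsv, partition_control_region, scan_motif,
)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# --- scanning --------------------------------------------------------------

def test_exact_hit_and_self_match():
    motif = MotifDefinition("CSB-F", "AGAGACCACC", 0)
    region = "TTTT" + motif.pattern + "GGGG"
    hits = scan_motif(region, motif)
    assert len(hits) == 1 and hits[0].start == 4 and hits[0].mismatches == 0
    assert scan_motif(motif.pattern, motif)[0].start == 0


def test_hamming_mismatch_hand_case():
    hits = scan_motif("AATA", MotifDefinition("m", "AAAA", 1))
    assert len(hits) == 1
    assert hits[0].mismatches == 1 and hits[0].matched_seq == "AATA"


def test_pattern_longer_than_region_is_empty():
    assert scan_motif("ACG", MotifDefinition("m", "ACGTACGT", 2)) == []


def test_hits_sorted_by_mismatches_then_position():
    motif = MotifDefinition("m", "AAAA", 1)
    hits = scan_motif("AATAAAAA", motif)
    assert [(h.mismatches, h.start) for h in hits] == sorted(
        (h.mismatches, h.start) for h in hits
    )
    assert hits[0].mismatches == 0


def test_zero_mismatch_scan_agrees_with_substring_search():
    """Brute-force oracle: exact scanning equals naive substring search."""
    rng = np.random.default_rng(99)
    for _ in range(50):
        region = random_dna(rng, 300)
        pattern = random_dna(rng, int(rng.integers(3, 8)))
        motif = MotifDefinition("m", pattern, 0)
        expected = [
            i for i in range(len(region) - len(pattern) + 1)
            if region[i : i + len(pattern)] == pattern
        ]
        assert [h.start for h in scan_motif(region, motif)] == expected


# --- TAS core --------------------------------------------------------------

def test_tas_pair_with_intervening_distance():
    pairs = find_tas_core("TACAT" + "G" * 5 + "ATGTA")
    assert len(pairs) == 1
    assert pairs[0].distance == 5


def test_tas_requires_downstream_reverse_complement():
    assert find_tas_core("TACATGGGG") == []
    assert find_tas_core("ATGTAGGGGTACAT") == []  # ATGTA upstream only


# --- partitioning ----------------------------------------------------------

def test_partition_tiles_synthetic_construction():
    rng = np.random.default_rng(5)
    tas = random_dna(rng, 221).replace("AGAGACCACC", "AGAGACCATT")
    region = (
        tas + "AGAGACCACC" + random_dna(rng, 80)
        + "TTCATCATTAAAAGACATA" + random_dna(rng, 120)
    )
    part = partition_control_region(region)
    assert part.tas == (0, 221)
    lengths = [end - start for start, end in part.intervals]
    assert sum(lengths) == len(region)


def test_partition_with_anchor_at_origin_gives_empty_tas():
    region = "AGAGACCACC" + "ACGT" * 10 + "TTCATCATTAAAAGACATA" + "ACGT" * 5
    part = partition_control_region(region)
    assert part.tas == (0, 0)
    assert part.central[0] == 0


def test_partition_error_names_missing_anchor():
    with pytest.raises(PartitionError, match="CSB-1"):
        partition_control_region("AGAGACCACC" + "ACGT" * 30)
    with pytest.raises(PartitionError, match="CSB-F"):
        partition_control_region("ACGT" * 30)


def test_partition_tiling_on_random_constructions():
    """500 random CR constructions: the three domains tile exactly."""
    rng = np.random.default_rng(2024)
    for _ in range(500):
        pre = random_dna(rng, int(rng.integers(0, 250)))
        mid = random_dna(rng, int(rng.integers(0, 150)))
        post = random_dna(rng, int(rng.integers(0, 300)))
        region = pre + "AGAGACCACC" + mid + "TTCATCATTAAAAGACATA" + post
        try:
            part = partition_control_region(region)
        except PartitionError:
            # a chance upstream CSB-1 may precede CSB-F; ordering is enforced
            continue
        starts = [s for s, _ in part.intervals]
        ends = [e for _, e in part.intervals]
        assert starts == [0, part.tas[1], part.central[1]]
        assert ends[-1] == len(region)
        assert sum(e - s for s, e in part.intervals) == len(region)


# --- defaults on the generated control region ------------------------------

def test_default_motifs_found_in_synthetic_cr(default_record):
    region = extract_gene_sequence(default_record, "CR")
    part = partition_control_region(region)
    assert part.tas == (0, 221)
    assert part.central == (221, 327)  # 106 bp central conserved domain
    for motif in DEFAULT_MOTIFS:
        hits = scan_motif(region, motif)
        assert hits and hits[0].mismatches == 0, motif.name
    assert find_tas_core(region[: part.tas[1]])  # TACAT...ATGTA inside TAS


def test_motif_tsv_round_trip(tmp_path):
    path = tmp_path / "motifs.tsv"
    path.write_text(
        "name\tpattern\tmax_mismatch\n"
        + "".join(f"{m.name}\t{m.pattern}\t{m.max_mismatch}\n" for m in DEFAULT_MOTIFS)
    )
    assert load_motifs_tsv(path) == DEFAULT_MOTIFS


def test_bed_output_schema():
    motif = MotifDefinition("m", "ACGT", 0)
    text = hits_to_bed(scan_motif("ACGTACGT", motif), region_name="CR")
    lines = text.strip().split("\n")
    assert lines[0].startswith("#region")
    assert lines[1].split("\t") == ["CR", "0", "4", "m", "0"]
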