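import math

import numpy as np
import pytest

from mitocodon.codes import ALL_CODONS, STANDARD
from mitocodon.codon_stats import (
    CodonCountTable, _family_homozygosity, cai, count_codons, enc, rscu,
)


def table_from(counts, code=STANDARD, source="t"):
    return CodonCountTable(source=source, code=code, counts=dict(counts))


def random_table(rng, max_count=30):
    counts = {c: int(rng.integers(0, max_count)) for c in sorted(STANDARD.sense_codons)}
    return table_from(counts)


# --- independent oracles ---------------------------------------------------

def rscu_oracle(table):
    """Direct per-family recomputation: count * size / family total."""
    out = {}
    for fam in table.code.families:
        total = sum(table.counts[c] for c in fam)
        for c in fam:
            out[c] = table.counts[c] * len(fam) / total if total else 0.0
    return out


def enc_oracle(table):
    """Literal Wright formula with class averages, written independently."""
    classes = {}
    for fam in table.code.families:
        classes.setdefault(len(fam), []).append([table.counts[c] for c in fam])
    fbar = {}
    for size, fams in classes.items():
        if size == 1:
            continue
        vals = []
        for counts in fams:
            n = sum(counts)
            if n >= 2:
                vals.append((n * sum((x / n) ** 2 for x in counts) - 1) / (n - 1))
        if vals:
            fbar[size] = sum(vals) / len(vals)
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    total = len(classes.get(1, []))
    for size, fams in classes.items():
        if size == 1:
            continue
        f = fbar.get(size)
        if f is None or f <= 0:
            total += len(fams) * size
        else:
            total += min(len(fams) / f, len(fams) * size)
    return min(total, table.code.enc_max)


# --- counting --------------------------------------------------------------

def test_count_codons_separates_stops_and_ambiguous():
    table = count_codons("ATGAAATAA", STANDARD)
    assert table.counts["ATG"] == 1 and table.counts["AAA"] == 1
    assert table.counts["TAA"] == 1
    assert "TAA" not in table.sense_counts
    assert table.skipped == 0

    table = count_codons("ATGNNNAAA", STANDARD)
    assert table.counts["ATG"] == 1 and table.counts["AAA"] == 1
    assert table.skipped == 1
    assert table.total_scanned == 3


def test_count_codons_ignores_trailing_partial():
    assert count_codons("ATGAA", STANDARD).total_scanned == 1


# --- RSCU ------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        ({"GAA": 2, "GAG": 2}, {"GAA": 1.0, "GAG": 1.0}),
        ({"GAA": 4, "GAG": 0}, {"GAA": 2.0, "GAG": 0.0}),
        ({"GAA": 3, "GAG": 1}, {"GAA": 1.5, "GAG": 0.5}),
    ],
)
def test_rscu_two_fold_family_hand_cases(counts, expected):
    vec = rscu(table_from(counts))
    for codon, value in expected.items():
        assert vec[codon] == pytest.approx(value)


def test_rscu_zero_families_flagged():
    vec = rscu(table_from({"GAA": 1}))
    assert vec["GAA"] == 2.0
    assert any("TTT" in fam for fam in vec.zero_families)  # Phe family unused


def test_rscu_family_sums_equal_family_size_on_random_tables():
    """Conservation law checked against the brute-force oracle, 1000 tables."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        table = random_table(rng)
        vec = rscu(table)
        oracle = rscu_oracle(table)
        assert all(vec[c] == pytest.approx(oracle[c]) for c in STANDARD.rscu_codons)
        for fam in STANDARD.families:
            if len(fam) < 2:
                continue
            total = sum(table.counts[c] for c in fam)
            fam_sum = sum(vec[c] for c in fam)
            assert fam_sum == pytest.approx(len(fam) if total else 0.0)


# --- ENC -------------------------------------------------------------------

def test_enc_uniform_usage_is_61():
    vec = table_from({c: 100 for c in STANDARD.sense_codons})
    assert enc(vec) == pytest.approx(61.0)


def test_enc_single_codon_per_family_is_20():
    counts = {min(fam): 100 for fam in STANDARD.families}
    assert enc(table_from(counts)) == pytest.approx(20.0)


def test_family_homozygosity_hand_case():
    # counts (3,1): F = (4 * 0.625 - 1) / 3 = 0.5
    assert _family_homozygosity([3, 1]) == pytest.approx(0.5)
    assert _family_homozygosity([1]) is None


def test_enc_matches_oracle_on_random_tables():
    rng = np.random.default_rng(7)
    for _ in range(200):
        table = random_table(rng)
        assert enc(table) == pytest.approx(enc_oracle(table))


def test_enc_invariant_to_relabeling_within_family():
    rng = np.random.default_rng(3)
    table = random_table(rng)
    swapped = dict(table.counts)
    swapped["GAA"], swapped["GAG"] = swapped["GAG"], swapped["GAA"]
    assert enc(table) == pytest.approx(enc(table_from(swapped)))


def test_enc_decreases_as_usage_concentrates():
    """Moving counts onto each family's majority codon at fixed totals
    weakly lowers ENC (per-family homozygosity can only increase)."""
    rng = np.random.default_rng(11)
    counts = {c: int(rng.integers(5, 30)) for c in sorted(STANDARD.sense_codons)}
    previous = enc(table_from(counts))
    for _ in range(10):
        for fam in STANDARD.families:
            if len(fam) < 2:
                continue
            members = sorted(fam)
            target = max(members, key=lambda c: (counts[c], c))
            for c in members:
                if c != target and counts[c] > 0:
                    counts[c] -= 1
                    counts[target] += 1
        current = enc(table_from(counts))
        assert current <= previous + 1e-9
        previous = current


def test_enc_undefined_without_observations():
    assert enc(table_from({})) is None


# --- CAI -------------------------------------------------------------------

def test_cai_is_one_for_reference_preferred_usage():
    reference = table_from({c: 10 for c in STANDARD.sense_codons})
    for fam in STANDARD.families:
        reference.counts[max(fam)] = 50  # make one codon dominant
    gene = table_from({max(fam): 5 for fam in STANDARD.families if len(fam) > 1})
    assert cai(gene, reference) == pytest.approx(1.0)


def test_cai_geometric_mean_hand_case():
    # w(GAA)=1, w(GAG)=0.25; equal usage -> sqrt(0.25) = 0.5
    reference = table_from({"GAA": 4, "GAG": 1})
    gene = table_from({"GAA": 1, "GAG": 1})
    assert cai(gene, reference) == pytest.approx(0.5)


def test_cai_decreases_when_swapping_to_unpreferred():
    reference = table_from({"GAA": 4, "GAG": 1})
    better = table_from({"GAA": 5, "GAG": 1})
    worse = table_from({"GAA": 4, "GAG": 2})
    assert cai(worse, reference) < cai(better, reference)


def test_cai_scale_invariant_in_reference():
    rng = np.random.default_rng(5)
    gene = random_table(rng)
    # strictly positive reference: the zero-count pseudo-count is a fixed
    # 0.5 and deliberately does not scale
    reference = table_from({c: int(rng.integers(1, 30)) for c in STANDARD.sense_codons})
    scaled = table_from({c: reference.counts[c] * 7 for c in ALL_CODONS})
    assert cai(gene, reference) == pytest.approx(cai(gene, scaled))


def test_cai_bounds_on_random_tables():
    rng = np.random.default_rng(13)
    for _ in range(100):
        gene, reference = random_table(rng), random_table(rng)
        value = cai(gene, reference)
        assert value is None or 0 < value <= 1 + 1e-12


def test_cai_requires_nonempty_reference():
    with pytest.raises(ValueError):
        cai(table_from({"GAA": 1}), table_from({}))
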