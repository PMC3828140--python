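from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import linear_annotation
from parasitome.rip import (
    COMPOSITE_THRESHOLD,
    TPA_APT_THRESHOLD,
    classify_rip_genes,
    compare_rip_fractions,
    composite_rip_index,
    dinucleotide_counts,
    dinucleotide_foldchange,
    stop_codon_census,
    tpa_apt_index,
)
from parasitome.synth import apply_rip

DNA = st.text(alphabet="ACGT", min_size=0, max_size=200)
DNA_N = st.text(alphabet="ACGTN", min_size=0, max_size=200)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_counts(seq: str) -> dict[str, int]:
    out = {a + b: 0 for a in "ACGT" for b in "ACGT"}
    seq = seq.upper()
    for i in range(len(seq) - 1):
        window = seq[i : i + 2]
        if window in out:
            out[window] += 1
    return out


class TestDinucleotideCounts:
    def test_hand_enumeration(self):
        counts = dinucleotide_counts("ACAC")
        assert counts["AC"] == 2 and counts["CA"] == 1
        assert sum(counts.values()) == 3

    def test_degenerate(self):
        assert all(v == 0 for v in dinucleotide_counts("A").values())
        assert all(v == 0 for v in dinucleotide_counts("").values())

    def test_n_windows_skipped(self):
        counts = dinucleotide_counts("ANAT")
        assert counts["AT"] == 1
        assert sum(counts.values()) == 1

    def test_case_insensitive(self):
        assert dinucleotide_counts("acgt") == dinucleotide_counts("ACGT")

    @given(DNA_N)
    def test_matches_naive(self, seq):
        assert dinucleotide_counts(seq) == naive_counts(seq)

    @given(DNA_N)
    def test_total_is_n_free_window_count(self, seq):
        expected = sum(
            1
            for i in range(len(seq) - 1)
            if "N" not in seq[i : i + 2].upper()
        )
        assert sum(dinucleotide_counts(seq).values()) == expected

    @given(DNA, DNA)
    def test_concatenation_with_n_separator(self, a, b):
        joined = dinucleotide_counts(a + "N" + b)
        parts = dinucleotide_counts(a)
        for dn, c in dinucleotide_counts(b).items():
            parts[dn] += c
        assert joined == parts


class TestIndices:
    def test_tpa_apt_hand(self):
        assert tpa_apt_index("TATA") == pytest.approx(2.0)

    def test_tpa_apt_undefined(self):
        assert tpa_apt_index("GCGC") is None

    def test_composite_hand(self):
        assert composite_rip_index("CAAC") == pytest.approx(1.0)

    def test_composite_undefined(self):
        assert composite_rip_index("CATG") is None

    @given(DNA)
    def test_strand_symmetry(self, seq):
        rc = revcomp(seq)
        assert tpa_apt_index(seq) == tpa_apt_index(rc)
        assert composite_rip_index(seq) == composite_rip_index(rc)

    def test_composite_null_distribution(self, rng):
        # uniform-composition 10 kb sequences: composite index close to 1
        inside = 0
        n = 1000
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(n):
            seq = rng.choice(bases, size=10_000).tobytes().decode()
            val = composite_rip_index(seq)
            inside += 0.8 <= val <= 1.25
        assert inside >= 0.99 * n


class TestClassifyRipGenes:
    def test_threshold_semantics(self):
        # "TA"*60 gives 60/59 >= 0.89; "ATC"*40 gives 0/40 < 0.89
        ann = linear_annotation([{"cds": "TA" * 60}, {"cds": "ATC" * 40}])
        scan = classify_rip_genes(ann, index="tpa_apt")
        calls = {r.seq_id: r.affected_tpa for r in scan.results}
        assert calls["g0001"] == "affected"
        assert calls["g0002"] == "unaffected"
        assert scan.pct_affected == 50.0

    def test_undefined_in_denominator_never_affected(self):
        ann = linear_annotation([{"cds": "GCGC" * 10} for _ in range(4)])
        scan = classify_rip_genes(ann, index="tpa_apt")
        assert scan.n_affected == 0
        assert scan.n_total == 4
        assert scan.pct_affected == 0.0

    def test_gene_without_cds_counts_as_undefined(self):
        ann = linear_annotation([{"cds": "TA" * 60}, {}])
        scan = classify_rip_genes(ann, index="tpa_apt")
        assert scan.n_total == 2 and scan.n_affected == 1

    def test_subset_restriction(self):
        ann = linear_annotation([{"cds": "TA" * 60}, {"cds": "ATC" * 40}])
        scan = classify_rip_genes(ann, gene_ids={"g0001"})
        assert scan.n_total == 1 and scan.pct_affected == 100.0

    def test_composite_call(self):
        # all-CA-free sequence depleted in targets
        ann = linear_annotation([{"cds": "TTAA" * 30}])
        scan = classify_rip_genes(ann, index="composite")
        assert scan.results[0].affected_composite == "undefined"


class TestStopCodonCensus:
    def test_hand_count(self):
        ann = linear_annotation(
            [{"cds": "ATGTAA"}, {"cds": "ATGTAA"}, {"cds": "ATGTGA"}]
        )
        census = stop_codon_census(ann)
        assert (census.taa, census.tag, census.tga) == (2, 0, 1)
        assert census.taa_tga_ratio == 2.0

    def test_other_and_undefined_ratio(self):
        ann = linear_annotation([{"cds": "ATGCCC"}, {"cds": "ATGTAG"}])
        census = stop_codon_census(ann)
        assert census.other == 1 and census.tag == 1
        assert census.taa_tga_ratio is None
        assert census.n_genes == census.taa + census.tag + census.tga + census.other

    def test_gene_set_restriction(self):
        ann = linear_annotation([{"cds": "ATGTAA"}, {"cds": "ATGTGA"}])
        census = stop_codon_census(ann, gene_set={"g0001"})
        assert census.n_genes == 1 and census.taa == 1

    def test_lowercase_terminus(self):
        ann = linear_annotation([{"cds": "atgtaa"}])
        assert stop_codon_census(ann).taa == 1


class TestDinucleotideFoldchange:
    def test_constructed_counts(self):
        # target freq(TA)=1/5 vs control 1/10 -> +log10(2)
        target = ["TAGGGG"]  # windows: TA GG GG GG GG
        control = ["TAGGGGGGGGG"]  # 10 windows, one TA
        fc = dinucleotide_foldchange(target, control)
        assert fc["TA"] == pytest.approx(math.log10(2.0))

    def test_identity(self):
        seqs = ["ACGTACGT", "TTAACC"]
        fc = dinucleotide_foldchange(seqs, seqs)
        assert all(v == pytest.approx(0.0) for v in fc.values() if v is not None)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            dinucleotide_foldchange([], ["ACGT"])

    def test_rip_simulation_signs(self, rng):
        originals = [
            rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=2000)
            .tobytes()
            .decode()
            for _ in range(20)
        ]
        ripped = [apply_rip(s, 0.5, seed=i) for i, s in enumerate(originals)]
        fc = dinucleotide_foldchange(ripped, originals)
        assert fc["TA"] > 0
        assert fc["TG"] < 0
        assert fc["CA"] < 0


def fisher_oracle(aff_a: int, tot_a: int, aff_b: int, tot_b: int) -> float:
    """Exhaustive enumeration: distribute the pooled affected individuals
    uniformly over labeled positions; P(group A gets >= aff_a)."""
    n = tot_a + tot_b
    k = aff_a + aff_b
    hits = total = 0
    for combo in itertools.combinations(range(n), k):
        total += 1
        hits += sum(1 for pos in combo if pos < tot_a) >= aff_a
    return hits / total


class TestCompareRipFractions:
    def test_hand_enumeration(self):
        assert compare_rip_fractions(3, 4, 1, 4) == pytest.approx(17 / 70)

    def test_no_enrichment(self):
        assert compare_rip_fractions(2, 5, 2, 5) > 0.5

    def test_large_counts_bound(self):
        assert compare_rip_fractions(533, 695, 4181, 10959) < 1e-10

    def test_total_zero_errors(self):
        with pytest.raises(ValueError):
            compare_rip_fractions(0, 0, 1, 2)

    @pytest.mark.parametrize(
        "aff_a,tot_a,aff_b,tot_b",
        [
            (a, ta, b, tb)
            for ta in (1, 3, 5)
            for tb in (2, 4, 6)
            for a in range(ta + 1)
            for b in range(tb + 1)
            if ta + tb <= 11
        ],
    )
    def test_matches_enumeration(self, aff_a, tot_a, aff_b, tot_b):
        expected = fisher_oracle(aff_a, tot_a, aff_b, tot_b)
        assert compare_rip_fractions(aff_a, tot_a, aff_b, tot_b) == pytest.approx(
            expected, abs=1e-12
        )
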