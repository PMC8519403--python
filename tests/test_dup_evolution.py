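"""Unit tests for tandem detection and NG86, with an oracle implemented
independently of the package (own code table, recursive full-path
enumeration)."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famchar.dup_evolution import (
    DuplicatePair,
    EvolutionParams,
    TandemCriteria,
    analyze_pair,
    chromosome_distribution,
    codon_align,
    divergence_time,
    find_tandem_pairs,
    jukes_cantor,
    nei_gojobori,
    selection_label,
)
from famchar.seq_model import CodingSequence, GeneModel, assign_ranks
from famchar.synthetic_data import evolve_codon_pair

# --- independent genetic code (TCAG row order, as printed in code tables) ---
_ORACLE_BASES = "TCAG"
_ORACLE_CODE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


def oracle_aa(codon: str) -> str:
    i = _ORACLE_BASES.index(codon[0])
    j = _ORACLE_BASES.index(codon[1])
    k = _ORACLE_BASES.index(codon[2])
    return _ORACLE_CODE[16 * i + 4 * j + k]


SENSE_CODONS = sorted(
    "".join(c) for c in product("ACGT", repeat=3) if oracle_aa("".join(c)) != "*"
)


def oracle_sites(codon: str):
    s = n = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if oracle_aa(mut) == "*":
                continue
            if oracle_aa(mut) == oracle_aa(codon):
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def oracle_path_diffs(seq1: str, seq2: str):
    """Joint exhaustive pathway enumeration over the whole (multi-codon)
    sequence, excluding paths through any intermediate stop codon."""
    diffs = [i for i in range(len(seq1)) if seq1[i] != seq2[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in permutations(diffs):
        cur = seq1
        sd = nd = 0
        ok = True
        for p in order:
            nxt = cur[:p] + seq2[p] + cur[p + 1 :]
            ci = p // 3
            if oracle_aa(nxt[3 * ci : 3 * ci + 3]) == "*":
                ok = False
                break
            if all(
                oracle_aa(nxt[i : i + 3]) == oracle_aa(cur[i : i + 3])
                for i in range(0, len(cur), 3)
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    assert results, "no unblocked path (cannot happen in the standard code)"
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_ng(seq1: str, seq2: str):
    s_sites = n_sites = 0.0
    for i in range(0, len(seq1), 3):
        s1, n1 = oracle_sites(seq1[i : i + 3])
        s2, n2 = oracle_sites(seq2[i : i + 3])
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
    sd, nd = oracle_path_diffs(seq1, seq2)
    return sd, nd, s_sites, n_sites


# ---------------------------------------------------------------------------
# Tandem detection
# ---------------------------------------------------------------------------

def make_map(rows):
    return assign_ranks([GeneModel(*r) for r in rows])


class TestFindTandemPairs:
    def test_adjacent_pair_reported(self):
        genes = make_map(
            [("a", "chr1", 1000, 2000), ("b", "chr1", 21_000, 22_000)]
        )
        assert find_tandem_pairs(genes, ["a", "b"]) == [("a", "b")]

    def test_distant_pair_excluded(self):
        genes = make_map(
            [("a", "chr1", 1000, 2000), ("b", "chr1", 3_001_000, 3_002_000)]
        )
        assert find_tandem_pairs(genes, ["a", "b"]) == []

    def test_intervening_gene_allowance(self):
        genes = make_map(
            [
                ("a", "chr1", 1000, 2000),
                ("x", "chr1", 10_000, 11_000),
                ("b", "chr1", 30_000, 31_000),
            ]
        )
        assert find_tandem_pairs(genes, ["a", "b"]) == [("a", "b")]
        strict = TandemCriteria(max_intervening_genes=0)
        assert find_tandem_pairs(genes, ["a", "b"], strict) == []

    def test_different_chromosome_excluded(self):
        genes = make_map(
            [("a", "chr1", 1000, 2000), ("b", "chr2", 2000, 3000)]
        )
        assert find_tandem_pairs(genes, ["a", "b"]) == []

    def test_missing_family_id_rejected(self):
        genes = make_map([("a", "chr1", 1000, 2000)])
        with pytest.raises(ValueError, match="zz"):
            find_tandem_pairs(genes, ["a", "zz"])

    def test_planted_clusters_recovered(self, default_bundle):
        genes = default_bundle.gene_models
        pairs = find_tandem_pairs(genes, [g.gene_id for g in genes])
        truth = sorted(
            tuple(sorted((r.gene_a, r.gene_b)))
            for r in default_bundle.truth["tandem_pairs"].itertuples()
        )
        assert pairs == truth
        assert len(pairs) == 9

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(min_value=1, max_value=400_000),
            ),
            min_size=2,
            max_size=12,
            unique_by=lambda t: t,
        )
    )
    def test_matches_bruteforce_filter(self, placements):
        genes = assign_ranks(
            [
                GeneModel(f"g{i}", chrom, start, start + 100)
                for i, (chrom, start) in enumerate(placements)
            ]
        )
        crit = TandemCriteria(max_intervening_genes=1, max_distance_bp=100_000)
        got = find_tandem_pairs(genes, [g.gene_id for g in genes], crit)
        expected = set()
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if a.chromosome != b.chromosome:
                    continue
                if abs(a.rank - b.rank) - 1 > 1:
                    continue
                if abs(a.start - b.start) > 100_000:
                    continue
                expected.add(tuple(sorted((a.gene_id, b.gene_id))))
        assert set(got) == expected


class TestChromosomeDistribution:
    def test_percentages(self):
        rows = [("g%d" % i, "chr2", 1000 * (i + 1), 1000 * (i + 1) + 10)
                for i in range(18)]
        rows += [("h%d" % i, "chr3", 1000 * (i + 1), 1000 * (i + 1) + 10)
                 for i in range(2)]
        rows += [("k%d" % i, "chr4", 1000 * (i + 1), 1000 * (i + 1) + 10)
                 for i in range(75)]
        dist = dict((c, (n, p)) for c, n, p in chromosome_distribution(make_map(rows)))
        assert dist["chr2"] == (18, 18.95)
        assert dist["chr3"] == (2, 2.11)


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

class TestCodonAlign:
    def test_identity(self):
        cds = CodingSequence("a", "ATGAAATTT")
        out = codon_align(cds, cds, ("MKF", "MKF"))
        assert out == ("ATGAAATTT", "ATGAAATTT")

    def test_gap_expansion(self):
        a = CodingSequence("a", "ATGAAATTT")
        b = CodingSequence("b", "ATGTTT")
        out = codon_align(a, b, ("MKF", "M-F"))
        assert out == ("ATGAAATTT", "ATG---TTT")

    def test_trailing_stop_ignored(self):
        a = CodingSequence("a", "ATGAAATAA")
        b = CodingSequence("b", "ATGAAA")
        out = codon_align(a, b, ("MK", "MK"))
        assert out == ("ATGAAA", "ATGAAA")

    def test_translation_mismatch_names_position(self):
        a = CodingSequence("a", "ATGAAATTT")
        b = CodingSequence("b", "ATGTTTTTT")
        with pytest.raises(ValueError, match="residue 2"):
            codon_align(a, b, ("MKF", "MKF"))


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

class TestNeiGojobori:
    def test_identical_sequences(self):
        r = nei_gojobori("ATGAAATTT", "ATGAAATTT")
        assert r.ka == 0.0 and r.ks == 0.0 and r.nd == 0.0 and r.sd == 0.0

    def test_phe_phe_synonymous(self):
        r = nei_gojobori("TTT", "TTC")
        assert r.sd == 1.0 and r.nd == 0.0
        assert r.ps == pytest.approx(1.0 / r.s_sites)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=30))
        b = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=30))
        r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
        assert r1.sd == pytest.approx(r2.sd)
        assert r1.nd == pytest.approx(r2.nd)
        assert r1.s_sites == pytest.approx(r2.s_sites)
        assert r1.n_sites == pytest.approx(r2.n_sites)

    def test_gap_columns_skipped(self):
        r = nei_gojobori("ATG---TTT", "ATGAAATTT")
        assert r.n_codons == 2

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori("TAAAAA", "TAAAAA")

    def test_site_sum_identity_vs_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            codon = SENSE_CODONS[rng.integers(0, 61)]
            s, n = oracle_sites(codon)
            stops = sum(
                1
                for pos in range(3)
                for b in "ACGT"
                if b != codon[pos]
                and oracle_aa(codon[:pos] + b + codon[pos + 1 :]) == "*"
            )
            assert s + n == pytest.approx(3.0 - stops / 3.0)
            r = nei_gojobori(codon, codon)
            assert r.s_sites == pytest.approx(s)
            assert r.n_sites == pytest.approx(n)

    def test_single_codon_sample_vs_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(150):
            c1 = SENSE_CODONS[rng.integers(0, 61)]
            c2 = SENSE_CODONS[rng.integers(0, 61)]
            sd, nd, s_sites, n_sites = oracle_ng(c1, c2)
            r = nei_gojobori(c1, c2)
            assert r.sd == pytest.approx(sd)
            assert r.nd == pytest.approx(nd)
            assert r.s_sites == pytest.approx(s_sites)
            assert r.n_sites == pytest.approx(n_sites)

    def test_jukes_cantor(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.9) is None
        with pytest.raises(ValueError):
            jukes_cantor(-0.1)

    def test_saturated_pair_has_ka_only(self):
        # every codon column synonymous-saturated: ps >= 3/4 -> ks undefined
        a = "TTT" * 3
        b = "TTC" * 3
        r = nei_gojobori(a, b)
        assert r.ks is None
        assert r.ka == 0.0
        assert r.ka_ks is None


class TestSelectionAndDating:
    def test_labels(self):
        assert selection_label(0.270) == "purifying"
        assert selection_label(0.949) == "purifying"
        assert selection_label(1.0) == "neutral"
        assert selection_label(1.5) == "positive"
        assert selection_label(None) == "undetermined"

    def test_divergence_closed_form(self):
        assert divergence_time(0.03) == pytest.approx(1.0)
        assert divergence_time(0.0) == 0.0
        assert divergence_time(1.92) == pytest.approx(64.0)

    def test_linearity_and_lambda_inverse(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            ks = float(rng.uniform(0, 3))
            c = float(rng.uniform(0.1, 5))
            assert divergence_time(c * ks) == pytest.approx(c * divergence_time(ks))
            p2 = EvolutionParams(lambda_rate=3.0e-8)
            assert divergence_time(ks, p2) == pytest.approx(divergence_time(ks) / 2)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)

    def test_pair_invariants(self):
        with pytest.raises(ValueError):
            DuplicatePair("a", "b", ka=0.1, ks=None, ka_ks=0.5,
                          divergence_time_mya=None, selection_label="undetermined")

    def test_analyze_pair_end_to_end(self):
        a, b, _ = evolve_codon_pair(200, 0.1, 0.3, seed=5)
        pair = analyze_pair("a", "b", (a.sequence, b.sequence))
        assert pair.ka is not None and pair.ks is not None
        assert pair.selection_label in {"purifying", "neutral", "positive"}
        assert pair.divergence_time_mya == pytest.approx(
            divergence_time(pair.ks)
        )
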