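"""Low-stringency search: SEG, local alignment vs DP oracle, KA statistics,
hit filtering, and the tabular-hit parser."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from anablast import (
    GenomeRegion,
    ScoringScheme,
    SearchConfig,
    evalue,
    local_align,
    parse_external_hits,
    search_hits,
    seg_mask,
    six_frame_translate,
    to_bit_score,
    write_hits_tabular,
)
from anablast.alignment import load_protein_db

from conftest import random_protein

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def gotoh_oracle(q: str, s: str, scheme: ScoringScheme) -> int:
    """Exhaustive affine-gap local DP (Gotoh), written independently of the
    production aligner: first gap residue costs open+extend."""
    sub = scheme.matrix
    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    n, m = len(q), len(s)
    NEG = -(10**9)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
            prev = max(0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = prev + int(sub[q[i - 1], s[j - 1]])
            best = max(best, M[i][j])
    return best


class TestSegMask:
    def test_homopolymer_fully_masked(self):
        assert seg_mask("A" * 16) == "x" * 16

    def test_all_distinct_window_unmasked(self):
        # entropy of a 12-mer over >=12 distinct residues is log2(12) = 3.58
        # bits, above hicut 2.5, so nothing can trigger or extend
        assert seg_mask("MKVLHEWRQDITFYNC") == "MKVLHEWRQDITFYNC"

    def test_mask_is_local(self):
        s = "MKVLHEWRQDITFYNC" + "A" * 20 + "MKVLHEWRQDITFYNC"
        masked = seg_mask(s)
        assert masked[16:36] == "x" * 20
        assert masked.startswith("MKVLHEW")

    @given(st.integers(0, 500))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        # biased composition so masking actually happens sometimes
        s = "".join(rng.choice(list("AAAALKV"), size=40))
        once = seg_mask(s)
        assert seg_mask(once) == once


class TestLocalAlign:
    def test_identity_scores_sum_of_diagonal(self, scheme):
        q = "MKVLHEWRQD"
        expected = sum(int(scheme.matrix[a, a]) for a in q)
        (hit,) = local_align(q, q, scheme)
        assert hit.raw_score == expected
        assert (hit.q_start, hit.q_end) == (0, 10)

    def test_dissimilar_sequences_give_no_alignment(self, scheme):
        # A/T is non-positive under BLOSUM90, so no positive local score
        assert int(scheme.matrix["A", "T"]) <= 0
        assert local_align("AAAA", "TTTT", scheme) == []

    def test_agrees_with_exhaustive_dp_oracle(self, scheme):
        rng = np.random.default_rng(11)
        for _ in range(200):
            q = random_protein(rng, int(rng.integers(1, 13)))
            s = random_protein(rng, int(rng.integers(1, 13)))
            expected = gotoh_oracle(q, s, scheme)
            hits = local_align(q, s, scheme)
            got = hits[0].raw_score if hits else 0
            assert got == expected, (q, s)

    def test_suboptimal_hsps_do_not_overlap_on_query(self, scheme):
        core = "MKVLHEWRQDWC"
        q = core + "PPPGGPGPGPPP" + core
        s = core
        hits = local_align(q, s, scheme, max_hsps=4)
        assert len(hits) == 2
        ivs = sorted((h.q_start, h.q_end) for h in hits)
        assert ivs[0][1] <= ivs[1][0]


class TestKarlinAltschul:
    def test_bit_score_analytic_case(self):
        scheme = ScoringScheme(lam=math.log(2), k=1.0)
        assert to_bit_score(30, scheme) == pytest.approx(30.0)
        assert to_bit_score(0, scheme) == pytest.approx(0.0)

    def test_bit_score_monotone_in_raw(self, scheme):
        bits = [to_bit_score(r, scheme) for r in range(0, 100, 7)]
        assert all(b1 < b2 for b1, b2 in zip(bits, bits[1:]))

    def test_evalue_arithmetic(self):
        assert evalue(0.0, 1.0) == pytest.approx(1.0)
        assert evalue(10.0, 102400.0) == pytest.approx(100.0)
        assert evalue(10.0, 204800.0) == pytest.approx(2 * evalue(10.0, 102400.0))

    def test_unknown_gap_combination_needs_explicit_params(self):
        with pytest.raises(ValueError, match="Karlin-Altschul"):
            ScoringScheme(gap_open=99, gap_extend=7)


def _frame1(dna: str):
    region = GenomeRegion("c", 0, len(dna), dna)
    return six_frame_translate(region)[0]


class TestSearchHits:
    def test_exact_implant_recovered_above_threshold(self, scheme, search_config, tmp_path):
        rng = np.random.default_rng(3)
        target = random_protein(rng, 50)
        from anablast.simulate import back_translate

        flank_l, flank_r = random_protein(rng, 10), random_protein(rng, 10)
        query_dna = back_translate(flank_l + target + flank_r, rng)
        t = _frame1(query_dna)
        db = {"hit1": target, "decoy1": random_protein(rng, 80), "decoy2": random_protein(rng, 80)}
        hits = search_hits(t, db, scheme, search_config)
        covering = [h for h in hits if h.subject_cluster == "hit1"]
        assert covering, "implanted protein not recovered"
        assert covering[0].q_start <= 10 and covering[0].q_end >= 60
        assert covering[0].bit_score >= search_config.bit_threshold

    def test_fully_masked_query_yields_no_hits(self, scheme, search_config):
        t = _frame1("GCA" * 30)  # poly-alanine: SEG masks everything
        hits = search_hits(t, {"selfish": "A" * 30}, scheme, search_config)
        assert hits == []

    def test_hit_cap_respected(self, scheme):
        rng = np.random.default_rng(4)
        target = random_protein(rng, 40)
        from anablast.simulate import back_translate

        t = _frame1(back_translate(target, rng))
        db = {f"c{i:03d}": target for i in range(25)}
        config = SearchConfig(max_hits_per_query=10)
        hits = search_hits(t, db, scheme, config)
        assert len(hits) == 10

    def test_deterministic_ordering(self, scheme, search_config):
        rng = np.random.default_rng(5)
        target = random_protein(rng, 40)
        from anablast.simulate import back_translate

        t = _frame1(back_translate(target, rng))
        db = {f"c{i}": target for i in range(5)}
        hits = search_hits(t, db, scheme, search_config)
        keys = [(-h.bit_score, h.subject_cluster, h.q_start) for h in hits]
        assert keys == sorted(keys)

    def test_empty_db_rejected(self, scheme, search_config):
        with pytest.raises(ValueError, match="empty"):
            search_hits(_frame1("ATGGCCGGG"), {}, scheme, search_config)

    def test_duplicate_db_ids_rejected(self, tmp_path):
        fa = tmp_path / "db.fa"
        fa.write_text(">c1\nMKVL\n>c1\nHEWR\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_protein_db(fa)


class TestParseExternalHits:
    LINE = "c:0-30|frame1\tclusterA\t95.0\t10\t0\t0\t{qs}\t{qe}\t1\t10\t{ev}\t{bits}\n"

    def _write(self, tmp_path, lines):
        path = tmp_path / "hits.tsv"
        path.write_text("".join(lines))
        return path

    def test_coordinates_converted_to_half_open(self, tmp_path):
        path = self._write(tmp_path, [self.LINE.format(qs=1, qe=10, ev="1e-5", bits="50.0")])
        hits = parse_external_hits(path, ["c:0-30|frame1"])
        assert (hits["c:0-30|frame1"][0].q_start, hits["c:0-30|frame1"][0].q_end) == (0, 10)

    def test_sub_threshold_bitscore_dropped(self, tmp_path):
        path = self._write(tmp_path, [self.LINE.format(qs=1, qe=10, ev="1e-5", bits="29.9")])
        assert parse_external_hits(path, ["c:0-30|frame1"]) == {}

    def test_cap_applied_per_query(self, tmp_path):
        lines = [self.LINE.format(qs=i + 1, qe=i + 10, ev="1.0", bits="40.0") for i in range(15)]
        path = self._write(tmp_path, lines)
        hits = parse_external_hits(path, ["c:0-30|frame1"], SearchConfig(max_hits_per_query=10))
        assert len(hits["c:0-30|frame1"]) == 10

    def test_unknown_query_skipped_with_warning(self, tmp_path, caplog):
        path = self._write(tmp_path, [self.LINE.format(qs=1, qe=10, ev="1e-5", bits="50.0")])
        with caplog.at_level("WARNING"):
            hits = parse_external_hits(path, ["other|frame1"])
        assert hits == {} and "unknown query id" in caplog.text

    def test_non_numeric_field_reports_line_number(self, tmp_path):
        path = self._write(tmp_path, [self.LINE.format(qs="one", qe=10, ev="1e-5", bits="50.0")])
        with pytest.raises(ValueError, match="line 1"):
            parse_external_hits(path, ["c:0-30|frame1"])

    def test_filtering_is_order_independent(self, tmp_path):
        rng = np.random.default_rng(9)
        lines = [
            self.LINE.format(qs=int(rng.integers(1, 20)), qe=int(rng.integers(21, 31)),
                             ev="1.0", bits=f"{rng.uniform(20, 60):.1f}")
            for _ in range(40)
        ]
        fwd = parse_external_hits(self._write(tmp_path, lines), ["c:0-30|frame1"])
        rev = parse_external_hits(self._write(tmp_path, lines[::-1]), ["c:0-30|frame1"])
        assert fwd == rev

    def test_round_trip_through_tabular_writer(self, tmp_path, scheme, search_config):
        rng = np.random.default_rng(6)
        target = random_protein(rng, 40)
        from anablast.simulate import back_translate

        t = _frame1(back_translate(target, rng))
        hits = search_hits(t, {"cA": target, "cB": target[5:35]}, scheme, search_config)
        path = tmp_path / "out.tsv"
        write_hits_tabular(hits, path)
        parsed = parse_external_hits(path, [t.query_id], search_config)
        assert [(h.q_start, h.q_end, h.subject_cluster) for h in parsed[t.query_id]] == [
            (h.q_start, h.q_end, h.subject_cluster) for h in hits
        ]


def test_shuffled_coding_dna_looks_like_random_dna(scheme):
    """Shuffling destroys the coding signal completely: hit counts of
    shuffled coding-DNA translations are statistically indistinguishable
    from translations of length-matched random DNA.  A permissive bit
    threshold is used so the null distributions are not degenerate at
    zero."""
    from scipy.stats import mannwhitneyu

    from anablast import shuffle_region
    from anablast.simulate import back_translate, generate_protein_db

    rng = np.random.default_rng(21)
    db, _ = generate_protein_db(n_clusters=50, n_families=10, seed=21)
    records = list(db.values())
    config = SearchConfig(bit_threshold=15.0, evalue_cap=1e12)
    shuffled_counts, random_counts = [], []
    for i in range(50):
        dna = back_translate(records[i % len(records)], rng)
        region = shuffle_region(GenomeRegion("c", 0, len(dna), dna), seed=1000 + i)
        shuffled_counts.append(
            len(search_hits(six_frame_translate(region)[0], db, scheme, config))
        )
        rdna = "".join(rng.choice(list("ACGT"), size=len(dna)))
        t_rand = six_frame_translate(GenomeRegion("c", 0, len(rdna), rdna))[0]
        random_counts.append(len(search_hits(t_rand, db, scheme, config)))
    assert shuffled_counts != random_counts  # non-degenerate comparison
    p = mannwhitneyu(shuffled_counts, random_counts).pvalue
    assert p > 0.01
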