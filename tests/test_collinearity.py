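"""Fragment filtering, collinear chaining and divergence calling."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recsup import collinearity as col


def frag(qs, qe, ts, te, strand="+", identity=95.0):
    return col.AlignmentFragment(
        qry_id="B", qry_start=qs, qry_end=qe, ref_id="A",
        ref_start=ts, ref_end=te, strand=strand,
        length=te - ts, identity=identity,
    )


def random_instance(rng, n=12, span=100_000):
    frags = []
    for _ in range(n):
        ts = rng.randrange(0, span)
        te = ts + rng.randrange(500, 8000)
        qs = rng.randrange(0, span)
        qe = qs + rng.randrange(500, 8000)
        frags.append(frag(qs, qe, ts, te, strand=rng.choice("++-")))
    return frags


def brute_force_best(frags):
    """Exhaustive maximum-total-length consistent subset, per strand.

    Pairwise consistency (non-overlap + concordant order in both genomes)
    is sufficient for a set to chain, so subsets are validated pairwise
    via a precomputed compatibility mask.
    """
    best = 0
    for strand in "+-":
        sel = [f for f in frags if f.strand == strand]
        n = len(sel)
        comp = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                a, b = sel[i], sel[j]
                if b.ref_start >= a.ref_end:
                    if strand == "+":
                        comp[i][j] = b.qry_start >= a.qry_end
                    else:
                        comp[i][j] = b.qry_end <= a.qry_start
        for mask in range(1 << n):
            members = [i for i in range(n) if mask >> i & 1]
            ok = all(
                comp[i][j] or comp[j][i]
                for x, i in enumerate(members)
                for j in members[x + 1 :]
            )
            if ok:
                best = max(best, sum(sel[i].length for i in members))
    return best


class TestFilter:
    @pytest.mark.parametrize(
        "length,identity,kept",
        [
            (2999, 90.0, False),  # below the >=3 kb boundary
            (3000, 75.0, True),  # both thresholds inclusive
            (3000, 74.9, False),
            (10_000, 90.0, True),
        ],
    )
    def test_thresholds(self, length, identity, kept):
        f = frag(0, length, 0, length, identity=identity)
        assert (col.filter_fragments([f]) == [f]) is kept

    def test_empty(self):
        assert col.filter_fragments([]) == []


class TestChain:
    def test_three_consistent_fragments(self):
        frags = [
            frag(0, 1000, 0, 1000),
            frag(2000, 3500, 2000, 3500),
            frag(4000, 5000, 4000, 5000),
        ]
        chain = col.chain_fragments(frags)
        assert len(chain.fragments) == 3
        assert chain.total_aligned == sum(f.length for f in frags)

    def test_minus_fragment_excluded_from_plus_chain(self):
        frags = [
            frag(0, 1000, 0, 1000),
            frag(1500, 2000, 1500, 2000, strand="-"),
            frag(2000, 3500, 2000, 3500),
        ]
        chain = col.chain_fragments(frags)
        assert chain.strand == "+"
        assert all(f.strand == "+" for f in chain.fragments)

    def test_minus_chain_wins_when_heavier(self):
        frags = [
            frag(9000, 10_000, 0, 1000, strand="-"),
            frag(5000, 8000, 2000, 5000, strand="-"),
            frag(0, 2000, 6000, 8000, strand="-"),
            frag(0, 500, 0, 500, strand="+"),
        ]
        chain = col.chain_fragments(frags)
        assert chain.strand == "-"
        assert len(chain.fragments) == 3

    def test_chain_matches_brute_force(self):
        rng = random.Random(17)
        for _ in range(20):
            frags = random_instance(rng)
            assert col.chain_fragments(frags).total_aligned == brute_force_best(
                frags
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = random.Random(seed)
        frags = random_instance(rng, n=8)
        base = col.chain_fragments(frags)
        rng.shuffle(frags)
        again = col.chain_fragments(frags)
        assert again.total_aligned == base.total_aligned
        assert again.fragments == base.fragments

    def test_empty_input(self):
        chain = col.chain_fragments([])
        assert chain.fragments == [] and chain.total_aligned == 0


class TestDivergenceCalls:
    def test_hdr_when_both_gaps_large(self):
        chain = col.CollinearChain(
            fragments=[frag(0, 1000, 0, 1000), frag(56_000, 57_000, 61_000, 62_000)],
            total_aligned=2000, strand="+",
        )
        calls = col.call_divergence(chain, qry_len=57_000, ref_len=62_000)
        assert [c.kind for c in calls] == ["hdr"]
        assert calls[0].ref_gap == 60_000 and calls[0].qry_gap == 55_000

    def test_insertion_in_query(self):
        chain = col.CollinearChain(
            fragments=[frag(0, 1000, 0, 1000), frag(391_000, 392_000, 3_000, 4_000)],
            total_aligned=2000, strand="+",
        )
        calls = col.call_divergence(chain, qry_len=392_000, ref_len=4_000)
        assert [c.kind for c in calls] == ["insertion_qry"]
        assert calls[0].qry_gap == 390_000 and calls[0].ref_gap == 2_000

    def test_collinear_chain_no_calls(self):
        chain = col.CollinearChain(
            fragments=[frag(0, 1000, 0, 1000), frag(1000, 2000, 1000, 2000)],
            total_aligned=2000, strand="+",
        )
        assert col.call_divergence(chain, 2000, 2000) == []

    def test_length_conservation_on_gapfree_fragments(self):
        # sum of (qry_gap - ref_gap) equals the genome length difference
        chain = col.CollinearChain(
            fragments=[
                frag(0, 10_000, 0, 10_000),
                frag(70_000, 80_000, 10_000, 20_000),
                frag(80_000, 90_000, 80_000, 90_000),
            ],
            total_aligned=30_000, strand="+",
        )
        qry_len, ref_len = 90_000, 90_000
        calls = col.call_divergence(chain, qry_len, ref_len,
                                    hdr_min=1, indel_min=1, collinear_slop=1)
        total = sum(c.qry_gap - c.ref_gap for c in calls)
        assert total == qry_len - ref_len - 0  # gap-free fragments


class TestCoverage:
    def test_full_window_covered(self):
        cov = col.coverage_map([frag(0, 10_000, 0, 10_000, identity=85.0)],
                               ref_len=10_000)
        assert cov.tolist() == [1.0]

    def test_below_similarity_threshold_ignored(self):
        cov = col.coverage_map([frag(0, 10_000, 0, 10_000, identity=79.0)],
                               ref_len=10_000)
        assert cov.tolist() == [0.0]

    def test_union_never_exceeds_one(self):
        frags = [
            frag(0, 7000, 0, 7000, identity=90.0),
            frag(4000, 10_000, 4000, 10_000, identity=90.0),
        ]
        cov = col.coverage_map(frags, ref_len=10_000)
        assert cov.tolist() == [1.0]
        # independent interval-union oracle
        marks = np.zeros(10_000, bool)
        for f in frags:
            marks[f.ref_start : f.ref_end] = True
        assert cov[0] == marks.mean()


class TestIO:
    def test_paf_round_trip(self, tmp_path, demo_pair):
        paths = demo_pair.write(tmp_path / "o")
        frags = col.read_paf(paths["alignments.paf"])
        assert frags
        assert all(f.identity == pytest.approx(99.0, abs=0.1) for f in frags)
        assert {f.strand for f in frags} == {"+", "-"}

    def test_paf_rejects_short_lines(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text("q\t10\t0\t5\n")
        with pytest.raises(ValueError):
            col.read_paf(str(p))

    def test_show_coords_reader(self, tmp_path):
        p = tmp_path / "coords.txt"
        p.write_text(
            "NUCMER\n\n[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[TAGS]\n"
            "1\t5000\t101\t5100\t5000\t5000\t97.5\tchrA\tchrB\n"
            "6001\t7000\t8100\t7101\t1000\t1000\t88.0\tchrA\tchrB\n"
        )
        frags = col.read_show_coords(str(p))
        assert len(frags) == 2
        assert frags[0].ref_start == 0 and frags[0].ref_end == 5000
        assert frags[0].qry_start == 100 and frags[0].identity == 97.5
        assert frags[1].strand == "-"
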