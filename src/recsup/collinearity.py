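"""Collinear chaining of local-alignment fragments and divergence calling.

Local alignments between two homologous chromosomes (from an upstream
aligner, read here from PAF-like or show-coords tables) are filtered by
length and identity, chained into the most representative collinear assembly
— the maximum-total-aligned-length set of non-overlapping fragments that are
consistently ordered on one strand — and the gaps of the chain are
classified: a large gap on both genomes is a highly diverged region (HDR),
a large gap on one genome only is an insertion in that genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignmentFragment",
    "CollinearChain",
    "DivergenceCall",
    "read_paf",
    "read_show_coords",
    "filter_fragments",
    "chain_fragments",
    "call_divergence",
    "coverage_map",
]

MIN_FRAGMENT_LEN = 3000  # bp
MIN_FRAGMENT_IDENTITY = 75.0  # percent
COVERAGE_MIN_SIMILARITY = 80.0  # percent


@dataclass(frozen=True)
class AlignmentFragment:
    """One local alignment between query and reference, 0-based half-open."""

    qry_id: str
    qry_start: int
    qry_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str  # "+" | "-"
    length: int  # aligned block length on the reference
    identity: float  # percent

    def __post_init__(self):
        if self.qry_end <= self.qry_start or self.ref_end <= self.ref_start:
            raise ValueError("fragment spans must be non-empty")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be a percentage in [0, 100]")


@dataclass
class CollinearChain:
    fragments: list[AlignmentFragment]
    total_aligned: int
    strand: str


@dataclass
class DivergenceCall:
    kind: str  # "hdr" | "insertion_qry" | "insertion_ref"
    qry_span: tuple[int, int]
    ref_span: tuple[int, int]
    qry_gap: int
    ref_gap: int


def read_paf(path: str) -> list[AlignmentFragment]:
    """Read a minimal 12-column PAF table.

    Columns: qname qlen qstart qend strand tname tlen tstart tend matches
    block_len mapq; identity is matches / block_len × 100.
    """
    frags = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: expected >=12 PAF columns")
            matches, block = int(f[9]), int(f[10])
            frags.append(
                AlignmentFragment(
                    qry_id=f[0],
                    qry_start=int(f[2]),
                    qry_end=int(f[3]),
                    strand=f[4],
                    ref_id=f[5],
                    ref_start=int(f[7]),
                    ref_end=int(f[8]),
                    length=int(f[8]) - int(f[7]),
                    identity=100.0 * matches / block if block else 0.0,
                )
            )
    return frags


def read_show_coords(path: str) -> list[AlignmentFragment]:
    """Read NUCmer show-coords ``-T`` tabular output.

    Columns: S1 E1 S2 E2 LEN1 LEN2 %IDY [tags] ref_id qry_id (1-based,
    inclusive; a reversed S2>E2 span denotes the minus strand).
    """
    frags = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or not f[0].lstrip("-").isdigit():
                continue  # headers
            s1, e1, s2, e2 = (int(x) for x in f[:4])
            idy = float(f[6])
            strand = "+" if s2 <= e2 else "-"
            if strand == "-":
                s2, e2 = e2, s2
            frags.append(
                AlignmentFragment(
                    qry_id=f[-1],
                    qry_start=s2 - 1,
                    qry_end=e2,
                    ref_id=f[-2],
                    ref_start=s1 - 1,
                    ref_end=e1,
                    strand=strand,
                    length=e1 - (s1 - 1),
                    identity=idy,
                )
            )
    return frags


def filter_fragments(
    frags: list[AlignmentFragment],
    min_len: int = MIN_FRAGMENT_LEN,
    min_identity: float = MIN_FRAGMENT_IDENTITY,
) -> list[AlignmentFragment]:
    """Keep fragments with length >= min_len and identity >= min_identity
    (both thresholds inclusive); input order preserved."""
    return [
        f for f in frags if f.length >= min_len and f.identity >= min_identity
    ]


def _chain_one_strand(frags: list[AlignmentFragment], strand: str) -> CollinearChain:
    """Weighted LIS over fragments of one strand.

    On '+' both coordinates must strictly increase without overlap; on '-'
    the query runs backwards as the reference advances.  Score is total
    aligned (reference) length; ties prefer fewer fragments, then the chain
    whose fragment list is lexicographically leftmost by ref start.
    """
    sel = [f for f in frags if f.strand == strand]
    sel.sort(key=lambda f: (f.ref_start, f.ref_end, f.qry_start, f.qry_id))
    n = len(sel)
    if n == 0:
        return CollinearChain(fragments=[], total_aligned=0, strand=strand)
    score = [f.length for f in sel]
    nfrag = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            a, b = sel[j], sel[i]
            if b.ref_start < a.ref_end:
                continue
            if strand == "+":
                ok = b.qry_start >= a.qry_end
            else:
                ok = b.qry_end <= a.qry_start
            if not ok:
                continue
            cand = score[j] + b.length
            if cand > score[i] or (cand == score[i] and nfrag[j] + 1 < nfrag[i]):
                score[i] = cand
                nfrag[i] = nfrag[j] + 1
                prev[i] = j
    best = max(range(n), key=lambda i: (score[i], -nfrag[i], -sel[i].ref_start))
    chain = []
    i = best
    while i != -1:
        chain.append(sel[i])
        i = prev[i]
    chain.reverse()
    return CollinearChain(
        fragments=chain, total_aligned=sum(f.length for f in chain), strand=strand
    )


def chain_fragments(frags: list[AlignmentFragment]) -> CollinearChain:
    """The most representative collinear assembly of the fragments.

    Both strands are chained by dynamic programming (weighted longest
    increasing subsequence on the (ref, qry) order); the strand with the
    larger total aligned length wins, '+' on a tie.  Deterministic in the
    input set, invariant under input permutation.
    """
    plus = _chain_one_strand(frags, "+")
    minus = _chain_one_strand(frags, "-")
    if minus.total_aligned > plus.total_aligned:
        return minus
    return plus


def call_divergence(
    chain: CollinearChain,
    qry_len: int,
    ref_len: int,
    hdr_min: int = 50_000,
    indel_min: int = 50_000,
    collinear_slop: int = 10_000,
) -> list[DivergenceCall]:
    """Classify inter-fragment gaps of a chain into HDRs and insertions.

    For every gap between consecutive chain fragments (chromosome ends
    included) the unaligned stretch is measured on both genomes: both gaps
    >= ``hdr_min`` → HDR; exactly one gap >= ``indel_min`` while the other
    is < ``collinear_slop`` → insertion in the genome carrying the large
    gap.  Calls are sorted by reference position.
    """
    frs = chain.fragments
    calls: list[DivergenceCall] = []
    if not frs:
        return calls
    minus = chain.strand == "-"

    # ref-ordered walk; on '-' the query walks from its far end backwards
    ref_edges = [0] + [f.ref_end for f in frs]
    ref_starts = [f.ref_start for f in frs] + [ref_len]
    if minus:
        qry_hi = [qry_len] + [f.qry_start for f in frs]
        qry_lo = [f.qry_end for f in frs] + [0]
        qry_gaps = [hi - lo for hi, lo in zip(qry_hi, qry_lo)]
        qry_spans = [(lo, hi) for hi, lo in zip(qry_hi, qry_lo)]
    else:
        qry_edges = [0] + [f.qry_end for f in frs]
        qry_starts = [f.qry_start for f in frs] + [qry_len]
        qry_gaps = [s - e for e, s in zip(qry_edges, qry_starts)]
        qry_spans = [(e, s) for e, s in zip(qry_edges, qry_starts)]

    for i in range(len(frs) + 1):
        ref_gap = ref_starts[i] - ref_edges[i]
        qry_gap = qry_gaps[i]
        ref_span = (ref_edges[i], ref_starts[i])
        qry_span = qry_spans[i]
        if ref_gap >= hdr_min and qry_gap >= hdr_min:
            kind = "hdr"
        elif qry_gap >= indel_min and ref_gap < collinear_slop:
            kind = "insertion_qry"
        elif ref_gap >= indel_min and qry_gap < collinear_slop:
            kind = "insertion_ref"
        else:
            continue
        calls.append(
            DivergenceCall(
                kind=kind,
                qry_span=qry_span,
                ref_span=ref_span,
                qry_gap=qry_gap,
                ref_gap=ref_gap,
            )
        )
    calls.sort(key=lambda c: c.ref_span)
    return calls


def coverage_map(
    frags: list[AlignmentFragment],
    ref_len: int,
    min_similarity: float = COVERAGE_MIN_SIMILARITY,
    window: int = 10_000,
) -> np.ndarray:
    """Fraction of each fixed reference window covered by >=80%-identity
    alignments (union of fragment reference spans)."""
    covered = np.zeros(ref_len, dtype=bool)
    for f in frags:
        if f.identity >= min_similarity:
            covered[max(0, f.ref_start) : min(ref_len, f.ref_end)] = True
    n_win = (ref_len + window - 1) // window
    out = np.empty(n_win)
    for w in range(n_win):
        seg = covered[w * window : (w + 1) * window]
        out[w] = seg.mean() if seg.size else 0.0
    return out
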