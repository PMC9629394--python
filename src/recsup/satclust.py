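"""Satellite-DNA array detection from tandem-repeat hit tables.

Tandem-repeat hits (Tandem Repeats Finder ``.dat`` dialect) are grouped when
they nest or overlap, groups separated by less than 100 bp are merged into
clusters, and clusters shorter than 1 kb are discarded.  Retained clusters
are classified by monomer periodicity (monomer / dimer / trimer of a base
unit, ~118 bp for the satellite family studied here), given a majority-rule
consensus with orientation against a family reference motif, and grouped
into large genomic pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "RepeatHit",
    "RepeatCluster",
    "Pool",
    "parse_trf",
    "write_trf",
    "cluster_hits",
    "classify_period",
    "consensus_and_orientation",
    "group_pools",
]

MERGE_GAP = 100  # bp; groups separated by less than this merge (strict <)
MIN_CLUSTER_LEN = 1000  # bp; clusters below this are discarded
BASE_PERIOD = 118  # bp monomer of the satellite family
PERIOD_TOL = 4  # bp tolerance around monomer/dimer/trimer periods
POOL_GAP = 200_000  # bp; clusters closer than this share a pool


@dataclass
class RepeatHit:
    """One tandem-repeat hit, 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    period: int
    copy_number: float
    motif: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"hit end {self.end} <= start {self.start}")
        if self.period < 1:
            raise ValueError("period must be >= 1")


@dataclass
class RepeatCluster:
    seq_id: str
    span: tuple[int, int]
    members: list[RepeatHit]
    consensus: str = ""
    orientation: str = ""  # "+" | "-" | "" (unclassified)
    identity: float = 0.0
    family_class: str = ""  # monomer|dimer|trimer|other

    @property
    def total_length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class Pool:
    clusters: list[RepeatCluster]

    @property
    def span(self) -> tuple[int, int]:
        return (self.clusters[0].span[0], self.clusters[-1].span[1])

    @property
    def total_satdna(self) -> int:
        return sum(c.total_length for c in self.clusters)


def parse_trf(path: str) -> list[RepeatHit]:
    """Read a Tandem Repeats Finder ``.dat``-dialect table.

    Hit lines (whitespace-separated, >=14 fields: start end period copies
    ... motif) appear under ``Sequence:`` headers; TRF coordinates are
    1-based inclusive and are converted to 0-based half-open.  Hits are
    returned sorted by (seq_id, start).
    """
    hits: list[RepeatHit] = []
    seq_id = ""
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                seq_id = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Parameters:", "Tandem", "Program", "Version",
                                "Gary", "Boston", "University")):
                continue
            f = line.split()
            if len(f) < 14:
                raise ValueError(f"{path}:{ln}: malformed TRF hit line")
            try:
                start, end, period = int(f[0]), int(f[1]), int(round(float(f[2])))
                copies = float(f[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed TRF hit line") from exc
            if end < start:
                raise ValueError(f"{path}:{ln}: hit end before start")
            hits.append(
                RepeatHit(
                    seq_id=seq_id,
                    start=start - 1,
                    end=end,
                    period=period,
                    copy_number=copies,
                    motif=f[13],
                )
            )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.end))
    return hits


def write_trf(hits: list[RepeatHit], path: str) -> None:
    """Write hits in the ``.dat`` dialect :func:`parse_trf` reads back."""
    with open(path, "w") as fh:
        last = None
        for h in sorted(hits, key=lambda h: (h.seq_id, h.start, h.end)):
            if h.seq_id != last:
                fh.write(f"Sequence: {h.seq_id}\n\n")
                last = h.seq_id
            comp = {b: round(100 * h.motif.upper().count(b) / max(1, len(h.motif)))
                    for b in "ACGT"}
            fh.write(
                f"{h.start + 1} {h.end} {h.period} {h.copy_number:.1f} "
                f"{len(h.motif)} 95 0 {2 * (h.end - h.start)} "
                f"{comp['A']} {comp['C']} {comp['G']} {comp['T']} 1.90 {h.motif}\n"
            )


def cluster_hits(
    hits: list[RepeatHit],
    merge_gap: int = MERGE_GAP,
    min_len: int = MIN_CLUSTER_LEN,
) -> list[RepeatCluster]:
    """Group nested/overlapping hits, merge near groups, drop short clusters.

    Hits whose spans overlap or nest are grouped; groups whose inter-span
    gap is strictly less than ``merge_gap`` are merged transitively; the
    surviving clusters keep their full genomic span and are discarded when
    that span is shorter than ``min_len``.  A single left-to-right sweep
    implements the transitive closure because spans are ordered.
    """
    out: list[RepeatCluster] = []
    for seq_id in sorted({h.seq_id for h in hits}):
        sel = sorted(
            (h for h in hits if h.seq_id == seq_id), key=lambda h: (h.start, h.end)
        )
        groups: list[list[RepeatHit]] = []
        for h in sel:
            if groups and h.start - max(m.end for m in groups[-1]) < merge_gap:
                groups[-1].append(h)
            else:
                groups.append([h])
        for g in groups:
            span = (min(m.start for m in g), max(m.end for m in g))
            if span[1] - span[0] >= min_len:
                out.append(RepeatCluster(seq_id=seq_id, span=span, members=g))
    return out


def classify_period(
    cluster: RepeatCluster, base: int = BASE_PERIOD, tol: int = PERIOD_TOL
) -> str:
    """Monomer/dimer/trimer call from the median member period.

    The family's repeat unit may be annotated at its monomer length or at a
    dimer/trimer multiple; the median period of the cluster members decides,
    within ``tol`` bp of base, 2×base or 3×base (the dimer/trimer windows
    cover the 235–236 and 353–354 bp annotations of a 118-bp unit).
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    med = float(np.median([m.period for m in cluster.members]))
    for mult, name in ((1, "monomer"), (2, "dimer"), (3, "trimer")):
        if abs(med - mult * base) <= tol:
            cluster.family_class = name
            return name
    cluster.family_class = "other"
    return "other"


_copy_aligner = Align.PairwiseAligner()
_copy_aligner.mode = "global"
_copy_aligner.match_score = 1
_copy_aligner.mismatch_score = -1
_copy_aligner.open_gap_score = -2
_copy_aligner.extend_gap_score = -2
_copy_aligner.end_insertion_score = 0
_copy_aligner.end_deletion_score = 0


def _identity(a: str, b: str) -> float:
    """Percent identity of a global free-end-gap alignment of two copies."""
    if not a or not b:
        return 0.0
    aln = _copy_aligner.align(a.upper(), b.upper())[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return 100.0 * matches / min(len(a), len(b))


def consensus_and_orientation(
    cluster: RepeatCluster, sequence: str, reference: str
) -> tuple[str, str, float]:
    """Cluster consensus, strand, and mean copy identity vs the reference.

    Monomer copies are cut from the cluster span in register with the
    best-scoring phase of the family reference (repeat annotations are
    rotationally ambiguous); the strand with the higher mean copy-to-
    reference identity wins; the consensus is the per-column majority over
    the phased copies, reported in reference orientation; identity is the
    mean copy-vs-consensus identity.  If no phase aligns at least 50% in
    either orientation the cluster is flagged unclassified (empty strand).
    """
    s, e = cluster.span
    region = sequence[s:e].upper()
    L = len(reference)
    if len(region) < 2 * L:
        raise ValueError("need at least 2 monomer copies in the cluster span")
    ref_rc = str(Seq(reference).reverse_complement())

    def phase_score(region_seq: str, ref: str) -> tuple[int, float]:
        best_phase, best_id = 0, -1.0
        for phase in range(L):
            if phase + L > len(region_seq):
                break
            ident = _identity(region_seq[phase : phase + L], ref)
            if ident > best_id:
                best_phase, best_id = phase, ident
        return best_phase, best_id

    fwd_phase, fwd_id = phase_score(region, reference)
    rc_region = str(Seq(region).reverse_complement())
    rev_phase, rev_id = phase_score(rc_region, reference)

    if max(fwd_id, rev_id) < 50.0:
        cluster.orientation = ""
        return "", "", 0.0
    if fwd_id >= rev_id:
        orientation, phase, work = "+", fwd_phase, region
    else:
        orientation, phase, work = "-", rev_phase, rc_region

    copies = [
        work[i : i + L]
        for i in range(phase, len(work) - L + 1, L)
    ]
    cols = np.array([list(c) for c in copies])
    consensus = "".join(
        max("ACGT", key=lambda b, col=col: np.sum(col == b)) for col in cols.T
    )
    ident = float(np.mean([_identity(c, consensus) for c in copies]))
    cluster.consensus = consensus
    cluster.orientation = orientation
    cluster.identity = ident
    return consensus, orientation, ident


def group_pools(
    clusters: list[RepeatCluster], pool_gap: int = POOL_GAP
) -> list[Pool]:
    """Merge position-sorted clusters separated by <= pool_gap into pools."""
    pools: list[Pool] = []
    for c in sorted(clusters, key=lambda c: (c.seq_id, c.span)):
        if (
            pools
            and pools[-1].clusters[-1].seq_id == c.seq_id
            and c.span[0] - pools[-1].span[1] <= pool_gap
        ):
            pools[-1].clusters.append(c)
        else:
            pools.append(Pool(clusters=[c]))
    return pools
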