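"""Synthetic chromosome pairs with known planted structure.

Every downstream stage consumes outputs of upstream shell tools (repeat
finders, aligners, LTR predictors, mapping software) that operate on
chromosome-scale assemblies; none of those inputs can ship with a small
package.  This module therefore builds a pair of homologous chromosomes with
the statistical structure the analyses assume — satellite arrays built from
a curved ~118-bp motif with phased A-tracts, LTR elements whose LTR–LTR
mismatch counts follow a known Poisson mixture, planted InDels and one
inversion, and paired genetic maps with a regionally compressed cM scale —
together with truth tables, so every stage is testable against ground truth.

All coordinates are 0-based half-open internally; exported GFF3 is 1-based
closed, BED is 0-based half-open, repeat tables use the 1-based TRF dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mapcomp import GeneticMap
from .satclust import RepeatHit

__all__ = [
    "SyntheticSpec",
    "ChromosomePair",
    "make_motif",
    "make_ltr_element",
    "make_chromosome_pair",
    "make_maps",
    "default_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MOTIF_LENGTH = 118  # satellite monomer length
A_TRACT_SPACING = 20  # centre-to-centre phasing of planted A-tracts
N_TRACTS = 3  # A-tracts per monomer


@dataclass
class SyntheticSpec:
    """Recipe for one homologous chromosome pair plus paired genetic maps.

    ``satellite_pools`` lists tandem arrays as (start, n_copies, motif_id);
    arrays closer than the pool-grouping distance form one pool.
    ``ltr_elements`` lists (position, ltr_length, component) where component
    indexes ``mixture.lambdas``: each element's planted mismatch count is
    Poisson with that component's rate.  ``indels`` are (position, length,
    which_genome): a segment present only in that genome.  ``map_spec`` is
    (n_markers, suppression_interval, suppression_factor).
    """

    seed: int = 0
    chrom_length: int = 2_000_000
    satellite_pools: list[tuple[int, int, int]] = field(default_factory=list)
    ltr_elements: list[tuple[int, int, int]] = field(default_factory=list)
    mixture: tuple[tuple[float, ...], tuple[float, ...]] = ((2.0, 9.0), (0.4, 0.6))
    indels: list[tuple[int, int, str]] = field(default_factory=list)
    inversion: tuple[int, int] | None = None
    map_spec: tuple[int, tuple[int, int], float] = (41, (750_000, 1_300_000), 4.0)
    global_coefficient: float = 1.6  # whole-map cM compression of the test cross
    ltr_internal_length: int = 400
    sat_divergence: float = 0.02  # per-base substitution rate within array copies

    def validate(self) -> None:
        lambdas, weights = self.mixture
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(l <= 0 for l in lambdas):
            raise ValueError("mixture lambdas must be positive")
        if any(ltr < 180 for _, ltr, _ in self.ltr_elements):
            raise ValueError("ltr_length must be >= 180")
        if any(c >= len(lambdas) for _, _, c in self.ltr_elements):
            raise ValueError("mixture component index out of range")
        n_markers, (s, e), factor = self.map_spec
        if factor <= 1:
            raise ValueError("suppression_factor must be > 1")
        if n_markers < 10:
            raise ValueError("need at least 10 markers")
        if not (0 <= s < e <= self.chrom_length):
            raise ValueError("suppression_interval outside chromosome")
        spans = self._feature_spans()
        spans.sort()
        for (a0, a1, na), (b0, b1, nb) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"planted features overlap: {na} and {nb}")
            if a1 > self.chrom_length or b1 > self.chrom_length:
                raise ValueError("planted feature beyond chromosome end")

    def _feature_spans(self) -> list[tuple[int, int, str]]:
        spans = []
        for i, (start, n_copies, _mid) in enumerate(self.satellite_pools):
            spans.append((start, start + n_copies * MOTIF_LENGTH, f"array_{i}"))
        for i, (pos, ltr_len, _c) in enumerate(self.ltr_elements):
            spans.append(
                (pos, pos + 2 * ltr_len + self.ltr_internal_length, f"ltr_{i}")
            )
        for i, (pos, length, which) in enumerate(self.indels):
            end = pos + (length if which == "A" else 1)
            spans.append((pos, end, f"indel_{i}"))
        if self.inversion:
            spans.append((*self.inversion, "inversion"))
        return spans


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def make_motif(
    length: int = MOTIF_LENGTH,
    a_tract_spacing: int = A_TRACT_SPACING,
    n_tracts: int = N_TRACTS,
    seed: int = 0,
    tract_len: int = 5,
) -> str:
    """A satellite monomer with ``n_tracts`` phased A-tracts.

    The background is random ACGT with A/T runs capped at 3 nt so the
    planted tracts are the only tracts; tract centres are spaced
    ``a_tract_spacing`` apart and the series is centred in the motif.
    Deterministic per seed.
    """
    if not 4 <= tract_len <= 6:
        raise ValueError("tract_len must be 4-6 nt")
    if length < n_tracts * (tract_len + 1):
        raise ValueError("motif too short for the requested tracts")
    extent = (n_tracts - 1) * a_tract_spacing + tract_len if n_tracts else 0
    if extent > length:
        raise ValueError(
            f"{n_tracts} tracts spaced {a_tract_spacing} bp need {extent} bp "
            f"> motif length {length}"
        )
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for _ in range(length):
        b = "ACGT"[rng.integers(0, 4)]
        while b in "AT" and out[-3:] == [b, b, b]:
            b = "ACGT"[rng.integers(0, 4)]
        out.append(b)
    if n_tracts:
        first = (length - extent) // 2
        for t in range(n_tracts):
            start = first + t * a_tract_spacing
            out[start : start + tract_len] = ["A"] * tract_len
            # G/C guards keep each planted tract maximal and isolated
            if start > 0:
                out[start - 1] = "GC"[rng.integers(0, 2)]
            if start + tract_len < length:
                out[start + tract_len] = "GC"[rng.integers(0, 2)]
    return "".join(out)


def make_ltr_element(
    ltr_length: int,
    k_mismatches: int,
    n_indels: int = 0,
    seed: int = 0,
    internal_length: int = 400,
    sub_region: tuple[int, int] | None = None,
) -> tuple[str, dict]:
    """One LTR retrotransposon: two LTR copies flanking an internal region.

    The 3′ LTR is the 5′ copy with exactly ``k_mismatches`` substitutions
    (at distinct positions, optionally confined to ``sub_region``) and
    ``n_indels`` short (1–5 bp) indels.  Returns the element sequence and a
    truth record with the planted counts and LTR spans within the element.
    """
    if ltr_length < 180:
        raise ValueError("ltr_length must be >= 180")
    region = sub_region or (0, ltr_length)
    if not (0 <= region[0] < region[1] <= ltr_length):
        raise ValueError("sub_region outside the LTR")
    if k_mismatches > region[1] - region[0]:
        raise ValueError("more mismatches than substitutable positions")
    rng = np.random.default_rng(seed)
    ltr5 = _random_seq(rng, ltr_length)
    internal = _random_seq(rng, internal_length)
    ltr3 = list(ltr5)
    sub_pos = sorted(
        rng.choice(np.arange(*region), size=k_mismatches, replace=False).tolist()
    )
    for p in sub_pos:
        ltr3[p] = rng.choice([b for b in "ACGT" if b != ltr3[p]])
    indel_events = []
    for _ in range(n_indels):
        ln = int(rng.integers(1, 6))
        # keep indels clear of the LTR ends so free-end-gap alignment stays
        # well-posed; clear of planted substitutions so events are countable
        while True:
            p = int(rng.integers(10, len(ltr3) - 10))
            if all(abs(p - sp) > 6 for sp in sub_pos):
                break
        if rng.random() < 0.5:
            ltr3[p:p] = list(_random_seq(rng, ln))
            indel_events.append(("ins", p, ln))
        else:
            del ltr3[p : p + ln]
            indel_events.append(("del", p, ln))
    ltr3_s = "".join(ltr3)
    element = ltr5 + internal + ltr3_s
    truth = {
        "true_k": k_mismatches,
        "n_indels": n_indels,
        "events": k_mismatches + n_indels,
        "sub_positions": sub_pos,
        "indel_events": indel_events,
        "ltr5_span": (0, ltr_length),
        "ltr3_span": (ltr_length + internal_length, len(element)),
    }
    return element, truth


@dataclass
class ChromosomePair:
    """A synthetic homologous pair plus all truth tables."""

    spec: SyntheticSpec
    seq_a: str
    seq_b: str
    elements: list[dict]  # id, span, ltr spans, k, component (A coordinates)
    sat_hits: list[RepeatHit]  # planted arrays, A coordinates
    indels: list[tuple[int, int, str]]  # A coordinates
    inversion: tuple[int, int] | None
    fragments: list[tuple]  # PAF-ready rows (A = reference, B = query)
    pools_truth: list[dict]  # planted pool spans and sizes

    def write(self, out_dir) -> dict:
        """Write FASTA, GFF3/BED/TRF truth, PAF fragments and both maps."""
        import os

        from . import satclust
        from .mapcomp import write_map

        os.makedirs(out_dir, exist_ok=True)
        paths = {}

        def p(name):
            paths[name] = os.path.join(out_dir, name)
            return paths[name]

        for name, seq in (("genomeA.fasta", self.seq_a), ("genomeB.fasta", self.seq_b)):
            with open(p(name), "w") as fh:
                fh.write(f">{name.split('.')[0]}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

        with open(p("elements.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for el in self.elements:
                s, e = el["span"]
                fh.write(
                    f"genomeA\trecsup\tLTR_retrotransposon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={el['id']};mismatches={el['k']};component={el['component']}\n"
                )
                for tag in ("ltr5_span", "ltr3_span"):
                    ls, le = el[tag]
                    fh.write(
                        f"genomeA\trecsup\tlong_terminal_repeat\t{ls + 1}\t{le}\t"
                        f".\t+\t.\tParent={el['id']}\n"
                    )

        with open(p("indels.bed"), "w") as fh:
            for i, (pos, length, which) in enumerate(self.indels):
                end = pos + (length if which == "A" else 1)
                fh.write(f"genomeA\t{pos}\t{end}\tindel_{i}_{which}_{length}\n")
            if self.inversion:
                s, e = self.inversion
                fh.write(f"genomeA\t{s}\t{e}\tinversion\n")

        satclust.write_trf(self.sat_hits, p("satellites.dat"))

        la, lb = len(self.seq_a), len(self.seq_b)
        with open(p("alignments.paf"), "w") as fh:
            for row in self.fragments:
                qs, qe, strand, ts, te = row
                block = te - ts
                matches = int(round(block * 0.99))
                fh.write(
                    f"genomeB\t{lb}\t{qs}\t{qe}\t{strand}\tgenomeA\t{la}\t"
                    f"{ts}\t{te}\t{matches}\t{block}\t60\n"
                )

        map_ref, map_test = make_maps(self.spec)
        write_map(map_ref, p("map_ref.tsv"), chrom="5S")
        write_map(map_test, p("map_test.tsv"), chrom="5S")
        return paths


def _mutate_copy(motif: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return motif
    out = list(motif)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def make_chromosome_pair(spec: SyntheticSpec) -> ChromosomePair:
    """Build genome A, derive genome B by planted edits, emit truth tables.

    Genome A carries the satellite arrays and LTR elements on a uniform
    ACGT background; genome B is A with the planted InDels applied (segments
    tagged "A" deleted from B, segments tagged "B" inserted into B) and the
    inversion reverse-complemented.  Alignment fragments covering every
    unedited collinear segment (minus-strand inside the inversion) are
    emitted in PAF form, standing in for upstream aligner output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lambdas, weights = spec.mixture

    genome = np.frombuffer(
        _random_seq(rng, spec.chrom_length).encode(), dtype=np.uint8
    ).copy()

    # satellite arrays
    sat_hits: list[RepeatHit] = []
    motifs: dict[int, str] = {}
    for start, n_copies, motif_id in spec.satellite_pools:
        if motif_id not in motifs:
            motifs[motif_id] = make_motif(seed=spec.seed * 1000 + motif_id)
        motif = motifs[motif_id]
        copies = [
            _mutate_copy(motif, spec.sat_divergence, rng) for _ in range(n_copies)
        ]
        arr = "".join(copies)
        genome[start : start + len(arr)] = np.frombuffer(arr.encode(), np.uint8)
        sat_hits.append(
            RepeatHit(
                seq_id="genomeA",
                start=start,
                end=start + len(arr),
                period=len(motif),
                copy_number=float(n_copies),
                motif=motif,
            )
        )

    # planted pools: arrays closer than the pool-grouping distance
    pools_truth: list[dict] = []
    for h in sorted(sat_hits, key=lambda h: h.start):
        if pools_truth and h.start - pools_truth[-1]["span"][1] <= 200_000:
            pools_truth[-1]["span"] = (pools_truth[-1]["span"][0], h.end)
            pools_truth[-1]["size"] += h.end - h.start
            pools_truth[-1]["n_arrays"] += 1
        else:
            pools_truth.append(
                {"span": (h.start, h.end), "size": h.end - h.start, "n_arrays": 1}
            )

    # LTR elements with Poisson-mixture mismatch counts
    elements: list[dict] = []
    for i, (pos, ltr_len, comp) in enumerate(spec.ltr_elements):
        k = int(rng.poisson(lambdas[comp]))
        k = min(k, 150)
        seq, truth = make_ltr_element(
            ltr_len,
            k,
            n_indels=0,
            seed=int(rng.integers(0, 2**31)),
            internal_length=spec.ltr_internal_length,
            sub_region=(0, min(150, ltr_len)),
        )
        genome[pos : pos + len(seq)] = np.frombuffer(seq.encode(), np.uint8)
        elements.append(
            {
                "id": f"ltr_{i}",
                "span": (pos, pos + len(seq)),
                "ltr5_span": (pos + truth["ltr5_span"][0], pos + truth["ltr5_span"][1]),
                "ltr3_span": (pos + truth["ltr3_span"][0], pos + truth["ltr3_span"][1]),
                "k": k,
                "component": comp,
            }
        )
    elements.sort(key=lambda e: e["span"])

    seq_a = genome.tobytes().decode()

    # genome B: apply inversion and indels in descending coordinate order
    comp_map = bytes.maketrans(b"ACGT", b"TGCA")
    edits = []  # (a_start, a_end_in_A, replacement_str, kind)
    for pos, length, which in spec.indels:
        if which == "A":
            edits.append((pos, pos + length, "", "del_in_B"))
        else:
            ins = _random_seq(rng, length)
            edits.append((pos, pos, ins, "ins_in_B"))
    if spec.inversion:
        s, e = spec.inversion
        inv = seq_a[s:e].encode().translate(comp_map)[::-1].decode()
        edits.append((s, e, inv, "inversion"))
    edits.sort()
    b_parts = []
    cursor = 0
    for a0, a1, repl, _kind in edits:
        b_parts.append(seq_a[cursor:a0])
        b_parts.append(repl)
        cursor = a1
    b_parts.append(seq_a[cursor:])
    seq_b = "".join(b_parts)

    # collinear truth fragments: walk the edits, track the A->B offset
    fragments: list[tuple] = []
    offset = 0  # b_pos - a_pos on collinear segments
    cursor = 0

    def emit(a0: int, a1: int, off: int) -> None:
        # split long segments so chaining sees several fragments
        chunk = 200_000
        for s0 in range(a0, a1, chunk):
            s1 = min(s0 + chunk, a1)
            if s1 - s0 >= 200:
                fragments.append((s0 + off, s1 + off, "+", s0, s1))

    for a0, a1, repl, kind in edits:
        emit(cursor, a0, offset)
        if kind == "inversion":
            # the inverted block aligns on the minus strand at the same locus
            fragments.append((a0 + offset, a1 + offset, "-", a0, a1))
        offset += len(repl) - (a1 - a0)
        cursor = a1
    emit(cursor, len(seq_a), offset)

    return ChromosomePair(
        spec=spec,
        seq_a=seq_a,
        seq_b=seq_b,
        elements=elements,
        sat_hits=sat_hits,
        indels=list(spec.indels),
        inversion=spec.inversion,
        fragments=fragments,
        pools_truth=pools_truth,
    )


def make_maps(spec: SyntheticSpec) -> tuple[GeneticMap, GeneticMap]:
    """Paired genetic maps: an intraspecific reference and a compressed test.

    Both maps share marker names and order.  Marker bp positions spread over
    the chromosome with seed-fixed jitter; reference inter-marker distances
    are proportional to physical distance (~2.5e-5 cM/bp); the test map
    divides every distance by the global reduction coefficient and distances
    inside the suppression interval additionally by the suppression factor.
    """
    n_markers, (sup_s, sup_e), factor = spec.map_spec
    rng = np.random.default_rng(spec.seed + 77)
    edges = np.linspace(0, spec.chrom_length, n_markers)
    jitter = rng.uniform(-0.3, 0.3, n_markers) * (edges[1] - edges[0])
    jitter[0] = jitter[-1] = 0.0
    bp = np.sort((edges + jitter).astype(int))
    rate = 2.5e-5  # cM per bp
    d_ref = np.diff(bp) * rate * rng.uniform(0.6, 1.4, n_markers - 1)
    d_test = d_ref / spec.global_coefficient
    for i in range(n_markers - 1):
        if bp[i] >= sup_s and bp[i + 1] <= sup_e:
            d_test[i] /= factor
    names = [f"M{i:04d}" for i in range(n_markers)]
    cm_ref = np.concatenate([[0.0], np.cumsum(d_ref)])
    cm_test = np.concatenate([[0.0], np.cumsum(d_test)])
    bp_map = {n: (int(b), int(b) + 100) for n, b in zip(names, bp)}
    map_ref = GeneticMap(
        population="reference_cross",
        markers=[(n, round(float(c), 4)) for n, c in zip(names, cm_ref)],
        bp=bp_map,
    )
    map_test = GeneticMap(
        population="test_cross",
        markers=[(n, round(float(c), 4)) for n, c in zip(names, cm_test)],
        bp=bp_map,
    )
    return map_ref, map_test


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The demo study conditions: 2-Mb pair, 2 satellite pools, 60 LTR
    elements with a (2, 9) mismatch mixture, two ≥50-kb InDels, one small
    InDel, one 60-kb inversion, and a 4× suppressed map interval."""
    rng = np.random.default_rng(seed + 12345)
    pools = [
        (300_000, 40, 0),
        (306_000, 30, 0),
        (311_000, 35, 0),
        (1_450_000, 60, 0),
        (1_460_000, 50, 0),
    ]
    indels = [
        (600_000, 8_000, "B"),
        (800_000, 60_000, "B"),
        (1_200_000, 80_000, "A"),
    ]
    inversion = (1_700_000, 1_760_000)
    blocked = [(s, s + n * MOTIF_LENGTH + 2_000) for s, n, _ in pools]
    blocked += [(p - 2_000, p + l + 2_000) for p, l, _ in indels]
    blocked.append((inversion[0] - 2_000, inversion[1] + 2_000))
    elements: list[tuple[int, int, int]] = []
    taken: list[tuple[int, int]] = []
    elem_len = 2 * 200 + 400
    while len(elements) < 60:
        pos = int(rng.integers(20_000, 2_000_000 - 20_000))
        span = (pos, pos + elem_len)
        if any(s < span[1] and span[0] < e for s, e in blocked + taken):
            continue
        # a young-element neighbourhood: the 0.4-0.7 Mb region draws from
        # the low-mismatch component, elsewhere the mixture weights apply
        if 400_000 <= pos <= 700_000:
            comp = 0
        else:
            comp = int(rng.choice([0, 1], p=[0.4, 0.6]))
        elements.append((pos, 200, comp))
        taken.append(span)
    elements.sort()
    return SyntheticSpec(
        seed=seed,
        chrom_length=2_000_000,
        satellite_pools=pools,
        ltr_elements=elements,
        mixture=((2.0, 9.0), (0.4, 0.6)),
        indels=indels,
        inversion=inversion,
        map_spec=(41, (750_000, 1_300_000), 4.0),
    )
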