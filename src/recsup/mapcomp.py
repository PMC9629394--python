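"""Comparative analysis of genetic linkage maps sharing markers.

A cross between diverged homologues shows regionally compressed genetic
(cM) distances where recombination is suppressed.  Given a test map (the
suppressed cross) and one or more reference maps sharing markers, the module
builds per-interval distance ratios, computes the whole-map reduction
coefficient, and calls suppression regions: maximal runs of intervals whose
ratio exceeds both an absolute threshold (default 3, the lower edge of the
3–3.5× criterion) and twice the whole-map coefficient.  Called regions are
anchored to physical coordinates when flanking markers carry them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneticMap",
    "SharedInterval",
    "SuppressionRegion",
    "read_map",
    "write_map",
    "skeletal",
    "shared_intervals",
    "reduction_coefficient",
    "detect_suppression",
    "detect_suppression_consensus",
    "anchor_region",
]

RATIO_MIN_DEFAULT = 3.0  # lower edge of the 3-3.5x interval-compression rule
FOLD_OVER_COEFF_DEFAULT = 2.0  # ratio must exceed 2x the whole-map coefficient


@dataclass
class GeneticMap:
    """Ordered markers with cM positions for one mapping population."""

    population: str
    markers: list[tuple[str, float]]  # (name, cM), non-decreasing
    bp: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        names = [n for n, _ in self.markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names: {dup}")
        pos = [p for _, p in self.markers]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValueError("cM positions must be non-decreasing")
        if any(p < 0 for p in pos):
            raise ValueError("cM positions must be >= 0")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.markers]

    def position(self, name: str) -> float:
        for n, p in self.markers:
            if n == name:
                return p
        raise KeyError(name)

    @property
    def length(self) -> float:
        return self.markers[-1][1] - self.markers[0][1]


@dataclass
class SharedInterval:
    """One consecutive shared-marker pair with its ref/test distance ratio."""

    left_marker: str
    right_marker: str
    d_ref: float
    d_test: float

    @property
    def infinite(self) -> bool:
        return self.d_test == 0 and self.d_ref > 0

    @property
    def ratio(self) -> float:
        if self.d_test == 0:
            return math.inf if self.d_ref > 0 else 1.0
        return self.d_ref / self.d_test


@dataclass
class SuppressionRegion:
    flank_left: str
    flank_right: str
    mean_ratio: float
    n_intervals: int
    physical_span: tuple[int, int] | None = None


def read_map(path: str) -> GeneticMap:
    """Read a marker map TSV with header: marker, chrom, cM[, bp].

    Markers are sorted by cM; duplicate names and negative positions are
    rejected with the offending line identified.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for want in ("marker", "cm"):
        if want not in cols:
            raise ValueError(f"{path}: missing column {want!r}")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 markers")
    dups = df[cols["marker"]][df[cols["marker"]].duplicated()].tolist()
    if dups:
        raise ValueError(f"{path}: duplicate marker names {dups}")
    if (df[cols["cm"]] < 0).any():
        bad = int(df.index[df[cols["cm"]] < 0][0]) + 2  # +header +0-base
        raise ValueError(f"{path}:{bad}: negative cM position")
    df = df.sort_values(cols["cm"], kind="stable")
    bp = {}
    if "bp" in cols:
        for _, row in df.iterrows():
            b = int(row[cols["bp"]])
            bp[str(row[cols["marker"]])] = (b, b)
    pop = str(df[cols["chrom"]].iloc[0]) if "chrom" in cols else path
    return GeneticMap(
        population=pop,
        markers=[(str(m), float(c)) for m, c in zip(df[cols["marker"]], df[cols["cm"]])],
        bp=bp,
    )


def write_map(gmap: GeneticMap, path: str, chrom: str | None = None) -> None:
    """Write the 4-column TSV read back by :func:`read_map`."""
    rows = []
    for name, cm in gmap.markers:
        row = {"marker": name, "chrom": chrom or gmap.population, "cM": cm}
        if name in gmap.bp:
            row["bp"] = gmap.bp[name][0]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def skeletal(gmap: GeneticMap) -> GeneticMap:
    """Collapse cosegregating markers (identical cM) to one skeletal marker.

    The representative of each cosegregating group is the lexicographically
    smallest name, mirroring skeletal-marker maps where one marker stands for
    a group occupying a single position.
    """
    by_pos: dict[float, list[str]] = {}
    for name, cm in gmap.markers:
        by_pos.setdefault(cm, []).append(name)
    markers = [(min(names), cm) for cm, names in sorted(by_pos.items())]
    return GeneticMap(
        population=gmap.population,
        markers=markers,
        bp={n: s for n, s in gmap.bp.items() if n in {m for m, _ in markers}},
    )


def shared_intervals(
    map_ref: GeneticMap, map_test: GeneticMap
) -> list[SharedInterval]:
    """Per-interval distances between consecutive markers shared by name.

    Both maps are reduced to their shared, skeletal markers, which must be
    collinear (same order); an order conflict raises with the discordant
    markers listed.  The ratio orientation is reference over test, so a
    compressed test map yields ratios > 1.
    """
    ref = skeletal(map_ref)
    test = skeletal(map_test)
    shared = [n for n in test.names if n in set(ref.names)]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared markers")
    order_ref = [n for n in ref.names if n in set(shared)]
    if order_ref != shared:
        discordant = [a for a, b in zip(order_ref, shared) if a != b]
        raise ValueError(f"marker order conflict between maps: {discordant}")
    out = []
    for left, right in zip(shared, shared[1:]):
        out.append(
            SharedInterval(
                left_marker=left,
                right_marker=right,
                d_ref=ref.position(right) - ref.position(left),
                d_test=test.position(right) - test.position(left),
            )
        )
    return out


def reduction_coefficient(map_ref: GeneticMap, map_test: GeneticMap) -> float:
    """Whole-map reduction: shared-span cM length, reference over test."""
    ivs = shared_intervals(map_ref, map_test)
    ref_span = sum(iv.d_ref for iv in ivs)
    test_span = sum(iv.d_test for iv in ivs)
    if test_span <= 0:
        raise ValueError("test map shared span is zero")
    if ref_span <= 0:
        raise ValueError("reference map shared span is zero")
    return ref_span / test_span


def detect_suppression(
    intervals: list[SharedInterval],
    coeff: float,
    ratio_min: float = RATIO_MIN_DEFAULT,
    fold_over_coeff: float = FOLD_OVER_COEFF_DEFAULT,
) -> list[SuppressionRegion]:
    """Merge runs of qualifying intervals into suppression regions.

    An interval qualifies when its ratio exceeds both ``ratio_min`` and
    ``fold_over_coeff × coeff``; infinite ratios (zero test distance with
    nonzero reference distance) qualify.  Maximal runs of consecutive
    qualifying intervals are reported as regions flanked by the outer
    markers of the run.
    """
    if coeff <= 0:
        raise ValueError("coeff must be positive")
    cut = max(ratio_min, fold_over_coeff * coeff)
    qual = [iv.ratio > cut for iv in intervals]
    regions = []
    i = 0
    while i < len(intervals):
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(intervals) and qual[j + 1]:
            j += 1
        run = intervals[i : j + 1]
        finite = [iv.ratio for iv in run if not math.isinf(iv.ratio)]
        mean_ratio = sum(finite) / len(finite) if finite else math.inf
        regions.append(
            SuppressionRegion(
                flank_left=run[0].left_marker,
                flank_right=run[-1].right_marker,
                mean_ratio=mean_ratio,
                n_intervals=len(run),
            )
        )
        i = j + 1
    return regions


def detect_suppression_consensus(
    map_test: GeneticMap,
    map_refs: list[GeneticMap],
    ratio_min: float = RATIO_MIN_DEFAULT,
    fold_over_coeff: float = FOLD_OVER_COEFF_DEFAULT,
) -> list[SuppressionRegion]:
    """Suppression regions qualifying against every reference map.

    An interval of the test map counts only when it qualifies in all
    test-vs-reference comparisons (markers restricted to each shared set),
    the consensus the multi-population comparison demands.
    """
    if not map_refs:
        raise ValueError("need at least one reference map")
    per_ref = []
    for ref in map_refs:
        ivs = shared_intervals(ref, map_test)
        coeff = reduction_coefficient(ref, map_test)
        cut = max(ratio_min, fold_over_coeff * coeff)
        per_ref.append({(iv.left_marker, iv.right_marker): iv for iv in ivs
                        if iv.ratio > cut})
    # consensus on the first reference's interval structure
    base = shared_intervals(map_refs[0], map_test)
    coeff0 = reduction_coefficient(map_refs[0], map_test)
    keep = []
    for iv in base:
        key = (iv.left_marker, iv.right_marker)
        if all(key in d for d in per_ref):
            keep.append(iv)
    kept_keys = {(iv.left_marker, iv.right_marker) for iv in keep}
    marked = [iv if (iv.left_marker, iv.right_marker) in kept_keys
              else SharedInterval(iv.left_marker, iv.right_marker, 0.0, 1.0)
              for iv in base]
    return detect_suppression(marked, coeff0, ratio_min, fold_over_coeff)


def anchor_region(
    left_flank: tuple[str, int, int], right_flank: tuple[str, int, int]
) -> dict:
    """Physical span between two flanking markers with known coordinates.

    Each flank is (marker_name, bp_start, bp_end) on the pseudomolecule.
    The span runs from the left flank's start to the right flank's end and
    is reported in bp and in Mb rounded to one decimal.
    """
    lname, lstart, _lend = left_flank
    rname, _rstart, rend = right_flank
    if rend < lstart:
        raise ValueError(
            f"right flank {rname} ends before left flank {lname} starts"
        )
    span_bp = rend - lstart
    return {
        "left_marker": lname,
        "right_marker": rname,
        "span_bp": span_bp,
        "span_mb": round(span_bp / 1e6, 1),
    }
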