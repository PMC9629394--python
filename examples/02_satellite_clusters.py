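"""Cluster tandem-repeat hits into satellite arrays and pools.

Writes the demo chromosome's repeat-hit table in Tandem Repeats Finder
dialect, re-reads it, merges hits into >=1-kb clusters, classifies their
periodicity against the 118-bp monomer, derives a consensus with
orientation, and groups nearby clusters into pools.
"""

import tempfile

from recsup import satclust, synth

pair = synth.make_chromosome_pair(synth.default_spec(seed=0))
with tempfile.NamedTemporaryFile("w", suffix=".dat", delete=False) as fh:
    trf_path = fh.name
satclust.write_trf(pair.sat_hits, trf_path)

hits = satclust.parse_trf(trf_path)
clusters = satclust.cluster_hits(hits)
reference = hits[0].motif
for c in clusters:
    satclust.classify_period(c)
    satclust.consensus_and_orientation(c, pair.seq_a, reference)
    print(
        f"cluster {c.span[0]:>9,}-{c.span[1]:<9,} {c.total_length:>6,} bp "
        f"{c.family_class:8s} strand {c.orientation} identity {c.identity:.1f}%"
    )

pools = satclust.group_pools(clusters)
for i, p in enumerate(pools, 1):
    print(
        f"pool {i}: {p.span[0]:,}-{p.span[1]:,}, "
        f"{len(p.clusters)} clusters, {p.total_satdna:,} bp of satellite DNA"
    )
print(
    "# arrays separated by <100 bp merge into clusters; clusters within\n"
    "# 200 kb form pools - the heterochromatin islands of the short-arm\n"
    "# suppression region."
)
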