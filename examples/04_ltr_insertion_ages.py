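"""Date LTR-retrotransposon insertions and scan for young-element hotspots.

Re-aligns the two LTRs of every planted element (150-bp fragments, free end
gaps), models the mismatch histogram with a negative binomial and a Poisson
mixture, converts the modal divergence into a young/old age threshold via
T = d / 2 mu, and runs the 10-element sliding hypergeometric scan.
"""

from recsup import ltrage, synth

pair = synth.make_chromosome_pair(synth.default_spec(seed=0))
elements = []
for t in pair.elements:
    el = ltrage.LTRElement(
        id=t["id"], seq_id="genomeA", start=t["span"][0], end=t["span"][1],
        ltr5=t["ltr5_span"], ltr3=t["ltr3_span"],
    )
    el.k, el.events, _ = ltrage.align_ltrs(
        pair.seq_a[slice(*el.ltr5)], pair.seq_a[slice(*el.ltr3)]
    )
    elements.append(el)

dist = ltrage.mismatch_histogram(elements)
model = ltrage.fit_divergence_model(dist, seed=0)
threshold = ltrage.threshold_from_model(model)
ltrage.classify_age(elements, threshold)

lam, w, r2 = model.mixture
print(f"elements: {dist.n_elements}, mismatch mean {dist.mean:.2f}")
print(f"negative binomial: r={model.nbd[0]:.2f} p={model.nbd[1]:.2f}")
print(f"gamma mode (modal divergence): {model.gamma_mode:.2f} mismatches")
print(f"mixture lambdas={[round(x, 2) for x in lam]} "
      f"weights={[round(x, 2) for x in w]} r2={r2:.3f}")
print(f"young/old threshold: {threshold} mismatches "
      f"(~{threshold / (2 * 1.3e-8 * 150) / 1e6:.2f} Myr)")

scan = ltrage.enrichment_scan(elements)
hot = [x for x in scan.windows if x["p_over"] < 0.05]
for x in hot:
    print(f"young-element hotspot {x['span'][0]:,}-{x['span'][1]:,}: "
          f"{x['n_young']}/10 young, p_over={x['p_over']:.3f}")
print(
    "# LTR pairs are identical at insertion; their divergence dates the\n"
    "# element. Windows enriched in young insertions localize recent\n"
    "# transposition bursts - here the planted 0.4-0.7 Mb neighbourhood."
)
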