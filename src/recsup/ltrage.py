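"""LTR-retrotransposon insertion dating from LTR–LTR divergence.

The two long terminal repeats of one element are identical at insertion and
diverge afterwards, so the mismatch count between them is a molecular clock.
The pipeline: align 150-bp LTR fragments with free end gaps and count
substitutions (each indel run is one event); model the element-wide mismatch
histogram with a negative binomial (whose Poisson–Gamma mixing density gives
a modal divergence — the young/old threshold) and with a Poisson mixture fit
by EM (age fractions); convert mismatches to years via T = d / 2μ; and scan
for windows of 10 consecutive elements enriched or depleted in young
insertions with exact hypergeometric tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy import optimize, special, stats

__all__ = [
    "LTRElement",
    "MismatchDistribution",
    "DivergenceModel",
    "EnrichmentScan",
    "align_ltrs",
    "mismatch_histogram",
    "fit_nbd",
    "gamma_mode_age",
    "fit_poisson_mixture",
    "select_n_components",
    "classify_age",
    "threshold_from_model",
    "enrichment_scan",
]

MU_DEFAULT = 1.3e-8  # substitutions / site / year, plant LTR retrotransposons
FRAGMENT_DEFAULT = 150  # bp of each LTR used for divergence
MIN_LTR_LENGTH = 180  # elements with shorter LTRs are excluded upstream


@dataclass
class LTRElement:
    """One LTR retrotransposon with paired-LTR divergence bookkeeping."""

    id: str
    seq_id: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    k: int = 0  # substitution mismatches between LTR fragments
    events: int = 0  # k + indel runs
    age_years: float = 0.0
    age_class: str = ""  # "young" | "old"

    @property
    def ltr_length(self) -> int:
        return min(self.ltr5[1] - self.ltr5[0], self.ltr3[1] - self.ltr3[0])


@dataclass
class MismatchDistribution:
    counts: dict[int, int]

    @property
    def n_elements(self) -> int:
        return sum(self.counts.values())

    def expand(self) -> np.ndarray:
        """Per-element sample of k values (order arbitrary)."""
        return np.repeat(
            np.fromiter(self.counts.keys(), dtype=int),
            np.fromiter(self.counts.values(), dtype=int),
        )

    @property
    def mean(self) -> float:
        x = self.expand()
        return float(x.mean())

    @property
    def var(self) -> float:
        x = self.expand()
        return float(x.var())


@dataclass
class DivergenceModel:
    nbd: tuple[float, float]  # (r, p); r = inf sentinel when not overdispersed
    gamma: tuple[float, float]  # (shape, scale) of the NBD mixing density
    gamma_mode: float
    mixture: tuple[list[float], list[float], float]  # lambdas, weights, r^2
    young_threshold: int
    overdispersed: bool = True


@dataclass
class EnrichmentScan:
    windows: list[dict]  # first, last, n_young, p_over, p_under, span
    window_size: int = 10
    step: int = 1
    n_total: int = 0
    n_young: int = 0


# affine gap costs keep a multi-bp indel in one gap run, so it counts as
# one evolutionary event; end gaps are free (150-bp fragments may overhang)
_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -3
_aligner.extend_gap_score = -1
_aligner.end_insertion_score = 0
_aligner.end_deletion_score = 0


def align_ltrs(
    ltr5_seq: str, ltr3_seq: str, fragment: int = FRAGMENT_DEFAULT
) -> tuple[int, int, int]:
    """Mismatches and events between two LTR copies of one element.

    The first ``fragment`` bp of each LTR are aligned globally with free end
    gaps; ``k`` counts substitution columns, each maximal internal gap run
    counts as one event (indels are single evolutionary events), and
    ``events = k + gap runs``.  End gaps are free and not counted.

    Returns (k, events, aligned_length).
    """
    a = ltr5_seq[:fragment].upper()
    b = ltr3_seq[:fragment].upper()
    if len(a) < fragment or len(b) < fragment:
        raise ValueError(
            f"LTR shorter than fragment ({len(a)}, {len(b)} < {fragment})"
        )
    aln = _aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim free end gaps
    lead = 0
    while sa[lead] == "-" or sb[lead] == "-":
        lead += 1
    tail = len(sa)
    while sa[tail - 1] == "-" or sb[tail - 1] == "-":
        tail -= 1
    k = 0
    gap_runs = 0
    in_gap = False
    aligned = 0
    for ca, cb in zip(sa[lead:tail], sb[lead:tail]):
        if ca == "-" or cb == "-":
            if not in_gap:
                gap_runs += 1
            in_gap = True
            continue
        in_gap = False
        aligned += 1
        if ca != cb:
            k += 1
    return k, k + gap_runs, aligned


def mismatch_histogram(elements: list[LTRElement]) -> MismatchDistribution:
    if not elements:
        raise ValueError("no elements")
    counts: dict[int, int] = {}
    for el in elements:
        counts[el.k] = counts.get(el.k, 0) + 1
    return MismatchDistribution(counts=dict(sorted(counts.items())))


def fit_nbd(dist: MismatchDistribution) -> tuple[float, float]:
    """Maximum-likelihood negative binomial (r, p) for the mismatch histogram.

    Profile likelihood in r with p̂(r) = r / (r + mean), so the fitted mean
    r(1−p)/p equals the sample mean exactly.  Requires overdispersion;
    equidispersed or underdispersed data return ``(inf, p)`` as a Poisson-
    regime sentinel.
    """
    x = dist.expand().astype(float)
    m, v = x.mean(), x.var()
    if v <= m:
        # Poisson regime: r -> inf with r(1-p)/p = m
        return math.inf, 1.0

    def nll(log_r: float) -> float:
        r = math.exp(log_r)
        p = r / (r + m)
        return -float(
            np.sum(
                special.gammaln(x + r)
                - special.gammaln(r)
                - special.gammaln(x + 1)
                + r * math.log(p)
                + x * math.log1p(-p)
            )
        )

    r0 = m * m / (v - m)  # method of moments
    res = optimize.minimize_scalar(
        nll, bracket=(math.log(r0) - 2, math.log(r0), math.log(r0) + 2)
    )
    r = float(math.exp(res.x))
    p = r / (r + m)
    return r, p


def gamma_mode_age(r: float, p: float) -> tuple[float, float, float]:
    """Gamma mixing density of the NBD and its mode.

    A negative binomial is a Poisson whose rate is Gamma-distributed with
    shape = r and scale = (1−p)/p; the mode of that Gamma, (shape−1)·scale
    for shape > 1 else 0, is the modal LTR–LTR divergence.
    """
    if r <= 0 or not (0 < p < 1):
        raise ValueError("need r > 0 and p in (0, 1)")
    shape = r
    scale = (1 - p) / p
    mode = (shape - 1) * scale if shape > 1 else 0.0
    return shape, scale, mode


def fit_poisson_mixture(
    dist: MismatchDistribution,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = 0,
) -> tuple[list[float], list[float], float, list[float]]:
    """EM fit of a Poisson mixture to the mismatch histogram.

    Runs weighted EM directly on the histogram.  The log-likelihood is
    asserted non-decreasing every iteration.  Returns (lambdas, weights, r²,
    loglik trace) with components sorted by λ; r² compares observed relative
    frequencies with the fitted PMF over the observed support.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    ks = np.fromiter(dist.counts.keys(), dtype=float)
    ws = np.fromiter(dist.counts.values(), dtype=float)
    n = ws.sum()
    mean = float((ks * ws).sum() / n)

    if n_components == 1:
        lam = [mean]
        weights = [1.0]
        r2 = _mixture_r2(ks, ws, lam, weights)
        ll = float(np.sum(ws * stats.poisson.logpmf(ks, mean)))
        return lam, weights, r2, [ll]

    rng = np.random.default_rng(seed)
    # quantile-spread initialization, jittered per seed
    qs = np.quantile(dist.expand(), np.linspace(0.15, 0.85, n_components))
    lam = np.maximum(qs * rng.uniform(0.8, 1.2, n_components), 1e-3)
    pi = np.full(n_components, 1.0 / n_components)

    trace: list[float] = []
    prev = -math.inf
    for _ in range(max_iter):
        # E step: responsibilities per observed k value
        logp = stats.poisson.logpmf(ks[:, None], lam[None, :]) + np.log(pi)[None, :]
        lse = special.logsumexp(logp, axis=1)
        resp = np.exp(logp - lse[:, None])
        ll = float((ws * lse).sum())
        assert ll >= prev - 1e-9 * max(1.0, abs(prev)), "EM log-likelihood decreased"
        trace.append(ll)
        if ll - prev < tol * max(1.0, abs(ll)):
            prev = ll
            break
        prev = ll
        # M step (histogram-weighted)
        nk = (ws[:, None] * resp).sum(axis=0)
        pi = nk / n
        lam = (ws[:, None] * resp * ks[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        lam = np.maximum(lam, 1e-6)

    order = np.argsort(lam)
    lam_s = [float(v) for v in lam[order]]
    pi_s = [float(v) for v in pi[order]]
    r2 = _mixture_r2(ks, ws, lam_s, pi_s)
    return lam_s, pi_s, r2, trace


def _mixture_r2(ks, ws, lambdas, weights) -> float:
    obs = ws / ws.sum()
    fit = np.zeros_like(obs)
    for lam, w in zip(lambdas, weights):
        fit += w * stats.poisson.pmf(ks, lam)
    ss_res = float(((obs - fit) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def select_n_components(
    dist: MismatchDistribution, max_components: int = 4, seed: int | None = 0
) -> int:
    """Number of mixture components minimizing BIC over 1..max_components."""
    n = dist.n_elements
    best_c, best_bic = 1, math.inf
    for c in range(1, max_components + 1):
        try:
            _, _, _, trace = fit_poisson_mixture(dist, c, seed=seed)
        except Exception:
            continue
        n_par = 2 * c - 1
        bic = n_par * math.log(n) - 2 * trace[-1]
        if bic < best_bic - 1e-9:
            best_c, best_bic = c, bic
    return best_c


def classify_age(
    elements: list[LTRElement],
    young_threshold: int,
    mu: float = MU_DEFAULT,
    fragment: int = FRAGMENT_DEFAULT,
) -> list[LTRElement]:
    """Assign age (years, T = d/2μ with d = k/fragment) and young/old class.

    Divergence accrues on both LTR copies, hence the factor 2μ; with the
    defaults the five-mismatch threshold corresponds to ~1.28 million years.
    Elements with k <= threshold are "young".  Mutates and returns elements.
    """
    if young_threshold < 0:
        raise ValueError("threshold must be >= 0")
    for el in elements:
        el.age_years = el.k / (2.0 * mu * fragment)
        el.age_class = "young" if el.k <= young_threshold else "old"
    return elements


def threshold_from_model(model: DivergenceModel) -> int:
    """Young/old mismatch threshold: the rounded modal divergence."""
    return int(math.floor(model.gamma_mode + 0.5))


def fit_divergence_model(
    dist: MismatchDistribution,
    n_components: int | None = None,
    seed: int | None = 0,
) -> DivergenceModel:
    """Fit NBD + Gamma-mode + Poisson mixture in one step."""
    r, p = fit_nbd(dist)
    overdispersed = math.isfinite(r)
    if overdispersed:
        shape, scale, mode = gamma_mode_age(r, p)
    else:
        shape, scale, mode = math.inf, 0.0, float(dist.mean)
    if n_components is None:
        n_components = select_n_components(dist, seed=seed)
    lam, w, r2, _ = fit_poisson_mixture(dist, n_components, seed=seed)
    model = DivergenceModel(
        nbd=(r, p),
        gamma=(shape, scale),
        gamma_mode=mode,
        mixture=(lam, w, r2),
        young_threshold=0,
        overdispersed=overdispersed,
    )
    model.young_threshold = int(math.floor(model.gamma_mode + 0.5))
    return model


def enrichment_scan(
    elements: list[LTRElement], window: int = 10, step: int = 1
) -> EnrichmentScan:
    """Sliding-window hypergeometric test for young-element enrichment.

    Elements (already classified, ordered by start coordinate) form the
    population of size N with K young members; each window of ``window``
    consecutive elements is one draw of n without replacement, and
    ``p_over = P(X >= k)``, ``p_under = P(X <= k)`` are exact tails.
    Raw p-values are reported, matching single-window usage.
    """
    els = sorted(elements, key=lambda e: (e.start, e.id))
    N = len(els)
    K = sum(1 for e in els if e.age_class == "young")
    if N < window:
        return EnrichmentScan(windows=[], window_size=window, step=step,
                              n_total=N, n_young=K)
    out = []
    hg = stats.hypergeom(N, K, window)
    for i in range(0, N - window + 1, step):
        chunk = els[i : i + window]
        k = sum(1 for e in chunk if e.age_class == "young")
        out.append(
            {
                "first": i,
                "last": i + window - 1,
                "n_young": k,
                "p_over": float(hg.sf(k - 1)),
                "p_under": float(hg.cdf(k)),
                "span": (chunk[0].start, chunk[-1].end),
                "seq_id": chunk[0].seq_id,
            }
        )
    return EnrichmentScan(
        windows=out, window_size=window, step=step, n_total=N, n_young=K
    )


def read_gff3_elements(path: str) -> list[LTRElement]:
    """Read LTR elements from GFF3 with element spans plus LTR sub-features.

    Expects features of type ``LTR_retrotransposon`` (or ``repeat_region``)
    with ``long_terminal_repeat`` children linked by ``Parent=``; truth files
    may carry a ``mismatches=`` attribute, which is loaded into ``k``.
    GFF3 is 1-based closed; internal coordinates are 0-based half-open.
    """
    parents: dict[str, LTRElement] = {}
    ltrs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seq_id, _, ftype, start, end, _, _, _, attrs = f[:9]
            s, e = int(start) - 1, int(end)
            ad = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("LTR_retrotransposon", "repeat_region"):
                el = LTRElement(
                    id=ad.get("ID", f"{seq_id}:{s}-{e}"),
                    seq_id=seq_id,
                    start=s,
                    end=e,
                    ltr5=(s, s),
                    ltr3=(e, e),
                    k=int(ad.get("mismatches", 0)),
                )
                parents[el.id] = el
            elif ftype == "long_terminal_repeat":
                ltrs.setdefault(ad.get("Parent", ""), []).append((s, e))
    for pid, spans in ltrs.items():
        if pid in parents and len(spans) == 2:
            spans.sort()
            parents[pid].ltr5, parents[pid].ltr3 = spans
    return sorted(parents.values(), key=lambda e: (e.seq_id, e.start, e.id))
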