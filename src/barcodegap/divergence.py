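"""Divergence parameters, barcoding-gap histograms and Wilcoxon tests.

Six parameters characterise a region's distance structure.
Interspecific: the mean over all heterospecific sample pairs; theta prime
(per species, the mean over partner species of the species-pair mean
distance, then averaged over species — one vote per species at both
ends, removing sample-size bias); and the minimum interspecific
distance (per-species nearest heterospecific neighbour, averaged).
Intraspecific: the mean over all conspecific pairs; theta (per-species
mean conspecific distance, averaged over species with >= 2 individuals);
and the coalescent depth (per-species maximum conspecific distance,
averaged).  Singleton species contribute no intraspecific values.

The barcoding gap compares the two raw distance distributions binned at
0.01 substitutions/site.  Regions are compared pairwise by Wilcoxon
signed-rank tests over matched units (species pairs for interspecific
values, conspecific sample pairs for intraspecific ones).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .distances import DistanceMatrix


@dataclass(frozen=True)
class MeanSD:
    """A mean with its population SD and the number of contributing values."""

    mean: float
    sd: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.4f} ± {self.sd:.4f}"


def _mean_sd(values) -> MeanSD:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no contributing values")
    return MeanSD(float(arr.mean()), float(arr.std(ddof=0)), int(arr.size))


@dataclass
class DivergenceSummary:
    """The six divergence parameters for one region."""

    region: str
    avg_inter: MeanSD
    theta_prime: MeanSD
    min_inter: MeanSD
    avg_intra: MeanSD | None
    theta: MeanSD | None
    coalescent_depth: MeanSD | None
    n_species_intra: int


class InsufficientSpeciesError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


def _pair_lists(dm: DistanceMatrix):
    """Split defined pairwise distances into conspecific and heterospecific."""
    intra: dict[str, list[float]] = {}
    inter: dict[str, list[tuple[str, float]]] = {sp: [] for sp in dm.species}
    intra_pooled: list[float] = []
    inter_pooled: list[float] = []
    for a, b, d in dm.pairs():
        sa, sb = dm.species_of[a], dm.species_of[b]
        if sa == sb:
            intra.setdefault(sa, []).append(d)
            intra_pooled.append(d)
        else:
            inter[sa].append((sb, d))
            inter[sb].append((sa, d))
            inter_pooled.append(d)
    return intra, intra_pooled, inter, inter_pooled


def interspecific_params(dm: DistanceMatrix) -> tuple[MeanSD, MeanSD, MeanSD]:
    """(avg_inter, theta_prime, min_inter) for one region.

    ``theta_prime`` aggregates at species-pair granularity (the mean
    distance between species s and s' counts once however many
    individuals were sampled), so it is exactly invariant to
    duplicating a species' individuals; ``avg_inter`` pools all sample
    pairs and is not.  Raises :class:`InsufficientSpeciesError` with
    fewer than two species.
    """
    if len(dm.species) < 2:
        raise InsufficientSpeciesError("need >= 2 species for interspecific parameters")
    _, _, inter, inter_pooled = _pair_lists(dm)
    if not inter_pooled:
        raise InsufficientSpeciesError("no defined heterospecific pairs")
    pair_vals: dict[tuple[str, str], list[float]] = {}
    for sp in dm.species:
        for other, d in inter[sp]:
            pair_vals.setdefault(tuple(sorted((sp, other))), []).append(d)
    # each heterospecific pair was recorded from both ends; the mean is
    # unaffected by the double entry
    pair_mean = {k: float(np.mean(v)) for k, v in pair_vals.items()}
    per_species_tp = []
    per_species_min = []
    for sp in dm.species:
        partner_means = [m for k, m in pair_mean.items() if sp in k]
        ds = [d for _, d in inter[sp]]
        if ds:
            per_species_tp.append(float(np.mean(partner_means)))
            per_species_min.append(float(np.min(ds)))
    return (
        _mean_sd(inter_pooled),
        _mean_sd(per_species_tp),
        _mean_sd(per_species_min),
    )


def intraspecific_params(dm: DistanceMatrix) -> tuple[MeanSD, MeanSD, MeanSD]:
    """(avg_intra, theta, coalescent_depth); singleton species excluded.

    Raises :class:`InsufficientDataError` if no species has >= 2 individuals.
    """
    intra, intra_pooled, _, _ = _pair_lists(dm)
    if not intra_pooled:
        raise InsufficientDataError("no species with >= 2 individuals")
    per_species_mean = [float(np.mean(v)) for v in intra.values()]
    per_species_max = [float(np.max(v)) for v in intra.values()]
    return (
        _mean_sd(intra_pooled),
        _mean_sd(per_species_mean),
        _mean_sd(per_species_max),
    )


def n_species_with_replicates(dm: DistanceMatrix) -> int:
    return sum(1 for sp in dm.species if len(dm.samples_of(sp)) >= 2)


def divergence_summary(dm: DistanceMatrix, region: str | None = None) -> DivergenceSummary:
    """All six parameters; intraspecific ones are None when undefined."""
    avg_inter, theta_prime, min_inter = interspecific_params(dm)
    try:
        avg_intra, theta, depth = intraspecific_params(dm)
    except InsufficientDataError:
        avg_intra = theta = depth = None
    return DivergenceSummary(
        region=region or "",
        avg_inter=avg_inter,
        theta_prime=theta_prime,
        min_inter=min_inter,
        avg_intra=avg_intra,
        theta=theta,
        coalescent_depth=depth,
        n_species_intra=n_species_with_replicates(dm),
    )


@dataclass
class GapHistogram:
    """Intra- vs interspecific distance distributions at fixed bin width."""

    bin_width: float
    intra_values: list[float]
    inter_values: list[float]
    intra_counts: list[int] = field(default_factory=list)
    inter_counts: list[int] = field(default_factory=list)
    overlap: bool = False
    overlap_fraction: float = 0.0

    @property
    def n_bins(self) -> int:
        return len(self.intra_counts)


def barcoding_gap(dm: DistanceMatrix, bin_width: float = 0.01) -> GapHistogram:
    """Histogram the conspecific and heterospecific distances.

    Bins are half-open [k*w, (k+1)*w) starting at 0.  ``overlap`` is true
    iff max(intra) >= min(inter); ``overlap_fraction`` is the proportion
    of intraspecific values >= min(inter).
    """
    _, intra, _, inter = _pair_lists(dm)
    if not intra or not inter:
        raise InsufficientDataError("need >= 1 intra and >= 1 inter pair")
    top = max(max(intra), max(inter))
    n_bins = int(math.floor(top / bin_width)) + 1
    edges = [k * bin_width for k in range(n_bins + 1)]

    def counts(vals):
        c = [0] * n_bins
        for v in vals:
            c[min(int(v // bin_width), n_bins - 1)] += 1
        return c

    lo_inter = min(inter)
    overlap = max(intra) >= lo_inter
    frac = sum(1 for v in intra if v >= lo_inter) / len(intra)
    hist = GapHistogram(
        bin_width=bin_width,
        intra_values=sorted(intra),
        inter_values=sorted(inter),
        intra_counts=counts(intra),
        inter_counts=counts(inter),
        overlap=overlap,
        overlap_fraction=frac,
    )
    hist.edges = edges
    return hist


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test outcome: rank sums, n, two-sided p and a verdict."""

    w_plus: float
    w_minus: float
    n: int
    p_value: float
    p_exact: float | None
    p_normal: float
    verdict: str
    alpha: float = 0.05


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided sign-flip p by full enumeration on the observed midranks.

    P(|W - mu| >= |w_plus - mu|) with mu = n(n+1)/4, over all 2^n sign
    assignments.  Exact even under ties, because enumeration uses the
    observed (mid)ranks.
    """
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    dev = abs(w_plus - mu) - 1e-12
    hits = 0
    for mask in itertools.product((0, 1), repeat=n):
        w = float(np.dot(mask, ranks))
        if abs(w - mu) >= dev:
            hits += 1
    return hits / 2**n


def _midranks(absdiff: np.ndarray) -> np.ndarray:
    order = np.argsort(absdiff, kind="stable")
    ranks = np.empty(len(absdiff))
    sorted_vals = absdiff[order]
    i = 0
    while i < len(absdiff):
        j = i
        while j + 1 < len(absdiff) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_signed_rank(
    paired_a, paired_b, alpha: float = 0.05, exact_max_n: int = 12
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of paired values A vs B.

    Differences are A - B; zero differences are dropped; |differences|
    are ranked with midranks for ties.  The p-value is by exact sign-flip
    enumeration for n <= ``exact_max_n`` and by the normal approximation
    with tie and continuity corrections otherwise (both are reported).
    The verdict is ``A=B`` when p >= alpha, else ``A>>B`` or ``A<<B`` by
    the larger rank sum.
    """
    a = np.asarray(list(paired_a), dtype=float)
    b = np.asarray(list(paired_b), dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired vectors must be equal-length and non-empty")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 0, 1.0, 1.0, 1.0, "A=B", alpha)
    ranks = _midranks(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    w_minus = float(ranks[diff < 0].sum())

    # normal approximation with tie correction and continuity correction
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(diff), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts).sum()) / 48.0
    )
    if var <= 0:
        p_normal = 1.0
    else:
        z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
        p_normal = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))

    p_exact = _exact_two_sided_p(ranks, w_plus) if n <= exact_max_n else None
    p = p_exact if p_exact is not None else p_normal

    if p >= alpha:
        verdict = "A=B"
    else:
        verdict = "A>>B" if w_plus > w_minus else "A<<B"
    return WilcoxonResult(w_plus, w_minus, n, p, p_exact, p_normal, verdict, alpha)


def pair_regions(
    dm_a: DistanceMatrix, dm_b: DistanceMatrix, level: str = "species-pair"
) -> tuple[list[float], list[float], list[tuple[str, str]]]:
    """Matched distance vectors for two regions.

    ``species-pair`` (interspecific): for each unordered species pair
    present in both regions, the mean heterospecific distance per region.
    ``sample-pair`` (intraspecific): each conspecific sample pair
    sequenced in both regions.  Units are ordered lexicographically; the
    roster of units is returned for audit.
    """
    if level not in ("species-pair", "sample-pair"):
        raise ValueError(f"unknown pairing level {level!r}")
    va: list[float] = []
    vb: list[float] = []
    roster: list[tuple[str, str]] = []
    if level == "species-pair":
        def by_species_pair(dm):
            acc: dict[tuple[str, str], list[float]] = {}
            for x, y, d in dm.pairs():
                sx, sy = dm.species_of[x], dm.species_of[y]
                if sx != sy:
                    acc.setdefault(tuple(sorted((sx, sy))), []).append(d)
            return {k: float(np.mean(v)) for k, v in acc.items()}

        ma, mb = by_species_pair(dm_a), by_species_pair(dm_b)
        shared = sorted(set(ma) & set(mb))
        for key in shared:
            va.append(ma[key])
            vb.append(mb[key])
            roster.append(key)
    else:
        def conspecific_pairs(dm):
            out = {}
            for x, y, d in dm.pairs():
                if dm.species_of[x] == dm.species_of[y]:
                    out[tuple(sorted((x, y)))] = d
            return out

        pa, pb = conspecific_pairs(dm_a), conspecific_pairs(dm_b)
        shared = sorted(set(pa) & set(pb))
        for key in shared:
            va.append(pa[key])
            vb.append(pb[key])
            roster.append(key)
    if not roster:
        raise ValueError("regions share no units at the requested level")
    return va, vb, roster
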