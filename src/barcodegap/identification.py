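"""Species identification: best-match classification and NJ monophyly.

Two assessments of a barcode region's discriminatory power:

* **best-match** — every sequence is used in turn as a query against all
  remaining sequences (leave-one-out); the hit set is the reference
  sample(s) at minimum K2P distance.  A query is *correct* when the hit
  set is exactly its own species, *ambiguous* when the hit set spans
  several species including its own, and *incorrect* otherwise.
* **tree-based** — a neighbor-joining tree is built from the K2P matrix
  (with bootstrap supports from column resampling); a species counts as
  identified when all of its individuals form a monophyletic group.

The NJ implementation follows Saitou & Nei's rate-corrected criterion
with a deterministic tie rule (lowest lexicographic label pair), so that
equidistant inputs always produce the same topology and additive inputs
are recovered exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix, distance_matrix, SaturationError, NoOverlapError
from .records import RegionAlignment


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The tree is represented as a :class:`skbio.TreeNode` with a
    trifurcating root.  Branch lengths keep their raw (possibly
    negative) NJ estimates so that path lengths on additive inputs
    reproduce the input matrix exactly; clamping happens only at export
    (:func:`write_newick`).  Ties in the join criterion are broken by
    the lexicographically lowest pair of cluster representative labels
    (a cluster is represented by its smallest leaf label).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains undefined entries")

    D = dm.values.astype(float).copy()
    nodes = [TreeNode(name=s) for s in dm.sample_ids]
    reps = list(dm.sample_ids)  # representative (min leaf) label per cluster
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        best = None
        for ai, aj in ties:
            if ai >= aj:
                continue
            i, j = active[ai], active[aj]
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]

        dij = D[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active cluster
        new_row = np.zeros(D.shape[0])
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = (D[i, ak] + D[j, ak] - dij) / 2.0
        D = np.vstack([D, new_row[None, :]])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # terminal three-cluster star: solve the three pairwise equations
    a, b, c = active
    nodes[a].length = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    nodes[b].length = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    nodes[c].length = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def tree_path_matrix(tree: TreeNode, labels) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``labels``."""
    skdm = tree.tip_tip_distances()
    idx = [skdm.ids.index(lab) for lab in labels]
    return np.asarray(skdm.data)[np.ix_(idx, idx)]


def write_newick(tree: TreeNode, path=None, clamp_negative: bool = True) -> str:
    """Newick string (written to ``path`` if given).

    Negative NJ branch-length estimates are clamped to zero with a
    warning; bootstrap supports (``node.support``) become internal node
    labels.
    """
    out = tree.copy()
    clamped = 0
    for node in out.traverse():
        if node.length is not None and node.length < 0 and clamp_negative:
            node.length = 0.0
            clamped += 1
        sup = getattr(node, "support", None)
        if sup is not None and not node.is_tip():
            node.name = f"{sup:.0f}"
    if clamped:
        warnings.warn(f"clamped {clamped} negative branch length(s) to 0 for export")
    nwk = str(out).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(nwk + "\n")
    return nwk


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, monophyly
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of tip names.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest tip is the canonical representation,
    so the set is invariant to rerooting and leaf order.
    """
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        if ref in side:
            side = tips - side
        splits.add(side)
    return splits


def bootstrap_supports(
    aln: RegionAlignment,
    replicates: int = 1000,
    seed: int = 0,
    on_undefined: str = "drop-pair",
) -> TreeNode:
    """NJ tree with bootstrap supports mapped onto its internal edges.

    Alignment columns are resampled with replacement ``replicates``
    times; each replicate's K2P matrix is rebuilt and NJ re-run, and the
    support of every internal edge of the original tree is the
    percentage of successful replicates whose tree contains the same
    bipartition.  Replicates yielding an undefined distance matrix are
    dropped with a warning.  Deterministic for a given seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    dm = distance_matrix(aln, on_undefined="error")
    tree = nj_tree(dm)
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(tree)}

    rng = np.random.default_rng(seed)
    cols = np.array([[ord(c) for c in r.sequence] for r in aln.records], dtype=np.uint8)
    ncols = cols.shape[1]
    used = 0
    dropped = 0
    for _ in range(replicates):
        pick = rng.integers(0, ncols, size=ncols)
        res = cols[:, pick]
        rec_seqs = ["".join(map(chr, row)) for row in res]
        try:
            rep_aln = RegionAlignment(
                region=aln.region,
                records=[
                    type(r)(r.sample_id, r.species, r.region, s)
                    for r, s in zip(aln.records, rec_seqs)
                ],
            )
            rep_dm = distance_matrix(rep_aln, on_undefined="error")
            rep_tree = nj_tree(rep_dm)
        except (SaturationError, NoOverlapError):
            dropped += 1
            continue
        used += 1
        rep_bps = _bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if dropped:
        warnings.warn(f"dropped {dropped} bootstrap replicate(s) with undefined distances")
    if used == 0:
        raise ValueError("every bootstrap replicate failed")

    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        canon = tips - side if ref in side else side
        node.support = 100.0 * counts[canon] / used
    return tree


def is_monophyletic(
    tree: TreeNode, species: str, species_of: dict[str, str], outgroup=()
) -> bool:
    """True iff all individuals of ``species`` form an exclusive group.

    On the unrooted tree this holds iff some edge bipartition isolates
    exactly that species' leaves.  When an outgroup is supplied the test
    is the rooted one (root on the outgroup edge); because the outgroup
    is disjoint from the species the two tests coincide, and the
    outgroup leaves are only checked for presence.  Singleton species
    are monophyletic by definition.
    """
    tips = frozenset(t.name for t in tree.tips())
    target = frozenset(s for s, sp in species_of.items() if sp == species) & tips
    if not target:
        raise ValueError(f"species {species!r} has no leaves in the tree")
    missing = set(outgroup) - tips
    if missing:
        raise ValueError(f"outgroup leaves absent from tree: {sorted(missing)}")
    if len(target) == 1:
        return True
    if len(target) == len(tips):
        return True
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset([node.name])
        if side == target or tips - side == target:
            return True
    return False


# ---------------------------------------------------------------------------
# best-match classification and identification rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QueryVerdict:
    """Outcome of one leave-one-out query."""

    sample_id: str
    true_species: str
    best_hit_species: frozenset
    best_distance: float
    classification: str  # correct | ambiguous | incorrect


def best_match_identify(
    dm: DistanceMatrix, tie_tolerance: float = 1e-9, exclude=()
) -> list[QueryVerdict]:
    """Leave-one-out best-match classification of every evaluable query.

    Each sample is queried against all remaining samples (self excluded;
    ``exclude`` lists reference-only labels such as outgroups, removed
    from both query and reference sets).  Queries whose species has no
    other sample are skipped.  The best-hit set is all references within
    ``tie_tolerance`` of the minimum distance.
    """
    work = dm.drop(exclude) if exclude else dm
    counts: dict[str, int] = {}
    for s in work.sample_ids:
        counts[work.species_of[s]] = counts.get(work.species_of[s], 0) + 1
    verdicts: list[QueryVerdict] = []
    ids = work.sample_ids
    for qi, query in enumerate(ids):
        sp = work.species_of[query]
        if counts[sp] < 2:
            continue
        row = work.values[qi].copy()
        row[qi] = np.nan
        if np.isnan(row).all():
            raise ValueError(f"query {query!r}: empty reference after exclusions")
        dmin = np.nanmin(row)
        hits = [ids[k] for k in range(len(ids)) if not np.isnan(row[k]) and row[k] <= dmin + tie_tolerance]
        hit_species = frozenset(work.species_of[h] for h in hits)
        if hit_species == {sp}:
            cls = "correct"
        elif sp in hit_species:
            cls = "ambiguous"
        else:
            cls = "incorrect"
        verdicts.append(QueryVerdict(query, sp, hit_species, float(dmin), cls))
    return verdicts


@dataclass
class IdentificationReport:
    """Per-region identification outcome for one method."""

    region: str
    method: str  # best-match | tree
    per_species: dict[str, bool] = field(default_factory=dict)
    n_species: int = 0
    n_identified: int = 0
    species_rate: float = 0.0
    n_samples: int = 0
    n_samples_correct: int = 0
    sample_rate: float = 0.0


def identification_rates(
    region: str = "",
    verdicts: list[QueryVerdict] | None = None,
    tree: TreeNode | None = None,
    species_of: dict[str, str] | None = None,
    outgroup=(),
) -> IdentificationReport:
    """Per-species and per-sample identification rates (percent).

    Best-match (pass ``verdicts``): a species is identified iff every
    one of its queries is classified correct; evaluable species are
    those with at least one query.  Tree method (pass ``tree`` and
    ``species_of``): a species is identified iff it is monophyletic;
    evaluable species are all non-outgroup species on the tree.  The
    denominator is always reported alongside the rate.
    """
    if (verdicts is None) == (tree is None):
        raise ValueError("pass exactly one of verdicts= or tree=")
    if verdicts is not None:
        per: dict[str, bool] = {}
        for v in verdicts:
            per[v.true_species] = per.get(v.true_species, True) and (
                v.classification == "correct"
            )
        n_corr = sum(1 for v in verdicts if v.classification == "correct")
        rep = IdentificationReport(region=region, method="best-match", per_species=per)
        rep.n_samples = len(verdicts)
        rep.n_samples_correct = n_corr
        rep.sample_rate = 100.0 * n_corr / len(verdicts) if verdicts else 0.0
    else:
        if species_of is None:
            raise ValueError("tree method needs species_of")
        out_sp = {species_of[o] for o in outgroup if o in species_of}
        tips = {t.name for t in tree.tips()}
        eval_species = sorted(
            {sp for s, sp in species_of.items() if s in tips and sp not in out_sp}
        )
        # the test runs on the full tree: with the outgroup present, an
        # edge isolating exactly the species' leaves is rooted monophyly
        per = {
            sp: is_monophyletic(tree, sp, species_of, outgroup=outgroup)
            for sp in eval_species
        }
        rep = IdentificationReport(region=region, method="tree", per_species=per)
        members = {sp: [s for s in tips if species_of.get(s) == sp] for sp in eval_species}
        rep.n_samples = sum(len(m) for m in members.values())
        rep.n_samples_correct = sum(len(members[sp]) for sp, ok in per.items() if ok)
        rep.sample_rate = (
            100.0 * rep.n_samples_correct / rep.n_samples if rep.n_samples else 0.0
        )
    rep.n_species = len(rep.per_species)
    rep.n_identified = sum(rep.per_species.values())
    rep.species_rate = (
        100.0 * rep.n_identified / rep.n_species if rep.n_species else 0.0
    )
    return rep
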