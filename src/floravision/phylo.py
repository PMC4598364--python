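"""Phylogenetic analyses: parsimony ancestral states and Mantel signal tests.

Trees are `dendropy` objects read from Newick (a consensus tree plus,
optionally, a sample of posterior trees, one per line). Ancestral states of
categorical colour characters are reconstructed by unordered (Fitch-type)
parsimony; the implementation is unit-cost Sankoff dynamic programming, which
yields the exact most-parsimonious-reconstruction (MPR) state set at every
node, works on multifurcating trees, and treats missing tips as the full
alphabet. Reconstructions can be traced over a whole tree sample and
summarised as per-node state frequencies on a majority-rule consensus tree.

Phylogenetic signal in multidimensional colour traits is tested by Mantel
permutation tests between a trait distance matrix and patristic (or genetic)
distance matrices; taxa with several entries in the trait data (colour
polymorphism, multiple accessions) are accommodated by grafting extra tips
with zero branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .categories import DistanceMatrix

__all__ = [
    "read_newick",
    "read_tree_sample",
    "write_newick",
    "add_zero_length_tips",
    "patristic_distances",
    "MantelResult",
    "MantelSummary",
    "mantel_test",
    "mantel_over_trees",
    "ASRResult",
    "ASROverTrees",
    "fitch_parsimony_asr",
    "asr_over_trees",
    "majority_consensus",
    "p_distance_matrix",
]

_INF = float("inf")


# ---------------------------------------------------------------------------
# Tree I/O and editing


def read_newick(path: str | Path, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Read a single rooted Newick tree."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )
    return tree


def read_tree_sample(path: str | Path) -> dendropy.TreeList:
    """Read a Newick tree sample (one tree per line) on a shared taxon namespace."""
    return dendropy.TreeList.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to Newick; write to ``path`` when given."""
    text = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def add_zero_length_tips(tree: dendropy.Tree, duplicates: Mapping[str, int]) -> dendropy.Tree:
    """Graft zero-length duplicate tips for taxa with multiple trait entries.

    Each duplicate is attached as sister to the original tip through
    zero-length branches, so duplicates are at patristic distance 0 from the
    original and all pre-existing tip-to-tip distances are unchanged.
    Duplicate tips are labelled ``<taxon>#2``, ``<taxon>#3``, ...
    """
    out = tree.clone(depth=1)
    ns = out.taxon_namespace
    by_label = {leaf.taxon.label: leaf for leaf in out.leaf_node_iter()}
    for taxon, count in duplicates.items():
        if count <= 0:
            continue
        leaf = by_label.get(taxon)
        if leaf is None:
            raise ValueError(f"taxon {taxon!r} not in tree")
        original_taxon = leaf.taxon
        # the old leaf becomes an internal node carrying the original edge
        leaf.taxon = None
        child = leaf.new_child(edge_length=0.0)
        child.taxon = original_taxon
        for i in range(count):
            dup = leaf.new_child(edge_length=0.0)
            dup.taxon = ns.new_taxon(f"{taxon}#{i + 2}")
    out.update_taxon_namespace()
    return out


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip distances: sum of branch lengths along the connecting path."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = tuple(l.taxon.label for l in leaves)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def majority_consensus(trees: Sequence[dendropy.Tree], threshold: float = 0.95) -> dendropy.Tree:
    """Majority-rule consensus: clades with frequency >= threshold, supports annotated."""
    if isinstance(trees, dendropy.TreeList):
        treelist = trees
    else:
        treelist = dendropy.TreeList(taxon_namespace=trees[0].taxon_namespace)
        treelist.extend(trees)
    tip_sets = {frozenset(tip_labels(t)) for t in treelist}
    if len(tip_sets) != 1:
        raise ValueError("trees have inconsistent tip sets")
    # dendropy retains splits with frequency strictly above min_freq in some
    # versions; pull back by a hair so 'frequency >= threshold' is honoured.
    return treelist.consensus(min_freq=threshold - 1e-9, support_as_labels=False)


# ---------------------------------------------------------------------------
# Mantel tests


@dataclass(frozen=True)
class MantelResult:
    """Pearson correlation of off-diagonal distances and its permutation p-value."""

    r: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class MantelSummary:
    """Mantel results aggregated over a tree sample."""

    mean_p: float
    sd_p: float
    pct_significant: float
    n_trees: int
    n_skipped: int = 0
    results: tuple[MantelResult, ...] = ()


def _aligned_square(d: DistanceMatrix, order: Sequence[str]) -> np.ndarray:
    idx = [d.labels.index(l) for l in order]
    return d.values[np.ix_(idx, idx)]


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two labelled distance matrices.

    r is the Pearson correlation of the vectorised upper triangles; the
    p-value is (1 + #{r_perm >= r_obs}) / (n_perm + 1), one-tailed for a
    positive association by default (phylogenetic signal is directional);
    ``alternative='two-sided'`` compares absolute values. Rows/columns of
    ``d2`` are permuted jointly.
    """
    if set(d1.labels) != set(d2.labels):
        raise ValueError("distance matrices must share the same labels")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("need at least 4 observations for a Mantel test")
    a = d1.values
    b = _aligned_square(d2, d1.labels)
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    x = (x - x.mean()) / x.std()
    m = x.size

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        sd = y.std()
        if sd == 0:
            return 0.0
        return float(x @ ((y - y.mean()) / sd)) / m

    r_obs = corr(b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stat = abs if alternative == "two-sided" else (lambda v: v)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if stat(corr(b[np.ix_(p, p)])) >= stat(r_obs) - 1e-12:
            exceed += 1
    return MantelResult(r=r_obs, p=(1 + exceed) / (n_perm + 1), n_perm=n_perm)


def mantel_over_trees(
    trees: Sequence[dendropy.Tree],
    trait_d: DistanceMatrix,
    duplicates: Mapping[str, int] | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    alternative: str = "greater",
    share_permutations: bool = False,
    keep_results: bool = False,
) -> MantelSummary:
    """Run a Mantel test against every tree in a sample and summarise.

    For each tree: graft zero-length duplicate tips if requested, compute
    patristic distances, and test against the trait distances. Reported are
    the mean and standard deviation of the per-tree p-values and the
    percentage of trees significant at ``alpha``. Trees missing a trait taxon
    are skipped and counted. A master ``seed`` fans out one child seed per
    tree (``share_permutations=True`` reuses the same permutation stream for
    every tree instead — with identical trees the p-values are then
    identical).
    """
    duplicates = duplicates or {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(trees))
    wanted = set(trait_d.labels)
    results: list[MantelResult] = []
    skipped = 0
    for tree, child in zip(trees, child_seeds):
        work = add_zero_length_tips(tree, duplicates) if duplicates else tree
        have = set(tip_labels(work))
        if not wanted <= have:
            skipped += 1
            continue
        pat = patristic_distances(work)
        if have != wanted:
            pat = pat.submatrix(sorted(wanted))
        rng = np.random.default_rng(np.random.SeedSequence(seed) if share_permutations else child)
        results.append(mantel_test(trait_d, pat, n_perm=n_perm, seed=rng, alternative=alternative))
    if not results:
        raise ValueError("no usable trees in the sample")
    ps = np.array([r.p for r in results])
    return MantelSummary(
        mean_p=float(ps.mean()),
        sd_p=float(ps.std(ddof=1)) if ps.size > 1 else 0.0,
        pct_significant=float(100.0 * np.mean(ps < alpha)),
        n_trees=len(results),
        n_skipped=skipped,
        results=tuple(results) if keep_results else (),
    )


def p_distance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Uncorrected p-distances from an alignment, with pairwise deletion.

    Sites where either sequence has a gap or ambiguity ('-', '?', 'N') are
    excluded per pair. Intended for plastid-alignment genetic distances as an
    alternative to tree-based patristic distances.
    """
    labels = tuple(sorted(sequences))
    seqs = {k: sequences[k].upper() for k in labels}
    length = {len(s) for s in seqs.values()}
    if len(length) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    n = len(labels)
    values = np.zeros((n, n))
    skip = set("-?N")
    for i in range(n):
        si = seqs[labels[i]]
        for j in range(i + 1, n):
            sj = seqs[labels[j]]
            pairs = [(a, b) for a, b in zip(si, sj) if a not in skip and b not in skip]
            if not pairs:
                raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
            diff = sum(a != b for a, b in pairs)
            values[i, j] = values[j, i] = diff / len(pairs)
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Parsimony ancestral-state reconstruction


@dataclass(frozen=True)
class ASRResult:
    """Single-tree parsimony reconstruction.

    ``node_sets`` maps each node (keyed by the frozenset of tip labels below
    it) to its MPR state set — the states occurring at the node in at least
    one most-parsimonious reconstruction. ``parsimony_length`` is the minimum
    number of state changes on the tree.
    """

    parsimony_length: int
    alphabet: tuple[str, ...]
    node_sets: dict[frozenset, frozenset]
    root_set: frozenset

    def states_at(self, clade: Iterable[str]) -> frozenset:
        return self.node_sets[frozenset(clade)]


@dataclass(frozen=True)
class ASROverTrees:
    """Parsimony reconstruction traced over a tree sample.

    ``frequencies`` maps each consensus node (keyed by its unrooted
    bipartition of the common taxon set) to per-state frequencies, averaged
    over the trees that contain that bipartition; ``coverage`` is the
    fraction of trees containing it.
    """

    alphabet: tuple[str, ...]
    frequencies: dict[frozenset, dict[str, float]]
    coverage: dict[frozenset, float]
    root_frequencies: dict[str, float]
    parsimony_lengths: tuple[int, ...]


def _tip_state_sets(
    tree: dendropy.Tree, traits: Mapping[str, str | set[str] | None], alphabet: tuple[str, ...]
) -> dict:
    full = frozenset(alphabet)
    out = {}
    for leaf in tree.leaf_node_iter():
        raw = traits.get(leaf.taxon.label)
        if raw is None or raw == "" or raw == "?":
            out[leaf] = full
        else:
            states = {raw} if isinstance(raw, str) else set(raw)
            bad = states - full
            if bad:
                raise ValueError(f"state(s) {sorted(bad)} for {leaf.taxon.label!r} outside alphabet")
            out[leaf] = frozenset(states)
    return out


def fitch_parsimony_asr(
    tree: dendropy.Tree,
    traits: Mapping[str, str | set[str] | None],
    alphabet: Sequence[str] | None = None,
) -> ASRResult:
    """Unordered-states (Fitch) parsimony ancestral-state reconstruction.

    Implemented as unit-cost Sankoff dynamic programming: a post-order pass
    computes, per node and state, the minimum number of changes in the
    subtree; a pre-order pass adds the cost of the rest of the tree; a
    node's MPR set is the states achieving the global minimum. Handles
    polytomies and missing tips (scored as the full alphabet).
    """
    if alphabet is None:
        observed: set[str] = set()
        for v in traits.values():
            if v is None or v == "" or v == "?":
                continue
            observed |= {v} if isinstance(v, str) else set(v)
        alphabet = tuple(sorted(observed))
    else:
        alphabet = tuple(alphabet)
    if not alphabet:
        raise ValueError("empty state alphabet")
    k = len(alphabet)
    state_index = {s: i for i, s in enumerate(alphabet)}
    tips = _tip_state_sets(tree, traits, alphabet)

    down: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cost = np.full(k, _INF)
            for s in tips[node]:
                cost[state_index[s]] = 0.0
            down[node] = cost
        else:
            cost = np.zeros(k)
            for child in node.child_nodes():
                c = down[child]
                # min over child states of (substitution cost + child subtree cost)
                cost += np.minimum(c, c.min() + 1.0)
            down[node] = cost

    root = tree.seed_node
    length = int(down[root].min())

    outside: dict = {root: np.zeros(k)}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        mins = [np.minimum(down[c], down[c].min() + 1.0) for c in children]
        total = np.sum(mins, axis=0)
        for child, m in zip(children, mins):
            # cost of everything outside `child`, per state of node
            rest = outside[node] + total - m
            outside[child] = np.minimum(rest, rest.min() + 1.0)

    node_sets: dict[frozenset, frozenset] = {}
    for node in tree.postorder_node_iter():
        total = down[node] + outside[node]
        best = total.min()
        mpr = frozenset(alphabet[i] for i in range(k) if total[i] <= best + 1e-9)
        if not mpr:
            raise RuntimeError("empty MPR set (internal error)")
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        node_sets[clade] = mpr
    root_clade = frozenset(l.taxon.label for l in root.leaf_iter())
    return ASRResult(length, alphabet, node_sets, node_sets[root_clade])


def asr_over_trees(
    trees: Sequence[dendropy.Tree],
    traits: Mapping[str, str | set[str] | None],
    consensus: dendropy.Tree,
    alphabet: Sequence[str] | None = None,
    fractional: bool = True,
) -> ASROverTrees:
    """Trace a character's parsimony reconstruction over a tree sample.

    For every internal node of ``consensus``, the reconstructed-state
    frequency is accumulated over the sample trees containing the same
    tip-set clade (trees are rooted consistently, so clade identity is
    well defined; unrooted matching would conflate the two children of the
    root). When a tree's MPR set at a node holds several equally
    parsimonious states, each receives weight 1/|set| (``fractional=True``,
    the default) or full weight 1 (``fractional=False``). Frequencies are
    normalised over the trees containing the node; the fraction containing
    it is reported as coverage.
    """
    all_taxa = frozenset(l.taxon.label for l in consensus.leaf_node_iter())
    cons_keys = []
    for node in consensus.preorder_internal_node_iter():
        cons_keys.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    root_key = all_taxa

    acc: dict[frozenset, dict[str, float]] = {key: {} for key in cons_keys}
    seen: dict[frozenset, int] = {key: 0 for key in cons_keys}
    lengths = []
    alpha_out: tuple[str, ...] | None = tuple(alphabet) if alphabet else None
    for tree in trees:
        res = fitch_parsimony_asr(tree, traits, alphabet)
        alpha_out = res.alphabet
        lengths.append(res.parsimony_length)
        by_key = {clade: mpr for clade, mpr in res.node_sets.items() if len(clade) > 1}
        # a tree's root always corresponds to the consensus root
        by_key[root_key] = res.root_set
        for key in cons_keys:
            mpr = by_key.get(key)
            if mpr is None:
                continue
            seen[key] += 1
            w = 1.0 / len(mpr) if fractional else 1.0
            bucket = acc[key]
            for s in mpr:
                bucket[s] = bucket.get(s, 0.0) + w

    n_trees = len(lengths)
    frequencies = {}
    coverage = {}
    for key in cons_keys:
        count = seen[key]
        coverage[key] = count / n_trees if n_trees else 0.0
        if count:
            frequencies[key] = {s: v / count for s, v in sorted(acc[key].items())}
        else:
            frequencies[key] = {}
    return ASROverTrees(
        alphabet=alpha_out or (),
        frequencies=frequencies,
        coverage=coverage,
        root_frequencies=frequencies.get(root_key, {}),
        parsimony_lengths=tuple(lengths),
    )
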