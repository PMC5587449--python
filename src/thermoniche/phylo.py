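"""Phylogenetic comparative analyses of niche limits.

Two questions about a continuous trait (here: one of the four thermal-niche
limits) measured at the tips of a rooted tree:

* What were the ancestral values?  Answered by *squared-change parsimony*:
  internal states minimise the sum over branches of (change)^2 / w, with
  w = branch length in the weighted variant (w = 1 unweighted).  The
  weighted optimum at the root coincides with the generalised-least-squares
  (Brownian) estimate of the phylogenetic mean, which provides an exact
  closed-form cross-check.

* Is there phylogenetic signal?  Blomberg's K compares the observed ratio
  of tip variance around the phylogenetic mean to the Brownian-expected
  ratio; K = 1 is the Brownian expectation, K < 1 weaker signal, K > 1
  stronger.  Significance comes from a permutation test on the variance of
  phylogenetically independent contrasts: shuffling tip values destroys any
  signal, and low observed contrast variance relative to the shuffles
  indicates that close relatives resemble each other.

Trees are handled as :class:`dendropy.Tree` objects throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .errors import (
    DegenerateDistributionError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

Phylogeny = dendropy.Tree  # the package's tree container


def read_newick(source: str | Path) -> Phylogeny:
    """Read a rooted tree from a Newick file path or literal string.

    Polytomies are allowed; duplicate tip labels are rejected.
    """
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")
    except Exception as exc:
        raise FormatError(f"could not parse Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate tip labels: {dupes}")
    if any(lf.taxon is None for lf in tree.leaf_node_iter()):
        raise FormatError("every tip must be labelled")
    return tree


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def label_internal_nodes(tree: Phylogeny, prefix: str = "N") -> None:
    """Assign deterministic labels (preorder N1, N2, ...) to unlabelled
    internal nodes, in place. Existing labels are kept."""
    used = {nd.label for nd in tree.preorder_node_iter() if nd.label}
    i = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.label:
            continue
        i += 1
        while f"{prefix}{i}" in used:
            i += 1
        nd.label = f"{prefix}{i}"


def _tip_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


@dataclass
class AncestralStates:
    """Reconstructed values at every internal node (labels are tree labels)."""

    states: dict[str, float]
    root: str

    @property
    def root_value(self) -> float:
        return self.states[self.root]


def _prepare_tree(
    tree: Phylogeny, traits: Mapping[str, float], weighted: bool, zero_length: str
) -> Phylogeny:
    """Clone, prune trait-less tips, and resolve zero-length branches."""
    work = tree.clone(depth=1)
    tip_labels = {_tip_label(lf) for lf in work.leaf_node_iter()}
    missing = tip_labels - set(traits)
    if missing:
        warnings.warn(
            f"pruning {len(missing)} tip(s) without trait values: {sorted(missing)}",
            stacklevel=3,
        )
        keep = [t for t in work.taxon_namespace if t.label in traits]
        work.retain_taxa(keep)
    extra = set(traits) - {_tip_label(lf) for lf in work.leaf_node_iter()}
    if extra:
        warnings.warn(f"ignoring trait values for non-tip labels: {sorted(extra)}", stacklevel=3)
    if weighted:
        zero_edges = [
            e
            for e in work.preorder_edge_iter()
            if e.head_node is not work.seed_node and not (e.length or 0) > 0
        ]
        internal_zero = [e for e in zero_edges if not e.head_node.is_leaf()]
        terminal_zero = [e for e in zero_edges if e.head_node.is_leaf()]
        if terminal_zero:
            raise ParameterError(
                "weighted reconstruction requires positive terminal branch lengths"
            )
        if internal_zero:
            if zero_length == "collapse":
                for e in internal_zero:
                    e.collapse()
            else:
                raise ParameterError("zero-length internal branch under weighted mode")
    return work


def ancestral_states(
    tree: Phylogeny,
    traits: Mapping[str, float],
    weighted: bool = True,
    zero_length: str = "collapse",
) -> AncestralStates:
    """Squared-change parsimony reconstruction of internal states.

    Minimises sum over branches of (x_child - x_parent)^2 / w with
    w = branch length (``weighted=True``) or w = 1. The minimiser solves a
    sparse linear system (the weighted graph Laplacian restricted to
    internal nodes); the solution is unique and deterministic, and every
    reconstructed value lies within [min(tips), max(tips)].

    Zero-length internal branches are collapsed into polytomies before
    weighted reconstruction (``zero_length="collapse"``) or rejected
    (``zero_length="error"``).
    """
    if zero_length not in ("collapse", "error"):
        raise ParameterError("zero_length must be 'collapse' or 'error'")
    work = _prepare_tree(tree, traits, weighted, zero_length)
    label_internal_nodes(work)
    internal = [nd for nd in work.preorder_node_iter() if not nd.is_leaf()]
    if not internal:
        raise InsufficientDataError("tree has no internal nodes")
    index = {id(nd): i for i, nd in enumerate(internal)}
    k = len(internal)
    A = np.zeros((k, k))
    b = np.zeros(k)
    for nd in internal:
        i = index[id(nd)]
        for child in nd.child_nodes():
            w = float(child.edge.length) if weighted else 1.0
            if weighted and not w > 0:
                raise ParameterError("non-positive branch length under weighted mode")
            c = 1.0 / w
            A[i, i] += c
            if child.is_leaf():
                b[i] += c * float(traits[_tip_label(child)])
            else:
                j = index[id(child)]
                A[i, j] -= c
                A[j, i] -= c
                A[j, j] += c
    x = np.linalg.solve(A, b)
    states = {internal[i].label: float(x[i]) for i in range(k)}
    return AncestralStates(states=states, root=work.seed_node.label)


def brownian_covariance(tree: Phylogeny) -> tuple[np.ndarray, list[str]]:
    """Brownian tip covariance C: C_ij = shared root-to-MRCA path length.

    Returns (C, tip_labels) with rows/columns in tip order.
    """
    tips = list(tree.leaf_node_iter())
    labels = [_tip_label(t) for t in tips]
    paths: list[list[dendropy.Node]] = []
    depth: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        d = depth.get(id(nd.parent_node), 0.0) if nd.parent_node is not None else 0.0
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise ParameterError("branch lengths required for Brownian covariance")
            d += float(nd.edge.length)
        depth[id(nd)] = d
    for t in tips:
        path = []
        nd = t
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(path[::-1])  # root -> tip
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depth[id(tips[i])]
        for j in range(i + 1, n):
            mrca_depth = 0.0
            for a, bnode in zip(paths[i], paths[j]):
                if a is not bnode:
                    break
                mrca_depth = depth[id(a)]
            C[i, j] = C[j, i] = mrca_depth
    return C, labels


def _resolve_polytomies(tree: Phylogeny) -> Phylogeny:
    """Clone and arbitrarily bifurcate polytomies with zero-length edges.

    Splitting a polytomy with zero-length internal edges leaves the Brownian
    tip covariance (hence K) unchanged while making independent contrasts
    computable; contrast denominators stay positive provided terminal
    branches are.
    """
    if all(len(nd.child_nodes()) <= 2 for nd in tree.preorder_internal_node_iter()):
        return tree
    work = tree.clone(depth=1)
    work.resolve_polytomies()
    for e in work.preorder_edge_iter():
        if e.head_node is not work.seed_node and e.length is None:
            e.length = 0.0
    return work


def _pic_contrasts(tree: Phylogeny, values: Mapping[str, float]) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts (standardised).

    Requires a strictly bifurcating tree with positive branch lengths.
    """
    x: dict[int, float] = {}
    v: dict[int, float] = {}
    contrasts: list[float] = []
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            x[id(nd)] = float(values[_tip_label(nd)])
            v[id(nd)] = float(nd.edge.length)
            continue
        children = nd.child_nodes()
        if len(children) != 2:
            raise ParameterError(
                "independent contrasts require a strictly bifurcating tree"
            )
        c1, c2 = children
        v1, v2 = v[id(c1)], v[id(c2)]
        contrasts.append((x[id(c1)] - x[id(c2)]) / np.sqrt(v1 + v2))
        x[id(nd)] = (x[id(c1)] / v1 + x[id(c2)] / v2) / (1.0 / v1 + 1.0 / v2)
        extra = v1 * v2 / (v1 + v2)
        v[id(nd)] = (float(nd.edge.length) if nd.parent_node is not None else 0.0) + extra
    return np.asarray(contrasts)


@dataclass
class SignalResult:
    """Blomberg's K with a permutation p-value."""

    K: float
    p: float
    n_perm: int
    seed: int | None
    pic_variance: float  # observed contrast variance (the test statistic)


def blomberg_k(
    tree: Phylogeny,
    traits: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K and its permutation test.

    K = (MSE0/MSE) / E[MSE0/MSE] with MSE0 the mean squared tip deviation
    from the GLS phylogenetic mean, MSE the C^-1-weighted counterpart, and
    E[MSE0/MSE] = (tr(C) - n / sum(C^-1)) / (n - 1).  The p-value counts
    tip-value permutations whose independent-contrast variance is <= the
    observed one: p = (1 + count) / (n_perm + 1), so p >= 1/(n_perm + 1).
    """
    tips = [_tip_label(lf) for lf in tree.leaf_node_iter()]
    n = len(tips)
    if n < 4:
        raise InsufficientDataError("Blomberg's K needs at least 4 tips")
    missing = set(tips) - set(traits)
    if missing:
        raise ParameterError(f"missing trait values for tips: {sorted(missing)}")
    y = np.array([float(traits[t]) for t in tips])
    if np.ptp(y) == 0:
        raise DegenerateDistributionError("trait is constant across tips")
    C, labels = brownian_covariance(tree)
    order = [labels.index(t) for t in tips]
    C = C[np.ix_(order, order)]
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a_hat = float(ones @ Cinv @ y) / float(ones @ Cinv @ ones)
    resid = y - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ Cinv @ resid) / (n - 1)
    expected = (np.trace(C) - n / float(Cinv.sum())) / (n - 1)
    K = (mse0 / mse) / expected

    pic_tree = _resolve_polytomies(tree)
    obs_contrasts = _pic_contrasts(pic_tree, dict(zip(tips, y)))
    obs_stat = float(np.var(obs_contrasts, ddof=1))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        stat = float(np.var(_pic_contrasts(pic_tree, dict(zip(tips, perm))), ddof=1))
        if stat <= obs_stat:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return SignalResult(K=float(K), p=p, n_perm=n_perm, seed=seed, pic_variance=obs_stat)


def delta_vs_ancestor(
    states: AncestralStates, traits: Mapping[str, float], tol: float = 0.05
) -> dict[str, str]:
    """Sign of each tip's deviation from the root ancestral state.

    '+' when tip - root > tol, '-' when < -tol, else '0'. The default
    tolerance 0.05 °C matches one-decimal reporting of temperatures.
    """
    root = states.root_value
    signs: dict[str, str] = {}
    for tip, value in traits.items():
        diff = float(value) - root
        signs[tip] = "+" if diff > tol else ("-" if diff < -tol else "0")
    return signs


def ancestral_states_to_frame(states: AncestralStates):
    """Ancestral states as a two-column DataFrame (node, value)."""
    import pandas as pd

    return pd.DataFrame(
        {"node": list(states.states), "value": list(states.states.values())}
    )
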