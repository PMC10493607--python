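"""Newick tree handling and maximum-likelihood ancestral state
reconstruction of continuous characters under Brownian motion.

Under Brownian motion with rate sigma^2 and root state mu, tip values are
multivariate normal with mean mu and covariance sigma^2 C, where
C[i,j] is the shared root-to-MRCA path length of tips i and j.  The ML
root state is the GLS mean

    mu_hat = (1' C^-1 x) / (1' C^-1 1),

the ML rate (divisor n, so the usual slight downward bias relative to
REML) is

    sigma2_hat = (x - mu_hat 1)' C^-1 (x - mu_hat 1) / n,

and the ML state of any internal node is the GLS mean obtained after
re-rooting the tree at that node -- the tip-data likelihood itself is
invariant to the re-rooting point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AsrResult",
    "read_newick",
    "tree_from_string",
    "prune_to_taxa",
    "phylo_covariance",
    "bm_asr",
    "simulate_bm",
    "label_internal_nodes",
]

_POLYTOMY_EPS = 1e-8


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to_taxa(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Restrict a tree to ``taxa``, preserving tip-to-tip path lengths.

    Degree-two nodes created by pruning are suppressed with their edge
    lengths summed.  Taxa absent from the tree raise a warning and are
    ignored; an empty intersection is an error.
    """
    taxa = set(taxa)
    present = set(_tip_labels(tree))
    missing = sorted(taxa - present)
    if missing:
        warnings.warn(f"taxa absent from the tree were ignored: {missing}")
    keep = taxa & present
    if not keep:
        raise ValueError("no requested taxa are present in the tree")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    pruned.is_rooted = True
    return pruned


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "node") -> None:
    """Give every unlabeled internal node a stable label, in place."""
    counter = 0
    for node in tree.preorder_internal_node_iter():
        if node.label is None or node.label == "":
            node.label = f"{prefix}{counter}"
        counter += 1


def _resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    if all(len(nd.child_nodes()) <= 2 for nd in tree.preorder_internal_node_iter()):
        return tree
    warnings.warn(
        "polytomies resolved to binary nodes with epsilon-length branches"
    )
    work = tree.clone(depth=1)
    work.resolve_polytomies()
    for edge in work.preorder_edge_iter():
        if edge.tail_node is not None and (edge.length is None or edge.length == 0):
            edge.length = _POLYTOMY_EPS
    return work


def _root_distances(tree: dendropy.Tree) -> dict:
    dist = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            length = 0.0
        dist[node] = dist[node.parent_node] + length
    return dist


def phylo_covariance(tree: dendropy.Tree, taxa: list[str] | None = None) -> pd.DataFrame:
    """Brownian-motion covariance structure of a rooted tree.

    C[i,j] is the root-to-MRCA path length of tips i and j; the diagonal
    is each tip's depth.  Symmetric positive semi-definite.
    """
    depth = _root_distances(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: k for k, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for lf in leaves:
        C[index[lf], index[lf]] = depth[lf]

    # descendant-leaf sets bottom-up; cross-subtree pairs share the MRCA depth
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [node]
            continue
        children = [below[ch] for ch in node.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for la in children[a]:
                    for lb in children[b]:
                        i, j = index[la], index[lb]
                        C[i, j] = C[j, i] = depth[node]
        below[node] = [lf for ch in children for lf in ch]

    frame = pd.DataFrame(C, index=labels, columns=labels)
    if taxa is not None:
        frame = frame.loc[taxa, taxa]
    return frame


def _gls_root(C: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """GLS mean and its precision denominator 1'C^-1 1."""
    ones = np.ones(len(x))
    try:
        Ci_x = np.linalg.solve(C, x)
        Ci_1 = np.linalg.solve(C, ones)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular phylogenetic covariance (zero-length branches?)"
        ) from err
    denom = ones @ Ci_1
    return float(ones @ Ci_x / denom), float(denom)


@dataclass
class AsrResult:
    """ML ancestral states for one continuous character on one tree."""

    sigma2: float
    root_state: float
    log_likelihood: float
    node_states: pd.Series
    node_variances: pd.Series
    tree: dendropy.Tree
    character: pd.Series
    transform: str = "none"

    def annotated_newick(self) -> str:
        """Newick with per-node reconstructed states as comments."""
        out = self.tree.clone(depth=1)
        for node in out.preorder_internal_node_iter():
            if node.label in self.node_states.index:
                state = self.node_states[node.label]
                node.annotations.add_new("state", f"{state:.6g}")
        return out.as_string(schema="newick", suppress_annotations=False)

    def to_dict(self) -> dict:
        return {
            "sigma2": self.sigma2,
            "root_state": self.root_state,
            "log_likelihood": self.log_likelihood,
            "transform": self.transform,
            "node_states": {k: float(v) for k, v in self.node_states.items()},
            "node_variances": {k: float(v) for k, v in self.node_variances.items()},
        }


def _validate_branch_lengths(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None or node.edge.length <= 0:
            raise ValueError(
                "all branch lengths must be positive for Brownian-motion ASR"
            )


def bm_asr(
    tree: dendropy.Tree,
    character: pd.Series | dict,
    estimate_nodes: bool = True,
    transform: str = "none",
) -> AsrResult:
    """Brownian-motion ML ancestral state reconstruction.

    ``character`` maps every tip label to a finite value (a per-mille
    sterol proportion in this package's use).  ``transform='logit'``
    reconstructs on the logit of value/1000 and back-transforms the node
    states; the default reconstructs proportions directly.
    ``estimate_nodes=False`` skips the per-node re-rooting pass and
    returns only the rate, root state and likelihood.
    """
    x_in = pd.Series(character, dtype=float)
    if transform == "logit":
        p = x_in / 1000.0
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("logit transform needs values strictly inside (0, 1000)")
        x_in = np.log(p / (1 - p))
    elif transform != "none":
        raise ValueError(f"unknown transform: {transform!r}")
    if not np.isfinite(x_in.to_numpy()).all():
        raise ValueError("character values must be finite")

    work = _resolve_polytomies(tree).clone(depth=1)
    tips = _tip_labels(work)
    missing = set(tips) - set(x_in.index)
    if missing:
        raise ValueError(f"character values missing for tips: {sorted(missing)}")
    _validate_branch_lengths(work)
    label_internal_nodes(work)

    x = x_in.loc[tips].to_numpy()
    n = len(x)
    C = phylo_covariance(work).loc[tips, tips].to_numpy()
    root_state, _ = _gls_root(C, x)
    resid = x - root_state
    Ci_resid = np.linalg.solve(C, resid)
    sigma2 = float(resid @ Ci_resid / n)
    sign, logdet = np.linalg.slogdet(C)
    if sigma2 > 0:
        loglik = -0.5 * (
            n * math.log(2 * math.pi * sigma2) + logdet + n
        )
    else:
        loglik = math.inf  # degenerate: constant character fits exactly

    states, variances = {}, {}
    if estimate_nodes:
        node_labels = [nd.label for nd in work.preorder_internal_node_iter()]
        for lab in node_labels:
            if lab == work.seed_node.label:
                state, denom = root_state, _gls_root(C, x)[1]
            else:
                rerooted = work.clone(depth=1)
                target = next(
                    nd
                    for nd in rerooted.preorder_internal_node_iter()
                    if nd.label == lab
                )
                rerooted.reroot_at_node(target, update_bipartitions=False)
                C_v = phylo_covariance(rerooted).loc[tips, tips].to_numpy()
                state, denom = _gls_root(C_v, x)
            states[lab] = state
            variances[lab] = sigma2 / denom

    back = (lambda v: 1000.0 / (1.0 + np.exp(-v))) if transform == "logit" else (lambda v: v)
    node_states = pd.Series({k: float(back(v)) for k, v in states.items()}, dtype=float)
    node_vars = pd.Series(variances, dtype=float)
    return AsrResult(
        sigma2=sigma2,
        root_state=float(back(root_state)),
        log_likelihood=float(loglik),
        node_states=node_states,
        node_variances=node_vars,
        tree=work,
        character=x_in.loc[tips],
        transform=transform,
    )


def simulate_bm(
    tree: dendropy.Tree,
    sigma2: float,
    root_state: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Simulate a Brownian character along a tree; returns tip values.

    Each branch adds an independent Normal(0, sigma2 * length) increment,
    so tip values are exactly multivariate normal with the tree's
    phylogenetic covariance.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = {tree.seed_node: float(root_state)}
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            length = node.edge.length or 0.0
            increment = (
                rng.normal(0.0, math.sqrt(sigma2 * length)) if sigma2 > 0 and length > 0 else 0.0
            )
            values[node] = values[node.parent_node] + increment
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return pd.Series(out, dtype=float)
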