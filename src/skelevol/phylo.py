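"""Phylogenetic machinery: tree I/O, Brownian-motion covariance, data
whitening, taxon grafting, and ancestral state estimation.

Trees are held as :class:`Phylogeny`, a thin wrapper over a rooted, fully
bifurcating :class:`dendropy.Tree` with branch lengths in time units (Myr).
All comparative statistics downstream consume the :class:`PhyloCovariance`
produced by :func:`bm_covariance`: the expected among-tip covariance ``C``
under Brownian motion, its GLS root estimator, and a whitening matrix ``P``
with ``P C Pᵀ = I`` so that ordinary (iid) statistics applied to
``P (Y - 1a)`` measure *evolutionary* (phylogeny-corrected) covariation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_tree",
    "write_tree",
    "graft_taxa",
    "bm_covariance",
    "phylo_transform",
    "phylo_untransform",
    "ancestral_discrete",
    "ancestral_continuous",
    "TreeArrays",
    "tree_arrays",
]

PSD_TOL = 1e-10


@dataclass
class Phylogeny:
    """A rooted, bifurcating, branch-length-bearing phylogeny."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def prune_to(self, keep: list[str]) -> "Phylogeny":
        """Return a copy retaining only the tips in ``keep``."""
        missing = set(keep) - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        t = self.tree.clone(depth=1)
        t.retain_taxa_with_labels(keep)
        # dendropy can leave a unifurcating root after pruning
        t.suppress_unifurcations()
        return Phylogeny(t)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        return (max(d) - min(d)) < tol * max(max(d), 1.0)


def read_tree(newick: str) -> Phylogeny:
    """Parse a Newick string (or path to a Newick file) into a Phylogeny.

    Polytomies are resolved into zero-length bifurcations (with a warning);
    missing branch lengths raise.
    """
    if "(" not in newick:  # looks like a path
        with open(newick) as fh:
            newick = fh.read()
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=False
    )
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            raise ValueError(f"missing branch length on edge above {nd}")
    npoly = sum(1 for nd in tree.preorder_node_iter() if len(nd.child_nodes()) > 2)
    if npoly:
        warnings.warn(
            f"{npoly} polytomies resolved to zero-length bifurcations", stacklevel=2
        )
        tree.resolve_polytomies()
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                nd.edge.length = 0.0
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels")
    return Phylogeny(tree)


def write_tree(phy: Phylogeny, path: str | None = None) -> str:
    """Serialize to Newick; round-trips topology and lengths."""
    s = phy.tree.as_string(schema="newick", suppress_rooting=True)
    s = s.strip() + ("\n" if not s.endswith("\n") else "")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


# ---------------------------------------------------------------------------
# grafting


def _node_age(node: dendropy.Node) -> float:
    """Age of a node = max distance to any descendant tip (0 for tips)."""
    if node.is_leaf():
        return 0.0
    return max(
        _node_age(c) + c.edge.length for c in node.child_nodes()
    )


def graft_taxa(
    phy: Phylogeny, attachments: list[tuple[str, str | tuple, float]]
) -> Phylogeny:
    """Graft new tips onto the tree as sisters to existing taxa or clades.

    Each attachment is ``(new_tip, sister, stem_age)`` where ``sister`` is a
    tip label or a tuple of tip labels (their MRCA is used) and ``stem_age``
    is the age (time before present) at which the new lineage diverges from
    the sister lineage's subtending edge.
    """
    out = phy.copy()
    tree = out.tree
    for new_tip, sister, stem_age in attachments:
        if isinstance(sister, (tuple, list, set)):
            taxa = [tree.taxon_namespace.get_taxon(s) for s in sister]
            if any(t is None for t in taxa):
                raise ValueError(f"sister taxa not found: {sister}")
            snode = tree.mrca(taxa=taxa)
        else:
            tx = tree.taxon_namespace.get_taxon(sister)
            if tx is None:
                raise ValueError(f"sister taxon not found: {sister}")
            snode = tree.find_node_with_taxon_label(sister)
        parent = snode.parent_node
        if parent is None:
            raise ValueError("cannot graft onto the root edge")
        s_age = _node_age(snode)
        p_age = s_age + snode.edge.length
        if not (s_age <= stem_age <= p_age + 1e-9):
            raise ValueError(
                f"stem age {stem_age} outside sister edge span [{s_age}, {p_age}]"
            )
        # split the sister's edge at stem_age
        new_internal = parent.new_child(edge_length=p_age - stem_age)
        parent.remove_child(snode)
        new_internal.add_child(snode)
        snode.edge.length = stem_age - s_age
        tx_new = tree.taxon_namespace.new_taxon(label=new_tip)
        tipnode = new_internal.new_child(edge_length=stem_age)
        tipnode.taxon = tx_new
    tree.update_bipartitions(suppress_unifurcations=True)
    return out


# ---------------------------------------------------------------------------
# array form (used by comparative stats and the rate MCMC)


@dataclass
class TreeArrays:
    """Indexed array representation: tips are nodes ``0..n_tips-1``.

    ``parent[i]`` is the parent index (-1 for root), ``length[i]`` the length
    of the edge above node ``i`` (0 for the root), ``postorder`` an index
    ordering with children before parents.
    """

    n_tips: int
    parent: np.ndarray
    length: np.ndarray
    postorder: np.ndarray
    children: list[list[int]]
    tip_labels: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    def clade_edges(self, node: int) -> list[int]:
        """Edge indices (by child node) in the clade of ``node``, stem included."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.parent[v] >= 0 or v != self.root:
                out.append(v)
            stack.extend(self.children[v])
        return out

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.length[v]
        return d


def tree_arrays(phy: Phylogeny, tip_order: list[str] | None = None) -> TreeArrays:
    tree = phy.tree
    leaves = list(tree.leaf_node_iter())
    if tip_order is None:
        tip_order = [lf.taxon.label for lf in leaves]
    label_to_idx = {lab: i for i, lab in enumerate(tip_order)}
    if len(label_to_idx) != len(leaves):
        raise ValueError("tip_order must enumerate every tip exactly once")
    internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    idx: dict[int, int] = {}
    for lf in leaves:
        idx[id(lf)] = label_to_idx[lf.taxon.label]
    for k, nd in enumerate(internals):
        idx[id(nd)] = len(leaves) + k
    n = len(leaves) + len(internals)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    for nd in tree.postorder_node_iter():
        i = idx[id(nd)]
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
            length[i] = float(nd.edge.length or 0.0)
            children[parent[i]].append(i)
    post = [idx[id(nd)] for nd in tree.postorder_node_iter()]
    return TreeArrays(
        n_tips=len(leaves),
        parent=parent,
        length=length,
        postorder=np.asarray(post, dtype=np.int64),
        children=children,
        tip_labels=list(tip_order),
    )


# ---------------------------------------------------------------------------
# BM covariance and whitening


@dataclass
class PhyloCovariance:
    """Among-tip Brownian-motion covariance with GLS and whitening helpers."""

    tips: list[str]
    C: np.ndarray
    P: np.ndarray = field(repr=False)
    Cinv: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.tips)

    def gls_mean(self, Y: np.ndarray) -> np.ndarray:
        """GLS (phylogenetic) root estimate ``a``, one row per trait set."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != self.n:
            raise ValueError("row count does not match tip count")
        one = np.ones(self.n)
        w = self.Cinv @ one
        return (w @ Y) / (one @ w)


def bm_covariance(phy: Phylogeny, tips: list[str] | None = None) -> PhyloCovariance:
    """Expected tip covariance under Brownian motion.

    ``C[i, j]`` is the shared root-to-MRCA path length of tips *i* and *j*;
    the whitener is the symmetric inverse square root ``P = U Λ^(-1/2) Uᵀ``
    from the eigendecomposition ``C = U Λ Uᵀ``.
    """
    ta = tree_arrays(phy, tips)
    n = ta.n_tips
    depths = ta.depths()
    C = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for v in ta.postorder:
        if not ta.children[v]:
            tipsets[v] = [v]
            C[v, v] = depths[v]
        else:
            kids = [tipsets[c] for c in ta.children[v]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.asarray(kids[a])
                    ib = np.asarray(kids[b])
                    C[np.ix_(ia, ib)] = depths[v]
                    C[np.ix_(ib, ia)] = depths[v]
            tipsets[v] = [t for k in kids for t in k]
    lam, U = np.linalg.eigh(C)
    scale = max(lam.max(), 1.0)
    bad = lam < -PSD_TOL * scale
    if bad.any():
        # identify near-duplicate tips: rows with tiny distinct path
        pairs = _near_duplicate_tips(C, ta.tip_labels)
        raise np.linalg.LinAlgError(
            f"covariance not PSD (min eigenvalue {lam.min():.3g}); "
            f"near-duplicate tips: {pairs}"
        )
    small = lam < PSD_TOL * scale
    if small.any():
        pairs = _near_duplicate_tips(C, ta.tip_labels)
        raise np.linalg.LinAlgError(
            f"covariance singular to tolerance; near-duplicate tips: {pairs}"
        )
    # symmetric inverse square root: whitens while keeping the row ↔
    # species correspondence (needed by per-group statistics) and is
    # invariant to tip ordering
    P = (U / np.sqrt(lam)) @ U.T
    Cinv = (U / lam) @ U.T
    return PhyloCovariance(tips=ta.tip_labels, C=C, P=P, Cinv=Cinv)


def _near_duplicate_tips(C: np.ndarray, labels: list[str]) -> list[tuple[str, str]]:
    n = C.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            # Procrustes of distinct paths: d2 = C_ii + C_jj - 2 C_ij
            d2 = C[i, i] + C[j, j] - 2 * C[i, j]
            if d2 < 1e-8 * max(C[i, i], 1.0):
                out.append((labels[i], labels[j]))
    return out[:10]


def phylo_transform(Y: np.ndarray, cov: PhyloCovariance) -> np.ndarray:
    """Whiten species data: ``P (Y - 1a)``.

    Rows of the output are uncorrelated (identity covariance contribution)
    under Brownian motion, so iid statistics on them measure evolutionary
    covariation.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != cov.n:
        raise ValueError(
            f"dimension mismatch: {Y.shape[0]} rows vs {cov.n} tips"
        )
    a = cov.gls_mean(Y)
    return cov.P @ (Y - a)


def phylo_untransform(U: np.ndarray, cov: PhyloCovariance, a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`phylo_transform` given the GLS mean ``a``."""
    return np.linalg.solve(cov.P, U) + a


# ---------------------------------------------------------------------------
# ancestral states


def _er_transition(k: int, q: float, t: float) -> np.ndarray:
    """Equal-rates Markov transition matrix exp(Qt) in closed form."""
    e = np.exp(-k * q * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, (1.0 + (k - 1) * e) / k)
    return P


def ancestral_discrete(
    phy: Phylogeny, tip_states: dict[str, str]
) -> tuple[dict, dict, float]:
    """ML marginal ancestral states under an equal-rates Markov model.

    Returns ``(node_probs, branch_state, q_hat)``: per-node marginal state
    probabilities (keyed by tip label or internal node index), a per-branch
    modal state labeling (each branch takes the modal state of its child
    node; tip branches take the tip state; ties break toward the parent's
    modal state), and the ML transition rate.
    """
    ta = tree_arrays(phy)
    states = sorted(set(tip_states.values()))
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    n = ta.n_nodes
    if k == 1:
        only = states[0]
        node_probs = {v: {only: 1.0} for v in range(n)}
        branch_state = {v: only for v in range(n) if v != ta.root}
        return _relabel_probs(node_probs, ta), _relabel_branches(branch_state, ta), 0.0

    tipL = np.zeros((n, k))
    for i, lab in enumerate(ta.tip_labels):
        tipL[i, sidx[tip_states[lab]]] = 1.0

    def down(q: float) -> tuple[np.ndarray, float]:
        """Partial likelihoods below each node, with log-scaling."""
        L = np.zeros((n, k))
        logscale = 0.0
        for v in ta.postorder:
            if not ta.children[v]:
                L[v] = tipL[v]
            else:
                prod = np.ones(k)
                for c in ta.children[v]:
                    P = _er_transition(k, q, ta.length[c])
                    prod *= P @ L[c]
                m = prod.max()
                if m <= 0:
                    return L, -np.inf
                L[v] = prod / m
                logscale += np.log(m)
        return L, logscale

    def negloglik(logq: float) -> float:
        q = float(np.exp(logq))
        L, logscale = down(q)
        root = ta.root
        lik = L[root].mean()  # uniform root prior
        if lik <= 0 or not np.isfinite(logscale):
            return 1e300
        return -(np.log(lik) + logscale)

    res = minimize_scalar(negloglik, bounds=(-12.0, 8.0), method="bounded")
    q_hat = float(np.exp(res.x))

    # up-down pass for marginals
    L, _ = down(q_hat)
    up = np.zeros((n, k))
    root = ta.root
    up[root] = 1.0 / k  # root prior
    for v in ta.postorder[::-1]:
        for c in ta.children[v]:
            # message to child c: (up[v] * prod over siblings) through P
            sib = np.ones(k)
            for c2 in ta.children[v]:
                if c2 != c:
                    P2 = _er_transition(k, q_hat, ta.length[c2])
                    sib *= P2 @ L[c2]
            P = _er_transition(k, q_hat, ta.length[c])
            msg = (up[v] * sib) @ P
            m = msg.max()
            up[c] = msg / (m if m > 0 else 1.0)
    marg = up * L
    marg /= marg.sum(axis=1, keepdims=True)

    node_probs = {
        v: {states[i]: float(marg[v, i]) for i in range(k)} for v in range(n)
    }
    # branch labeling: modal state of child node, ties toward parent's mode
    branch_state: dict[int, str] = {}
    modal = {}
    for v in ta.postorder[::-1]:
        p = marg[v]
        best = np.flatnonzero(np.isclose(p, p.max(), rtol=0, atol=1e-12))
        if len(best) > 1 and ta.parent[v] >= 0 and ta.parent[v] in modal:
            pm = sidx[modal[ta.parent[v]]]
            choice = pm if pm in best else int(best[0])
        else:
            choice = int(best[0])
        modal[v] = states[choice]
    for v in range(n):
        if v == ta.root:
            continue
        if v < ta.n_tips:
            branch_state[v] = tip_states[ta.tip_labels[v]]
        else:
            branch_state[v] = modal[v]
    return _relabel_probs(node_probs, ta), _relabel_branches(branch_state, ta), q_hat


def _relabel_probs(node_probs: dict, ta: TreeArrays) -> dict:
    out = {}
    for v, p in node_probs.items():
        key = ta.tip_labels[v] if v < ta.n_tips else f"node{v}"
        out[key] = p
    return out


def _relabel_branches(branch_state: dict, ta: TreeArrays) -> dict:
    out = {}
    for v, s in branch_state.items():
        key = ta.tip_labels[v] if v < ta.n_tips else f"node{v}"
        out[key] = s
    return out


def ancestral_continuous(
    phy: Phylogeny, Y: np.ndarray, tips: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """GLS/ML ancestral trait estimates under Brownian motion.

    Computes the joint-normal conditional mean of every internal node given
    the tip values, with the root at its GLS estimate. Returns
    ``(estimates, node_ids)`` where rows of ``estimates`` are internal nodes
    (ids ``node{i}`` matching :func:`ancestral_discrete`; the root is last
    in postorder).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not np.isfinite(Y).all():
        raise ValueError("missing rows/values in Y")
    ta = tree_arrays(phy, tips)
    n, m = ta.n_tips, ta.n_nodes
    if Y.shape[0] != n:
        raise ValueError("row count does not match tip count")
    depths = ta.depths()
    # shared path length (root-to-MRCA depth) for every node pair, via
    # postorder accumulation of descendant node sets
    S = np.zeros((m, m))
    below: dict[int, list[int]] = {}
    for v in ta.postorder:
        groups = [below[c] for c in ta.children[v]] + [[v]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia, ib = np.asarray(groups[a]), np.asarray(groups[b])
                S[np.ix_(ia, ib)] = depths[v]
                S[np.ix_(ib, ia)] = depths[v]
        mem = [u for g in groups for u in g]
        below[v] = mem
    S[np.diag_indices(m)] = depths
    tipix = np.arange(n)
    nodeix = np.arange(n, m)
    Ctt = S[np.ix_(tipix, tipix)]
    Cnt = S[np.ix_(nodeix, tipix)]
    one = np.ones(n)
    Cinv_y = np.linalg.solve(Ctt, Y)
    Cinv_1 = np.linalg.solve(Ctt, one)
    a = (one @ Cinv_y) / (one @ Cinv_1)
    est = a + Cnt @ np.linalg.solve(Ctt, Y - a)
    node_ids = [f"node{v}" for v in range(n, m)]
    return est, node_ids
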