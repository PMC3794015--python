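"""Brownian-motion ancestral niche reconstruction on a time-calibrated tree.

Envelope bounds (lower and upper per climate variable) are treated as
independent continuous characters evolving by Brownian motion along the
tree.  Ancestral values at internal nodes are the generalized-least-squares
(equivalently, joint maximum-likelihood) estimates under the Brownian
covariance implied by shared path lengths; the root estimate is the GLS
grand mean.  Each species' envelope at a past time t on its terminal
branch is the linear interpolation between its modern (tip) bounds at t=0
and the GLS estimate at its parent node, evaluated at 4-ky steps.

Branch lengths are in My; slice ages are in ka BP, converted at this
module's interface at a fixed 1 My = 1000 ky.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd

from .niche import NicheEnvelope

KY_PER_MY = 1000.0


class MissingTraitError(KeyError):
    """A tip has no trait value; no silent imputation is performed."""


class BeyondBranchError(ValueError):
    """Requested time lies beyond the species' terminal branch."""


class PhyloTree:
    """Thin wrapper over a dendropy tree with node ages in My.

    Zero-length branches are collapsed on read (with a warning); extant
    tips are required to be at age 0 within tolerance (ultrametric for
    living species).
    """

    def __init__(self, tree: dendropy.Tree, ultrametric_tol: float = 1e-6):
        tree = tree.clone(depth=1)
        zero = [e for e in tree.preorder_edge_iter()
                if e.length is not None and e.length <= 0
                and e.head_node.parent_node is not None]
        internal_zero = [e for e in zero if not e.head_node.is_leaf()]
        if internal_zero:
            warnings.warn(f"collapsing {len(internal_zero)} zero-length "
                          "internal branches")
            for e in internal_zero:
                e.collapse()
        self.tree = tree
        self._index_nodes(ultrametric_tol)

    def _index_nodes(self, tol: float):
        t = self.tree
        # depth = distance from root; age = depth of deepest tip - depth
        depths = {}
        for nd in t.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
        self.root_age = max(depths[l] for l in t.leaf_node_iter())
        tip_depths = np.array([depths[l] for l in t.leaf_node_iter()])
        if np.any(np.abs(tip_depths - self.root_age) > max(tol, 1e-6 * self.root_age)):
            warnings.warn("tree is not ultrametric: extant tip ages deviate "
                          "from 0")
        self.nodes = list(t.preorder_node_iter())
        self.node_id = {nd: i for i, nd in enumerate(self.nodes)}
        self.ages = {nd: self.root_age - depths[nd] for nd in self.nodes}
        self.tips = [nd for nd in self.nodes if nd.is_leaf()]
        self.internal = [nd for nd in self.nodes if not nd.is_leaf()]
        self.tip_labels = [nd.taxon.label for nd in self.tips]
        self._tip_by_label = dict(zip(self.tip_labels, self.tips))

    # --- constructors ----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    # --- accessors -------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip(self, label: str):
        return self._tip_by_label[label]

    def parent_age_my(self, label: str) -> float:
        """Age (My BP) of the node subtending a species' terminal branch."""
        return float(self.ages[self.tip(label).parent_node])

    def min_terminal_branch_my(self) -> float:
        return min(self.ages[t.parent_node] for t in self.tips)

    def validate_window(self, window_ka: float = 320.0) -> None:
        """Require the modeled time window to lie within every terminal
        branch, so along-branch interpolation never leaves the branch."""
        short = [l for l in self.tip_labels
                 if self.parent_age_my(l) * KY_PER_MY < window_ka]
        if short:
            raise BeyondBranchError(
                f"terminal branches shorter than {window_ka} ka for {short}")

    def node_label(self, nd) -> str:
        if nd.is_leaf():
            return nd.taxon.label
        return f"node{self.node_id[nd]}"


def _bm_precision_system(ptree: PhyloTree):
    """Edge list (parent idx, child idx, 1/length) over all nodes."""
    entries = []
    for nd in ptree.nodes:
        p = nd.parent_node
        if p is None:
            continue
        ln = nd.edge.length
        if ln is None or ln <= 0:
            ln = 1e-9   # collapsed terminal zero branches, guarded upstream
        entries.append((ptree.node_id[p], ptree.node_id[nd], 1.0 / ln))
    return entries


def ancestral_estimate(ptree: PhyloTree, trait: dict,
                       with_se: bool = True) -> pd.DataFrame:
    """GLS ancestral state estimates at every internal node.

    ``trait`` maps tip label -> value; every tip must be present.  The
    joint Brownian log-likelihood is quadratic in the unknown internal
    states, so the estimates solve a weighted-Laplacian linear system with
    edge weights 1/branch-length.  Standard errors come from the inverse
    of the internal-block precision matrix scaled by the ML rate.

    Returns a DataFrame indexed by node label with columns ``estimate``,
    ``se``, ``age_my``.
    """
    missing = [l for l in ptree.tip_labels if l not in trait]
    if missing:
        raise MissingTraitError(f"tips without trait values: {missing}")
    n_nodes = len(ptree.nodes)
    tip_idx = np.array([ptree.node_id[t] for t in ptree.tips])
    anc_idx = np.array([ptree.node_id[nd] for nd in ptree.internal])
    x_full = np.zeros(n_nodes)
    for t in ptree.tips:
        x_full[ptree.node_id[t]] = float(trait[t.taxon.label])

    L = np.zeros((n_nodes, n_nodes))
    for i, j, w in _bm_precision_system(ptree):
        L[i, i] += w
        L[j, j] += w
        L[i, j] -= w
        L[j, i] -= w
    Laa = L[np.ix_(anc_idx, anc_idx)]
    Lat = L[np.ix_(anc_idx, tip_idx)]
    a_hat = np.linalg.solve(Laa, -Lat @ x_full[tip_idx])

    out = pd.DataFrame({
        "node": [ptree.node_label(nd) for nd in ptree.internal],
        "estimate": a_hat,
        "age_my": [ptree.ages[nd] for nd in ptree.internal],
    }).set_index("node")

    if with_se:
        rate = bm_rate_ml(ptree, trait)
        cov = np.linalg.inv(Laa) * max(rate, 0.0)
        out["se"] = np.sqrt(np.diag(cov))
    return out


def _tip_covariance(ptree: PhyloTree) -> np.ndarray:
    """Brownian tip covariance: shared path length from the root."""
    n = ptree.n_tips
    tip_pos = {t: i for i, t in enumerate(ptree.tips)}
    C = np.zeros((n, n))
    for t in ptree.tips:
        C[tip_pos[t], tip_pos[t]] = ptree.root_age - ptree.ages[t]
    # shared path length of a tip pair = depth of their MRCA; accumulate by
    # postorder: tips in different child subtrees of a node have that node
    # as MRCA
    below = {}
    for nd in ptree.tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = [tip_pos[nd]]
            continue
        groups = [below[ch] for ch in nd.child_nodes()]
        depth = ptree.root_age - ptree.ages[nd]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        C[i, j] = C[j, i] = depth
        below[nd] = [i for g in groups for i in g]
    return C


def bm_rate_ml(ptree: PhyloTree, trait: dict) -> float:
    """Maximum-likelihood Brownian rate (trait variance per My).

    sigma^2 = (x - mu 1)' C^{-1} (x - mu 1) / n with mu the GLS grand mean
    and C the shared-path-length covariance.  A constant trait returns 0
    with a warning.
    """
    missing = [l for l in ptree.tip_labels if l not in trait]
    if missing:
        raise MissingTraitError(f"tips without trait values: {missing}")
    x = np.array([float(trait[l]) for l in ptree.tip_labels])
    if np.ptp(x) == 0.0:
        warnings.warn("constant trait: Brownian rate estimated as 0")
        return 0.0
    C = _tip_covariance(ptree)
    Cinv = np.linalg.inv(C)
    one = np.ones_like(x)
    mu = (one @ Cinv @ x) / (one @ Cinv @ one)
    r = x - mu
    return float(r @ Cinv @ r / x.size)


class NicheReconstruction:
    """Fitted Brownian reconstruction of envelope-bound traits.

    Each column of the trait matrix (``{VAR}_lower`` / ``{VAR}_upper`` per
    modeling variable) is reconstructed independently; the fitted object
    then serves time-adjusted envelopes along any terminal branch.
    """

    def __init__(self, ptree: PhyloTree, traits: pd.DataFrame):
        missing = [l for l in ptree.tip_labels if l not in traits.index]
        if missing:
            raise MissingTraitError(f"tips missing from trait matrix: {missing}")
        self.ptree = ptree
        self.traits = traits.loc[ptree.tip_labels]
        self.node_estimates = pd.DataFrame({
            col: ancestral_estimate(ptree, self.traits[col].to_dict(),
                                    with_se=False)["estimate"]
            for col in traits.columns
        })
        self.var_names = tuple(dict.fromkeys(
            c.rsplit("_", 1)[0] for c in traits.columns))

    def rates(self) -> pd.Series:
        """ML Brownian rate per trait column (variance per My)."""
        return pd.Series({c: bm_rate_ml(self.ptree, self.traits[c].to_dict())
                          for c in self.traits.columns})

    def envelope_at_time(self, species: str, t_ka: float,
                         trim_fraction: float = 0.0) -> NicheEnvelope:
        """Time-adjusted envelope for a species at t ka BP on its branch.

        Bounds interpolate linearly between the tip's modern value (t=0)
        and the parent node's GLS estimate (at the node's age).  If the
        interpolation crosses (lower > upper) on a variable, both bounds
        collapse to their midpoint with a warning.
        """
        if t_ka < 0:
            raise ValueError("t must be >= 0 ka BP")
        age_my = self.ptree.parent_age_my(species)
        t_my = t_ka / KY_PER_MY
        if t_my > age_my + 1e-12:
            raise BeyondBranchError(
                f"{t_ka} ka exceeds {species}'s terminal branch "
                f"({age_my * KY_PER_MY:.0f} ka)")
        frac = 0.0 if age_my == 0 else t_my / age_my
        parent = self.ptree.tip(species).parent_node
        node_lbl = self.ptree.node_label(parent)
        lower, upper = [], []
        for v in self.var_names:
            lo_tip = self.traits.at[species, f"{v}_lower"]
            up_tip = self.traits.at[species, f"{v}_upper"]
            lo_node = self.node_estimates.at[node_lbl, f"{v}_lower"]
            up_node = self.node_estimates.at[node_lbl, f"{v}_upper"]
            lo = lo_tip + frac * (lo_node - lo_tip)
            up = up_tip + frac * (up_node - up_tip)
            if lo > up:
                warnings.warn(f"bound crossing for {species}/{v} at "
                              f"{t_ka} ka; collapsing to midpoint")
                lo = up = 0.5 * (lo + up)
            lower.append(lo)
            upper.append(up)
        return NicheEnvelope(var_names=self.var_names,
                             lower=np.array(lower), upper=np.array(upper),
                             trim_fraction=trim_fraction,
                             provenance=f"time-adjusted at {t_ka:g} ka")


def envelopes_to_traits(envelopes: dict) -> pd.DataFrame:
    """Stack per-species envelopes into a trait matrix (rows = tips,
    columns = ``{VAR}_lower`` / ``{VAR}_upper``)."""
    rows = {}
    for sp, env in envelopes.items():
        row = {}
        for i, v in enumerate(env.var_names):
            row[f"{v}_lower"] = env.lower[i]
            row[f"{v}_upper"] = env.upper[i]
        rows[sp] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def envelope_at_time(ptree: PhyloTree, traits: pd.DataFrame, species: str,
                     t_ka: float) -> NicheEnvelope:
    """Convenience one-shot form of
    :meth:`NicheReconstruction.envelope_at_time`."""
    return NicheReconstruction(ptree, traits).envelope_at_time(species, t_ka)
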