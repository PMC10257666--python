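"""Phylogenetically independent contrasts and local (genus-level) rates.

A contrast is the trait difference between the two descendants of an internal
node, standardised by the phylogenetic distance between them:
``PIC = (x1 - x2) / sqrt(l1 + l2)``, where the branch lengths are corrected
during the Felsenstein recursion (each merged node extends its parent branch
by ``l1*l2/(l1+l2)``).  The same recursion, generalised to per-branch rates
and per-tip white-noise variances, is the workhorse behind the pulsed
evolution likelihood (:mod:`pulsegcn.model`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import Phylogeny, induced_subtree

__all__ = ["Contrast", "compute_pics", "contrast_decomposition", "local_rates",
           "PATH_LENGTH_FLOOR"]

#: floor used in place of an exactly-zero contrast path length when division
#: cannot be avoided (conspecific duplicates with equal traits)
PATH_LENGTH_FLOOR = 1e-9


@dataclass
class Contrast:
    """Standardised contrast at one internal node of a bifurcating tree."""

    value: float           # (x1 - x2) / sqrt(path_length)
    raw_difference: float  # x1 - x2
    path_length: float     # corrected l1 + l2 (floored if degenerate-equal)
    node: int              # internal node id where the contrast is formed
    tip_flags: tuple[bool, bool]
    degenerate: bool = False  # zero path with unequal traits (infinite PIC)


def _trait_vector(tree: Phylogeny, traits: dict[str, float]) -> np.ndarray:
    x = np.full(tree.n_nodes, np.nan)
    missing = [lab for lab in tree.tip_labels if lab not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    for t in tree.tip_ids:
        x[t] = float(traits[tree.labels[t]])
    return x


def compute_pics(tree: Phylogeny, traits: dict[str, float]) -> list[Contrast]:
    """Felsenstein's independent contrasts (unit BM rate, no tip noise).

    Returns ``n_tips - 1`` contrasts.  A zero sister path with unequal traits
    yields a contrast flagged ``degenerate`` (value ``inf``); with equal
    traits the value is 0 and the path length is replaced by
    :data:`PATH_LENGTH_FLOOR`.
    """
    x = _trait_vector(tree, traits)
    adj = tree.lengths.astype(float).copy()  # corrected branch lengths
    out: list[Contrast] = []
    for node in tree.postorder:
        ch = tree.children[node]
        if not ch:
            continue
        if len(ch) != 2:  # pragma: no cover - parse_tree resolves polytomies
            raise ValueError("tree must be bifurcating (resolve polytomies first)")
        c1, c2 = ch
        l1, l2 = adj[c1], adj[c2]
        L = l1 + l2
        d = x[c1] - x[c2]
        if L > 0:
            out.append(Contrast(value=d / np.sqrt(L), raw_difference=d, path_length=L,
                                node=int(node),
                                tip_flags=(tree.is_tip(c1), tree.is_tip(c2))))
            x[node] = (l2 * x[c1] + l1 * x[c2]) / L
            adj[node] += l1 * l2 / L
        else:
            degenerate = d != 0
            value = np.inf * np.sign(d) if degenerate else 0.0
            out.append(Contrast(value=value, raw_difference=d,
                                path_length=PATH_LENGTH_FLOOR, node=int(node),
                                tip_flags=(tree.is_tip(c1), tree.is_tip(c2)),
                                degenerate=degenerate))
            x[node] = 0.5 * (x[c1] + x[c2])
    return out


class ContrastPlan:
    """Precomputed traversal for repeated contrast decompositions.

    Fitting evaluates the likelihood thousands of times on one (tree,
    traits) pair; this caches the postorder merge schedule and tip trait
    vector so each evaluation is a tight scalar loop.
    """

    __slots__ = ("tree", "n_nodes", "x0", "tip_list", "merges", "nodes",
                 "child_nodes")

    def __init__(self, tree: Phylogeny, traits: dict[str, float]):
        self.tree = tree
        self.n_nodes = tree.n_nodes
        xv = _trait_vector(tree, traits)
        self.x0 = [float(v) if np.isfinite(v) else 0.0 for v in xv]
        self.tip_list = [int(t) for t in tree.tip_ids]
        merges = []
        nodes = []
        child_nodes = []
        for node in tree.postorder:
            ch = tree.children[node]
            if not ch:
                continue
            if len(ch) != 2:
                raise ValueError("tree must be bifurcating (resolve polytomies first)")
            c1, c2 = ch
            merges.append((int(node), int(c1), int(c2),
                           float(tree.lengths[c1]), float(tree.lengths[c2])))
            nodes.append(int(node))
            child_nodes.append((int(c1), int(c2)))
        self.merges = merges
        self.nodes = np.array(nodes, dtype=int)
        self.child_nodes = np.array(child_nodes, dtype=int)

    def decompose(self, rate, tip_noise, intensity=None):
        """Run the recursion; ``rate``/``tip_noise``/``intensity`` may be
        scalars or per-node arrays (see :func:`contrast_decomposition`)."""
        n = self.n_nodes
        rate_l = [float(rate)] * n if np.isscalar(rate) else list(map(float, rate))
        x = list(self.x0)
        s = [0.0] * n
        if np.isscalar(tip_noise):
            for t in self.tip_list:
                s[t] = float(tip_noise)
        else:
            for t in self.tip_list:
                s[t] = float(tip_noise[t])
        lam_l = None
        if intensity is not None:
            lam_l = [float(intensity)] * n if np.isscalar(intensity) \
                else list(map(float, intensity))

        m = len(self.merges)
        d = [0.0] * m
        gauss_var = [0.0] * m
        proc_var = [0.0] * m
        pois = [0.0] * m if lam_l is not None else None
        for k, (node, c1, c2, l1, l2) in enumerate(self.merges):
            u1 = rate_l[c1] * l1 + s[c1]
            u2 = rate_l[c2] * l2 + s[c2]
            d[k] = x[c1] - x[c2]
            gauss_var[k] = s[c1] + s[c2]
            proc_var[k] = rate_l[c1] * l1 + rate_l[c2] * l2
            if pois is not None:
                pois[k] = lam_l[c1] * l1 + lam_l[c2] * l2
            U = u1 + u2
            if U > 0.0:
                x[node] = (u2 * x[c1] + u1 * x[c2]) / U
                s[node] = u1 * u2 / U
            else:
                x[node] = 0.5 * (x[c1] + x[c2])
                s[node] = 0.0
        return {"d": np.array(d), "gauss_var": np.array(gauss_var),
                "proc_var": np.array(proc_var),
                "pois": np.array(pois) if pois is not None else None,
                "node": self.nodes, "child_nodes": self.child_nodes}


def contrast_decomposition(
    tree: Phylogeny,
    traits: dict[str, float],
    rate,
    tip_noise,
    intensity=None,
    plan: ContrastPlan | None = None,
):
    """Generalised contrast recursion with per-branch rates and tip noise.

    Parameters
    ----------
    rate
        Per-node variance-accumulation rate of the branch above each node
        (``sigma^2`` for BM, ``lambda * sigma2_jump`` for pulsed evolution);
        scalar or array.
    tip_noise
        Per-node white-noise variance (only entries at tips are used).
    intensity
        Optional per-node Poisson jump intensity per unit branch length; when
        given, each contrast's total jump intensity ``lam1*l1 + lam2*l2`` is
        returned (Poisson additivity along the two sister branches).

    Returns a dict of arrays over the ``n_tips - 1`` internal-node contrasts:
    ``d`` raw differences, ``gauss_var`` the Gaussian variance carried into
    the contrast (descendant uncertainty plus tip noise, excluding the branch
    process), ``proc_var`` the branch-process variance ``rate1*l1+rate2*l2``,
    ``pois`` total jump intensity (or None), ``node`` contrast node ids, and
    ``child_nodes`` the two direct children forming each contrast.
    """
    if plan is None:
        plan = ContrastPlan(tree, traits)
    return plan.decompose(rate, tip_noise, intensity)


def local_rates(
    tree: Phylogeny,
    traits: dict[str, float],
    clade_map: dict[str, str],
    min_tips: int = 10,
) -> dict[str, float]:
    """Per-clade local evolution rate: the variance of the clade's contrasts.

    Each clade (e.g. a genus) with at least ``min_tips`` member tips is pruned
    to its induced subtree and the rate is estimated as the mean squared
    standardised contrast (the unit-scaling BM rate estimator; contrasts have
    zero expectation under BM).  Degenerate contrasts (zero sister path) are
    dropped from the estimate.  Clades below the size floor are omitted.
    """
    clades: dict[str, list[str]] = {}
    for lab, clade in clade_map.items():
        clades.setdefault(clade, []).append(lab)
    out: dict[str, float] = {}
    for clade, members in sorted(clades.items()):
        members = [m for m in members if m in tree._label_to_id]
        if len(members) < min_tips:
            continue
        sub = induced_subtree(tree, members)
        pics = compute_pics(sub, {m: traits[m] for m in members})
        vals = np.array([c.value for c in pics
                         if not c.degenerate and c.path_length > PATH_LENGTH_FLOOR])
        if len(vals) == 0:
            out[clade] = 0.0
        else:
            out[clade] = float(np.mean(vals ** 2))
    return out
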