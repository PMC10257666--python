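"""Hidden-state prediction of gene copy numbers with calibrated confidence.

A query attached to the reference phylogeny (by a jplace placement, or as a
held-out tip) is predicted in three steps:

1. the ancestral trait distribution at the attachment point is reconstructed
   by Gaussian message passing over the tree, each branch contributing
   variance at its group's process rate (``lambda * sigma2_jump``); observed
   reference values are treated as exact — exact under BM, moment-matched
   under pulsed evolution;
2. the pendant branch applies the compound-Poisson jump mixture of the
   query's group, plus the group's time-independent variance (for the
   regularly-evolving group this is the "small added branch" that caps
   attainable confidence);
3. the continuous predictive distribution is integrated over unit intervals
   to an integer PMF (all mass below 1.5 folds into copy number 1); the point
   estimate is the rounded continuous mean (clamped to >= 1), its PMF mass is
   the confidence, and predictions under 95% confidence are flagged
   unreliable.

Reference-tree rescaling for adjusted NSTD/NSTI multiplies slowly-evolving
branch lengths by the jump-frequency ratio ``lambda_slow / lambda_regular``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from .model import HeterogeneousPEModel
from .pulsed import mixture_cdf
from .tree import Phylogeny, TreeError

__all__ = [
    "Placement",
    "IntegerPMF",
    "PredictionResult",
    "rescale_reference",
    "predict_tip",
    "predict_holdout",
    "adjusted_nstd",
    "adjusted_nsti",
    "read_jplace",
    "CONFIDENCE_THRESHOLD",
]

#: predictions with confidence below this are flagged unreliable
CONFIDENCE_THRESHOLD = 0.95


@dataclass
class Placement:
    """Attachment of a query to a reference-tree edge.

    ``edge_node`` is the child-end node of the attachment edge;
    ``distal_position`` the distance from that child node up towards the
    parent (must not exceed the edge length); ``pendant_length`` the length
    of the new branch leading to the query.
    """

    query: str
    edge_node: int
    distal_position: float = 0.0
    pendant_length: float = 0.0

    def validate(self, tree: Phylogeny) -> None:
        if not (0 <= self.edge_node < tree.n_nodes) or self.edge_node == tree.root:
            raise ValueError(f"attachment edge node {self.edge_node} not in tree")
        if self.distal_position < 0 or self.pendant_length < 0:
            raise ValueError("negative placement lengths")
        if self.distal_position > tree.lengths[self.edge_node] + 1e-12:
            raise ValueError("distal position exceeds edge length")


class IntegerPMF(dict):
    """PMF over integer copy numbers k >= 1 (sums to 1 within 1e-9)."""

    def __init__(self, probs: dict[int, float]):
        super().__init__({int(k): float(p) for k, p in probs.items() if p > 0})
        total = sum(self.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"PMF sums to {total}, not 1")

    @property
    def mode(self) -> int:
        return max(self, key=lambda k: (self[k], -k))

    def mean(self) -> float:
        return sum(k * p for k, p in self.items())

    def to_json(self) -> str:
        return json.dumps({str(k): self[k] for k in sorted(self)})

    @classmethod
    def from_json(cls, text: str) -> "IntegerPMF":
        return cls({int(k): v for k, v in json.loads(text).items()})


@dataclass
class PredictionResult:
    """A query's predicted copy number with uncertainty bookkeeping."""

    query: str
    point_estimate: int
    continuous_mean: float
    continuous_variance: float
    pmf: IntegerPMF
    confidence: float
    reliable: bool
    group: str
    adjusted_nstd: float = np.nan
    raw_nstd: float = np.nan
    pmf_argmax: int = field(default=0)  # diagnostic alternative point estimate


# --------------------------------------------------------------------------
# tree rescaling & adjusted NSTD / NSTI
# --------------------------------------------------------------------------

def rescale_reference(tree: Phylogeny, model: HeterogeneousPEModel) -> Phylogeny:
    """Rescaled reference tree: slowly-evolving branch lengths multiplied by
    ``lambda_slow / lambda_regular``; regular branches unchanged."""
    if model.lambda_regular <= 0:
        raise ValueError("lambda_regular must be positive to rescale")
    ratio = model.lambda_slow / model.lambda_regular
    out = tree.copy()
    slow = ~model.assignment.regular
    slow[tree.root] = False
    out.lengths[slow] *= ratio
    return out


def adjusted_nstd(query_tip: str, rescaled_tree: Phylogeny, reference_tips) -> float:
    """NSTD of the query on the rate-rescaled reference tree."""
    from .tree import nstd

    return nstd(rescaled_tree, query_tip, reference_tips)


def adjusted_nsti(read_counts: dict[str, float], adjusted_nstds: dict[str, float]) -> float:
    """Read-abundance-weighted mean of adjusted NSTDs over community members."""
    total = float(sum(read_counts.values()))
    if total <= 0:
        raise ValueError("community has zero total reads")
    missing = [o for o in read_counts if o not in adjusted_nstds]
    if missing:
        raise ValueError(f"no adjusted NSTD for OTUs: {missing[:5]}")
    return sum(c * adjusted_nstds[o] for o, c in read_counts.items()) / total


# --------------------------------------------------------------------------
# Gaussian message passing (ancestral reconstruction)
# --------------------------------------------------------------------------

_INVALID = (0.0, np.inf)  # flat message: no information


def _combine(messages):
    """Precision-weighted combination of (mean, var) messages; variance-zero
    messages are exact observations."""
    msgs = [(m, v) for m, v in messages if np.isfinite(v)]
    if not msgs:
        return _INVALID
    exact = [m for m, v in msgs if v <= 0]
    if exact:
        return (float(np.mean(exact)), 0.0)
    prec = np.array([1.0 / v for _, v in msgs])
    means = np.array([m for m, _ in msgs])
    p = prec.sum()
    return (float(np.dot(prec, means) / p), float(1.0 / p))


class AncestralReconstructor:
    """Two-pass Gaussian belief propagation for conditional trait
    distributions at arbitrary points of the reference tree.

    ``masked`` tips contribute no information (used for cross-validation
    hold-outs and NSTD-threshold reference thinning without tree surgery).
    """

    def __init__(self, tree: Phylogeny, traits: dict[str, float],
                 model: HeterogeneousPEModel, masked: set[str] | None = None):
        self.tree = tree
        self.model = model
        self.lam, self.rate, self.eps = model.branch_arrays(tree)
        masked_ids = {tree.tip_id(m) for m in (masked or set())}
        self.masked_ids = masked_ids
        n = tree.n_nodes

        # upward messages: distribution at each node given its subtree
        self.up = [_INVALID] * n
        for node in tree.postorder:
            if tree.is_tip(node):
                lab = tree.labels[node]
                # Tips without a trait value carry no information (queries or
                # unobserved taxa present in the tree).  Observed reference
                # values are treated as exact: the white-noise term enters
                # once, on the query's side of the insertion (this is what
                # caps regular-group confidence at 85% for a query identical
                # to a reference).
                if node not in masked_ids and lab in traits:
                    self.up[node] = (float(traits[lab]), 0.0)
                continue
            inc = []
            for c in tree.children[node]:
                m, v = self.up[c]
                if np.isfinite(v):
                    inc.append((m, v + self.rate[c] * tree.lengths[c]))
            self.up[node] = _combine(inc)
        if not np.isfinite(self.up[tree.root][1]):
            raise ValueError("no reference information available (all tips masked)")

        # downward: self.side[c] = message at parent(c) from everything
        # outside c's subtree (before adding c's own branch)
        self.side = [_INVALID] * n
        outside = [_INVALID] * n  # message at node from outside its subtree
        for node in tree.postorder[::-1]:  # preorder
            ch = tree.children[node]
            for c in ch:
                inc = [outside[node]] if np.isfinite(outside[node][1]) else []
                for s in ch:
                    if s is c:
                        continue
                    m, v = self.up[s]
                    if np.isfinite(v):
                        inc.append((m, v + self.rate[s] * tree.lengths[s]))
                self.side[c] = _combine(inc)
                m, v = self.side[c]
                outside[c] = (m, v + self.rate[c] * tree.lengths[c]) \
                    if np.isfinite(v) else _INVALID

    def holdout_attachment(self, query_node: int):
        """Attachment of a held-out tip to the *informative* part of the tree.

        Walking rootward from the query, the junction is the first ancestor
        where some other direction (a sibling subtree or the rest of the
        tree) carries reference information — the point where the query
        would insert if masked tips were actually pruned.  Everything
        between the query and the junction becomes pendant path: its branch
        lengths and per-branch jump intensities are accumulated so the full
        compound-Poisson mixture (stasis atom and heavy tails included)
        applies over it, rather than a Gaussian approximation.

        Returns ``(mean, variance, pendant_length, pendant_intensity)``.
        """
        t = self.tree
        node = query_node
        pend_len = 0.0
        pend_int = 0.0
        while node != t.root:
            pend_len += t.lengths[node]
            pend_int += self.lam[node] * t.lengths[node]
            u = int(t.parent[node])
            sibs = []
            for s in t.children[u]:
                if s == node:
                    continue
                m, v = self.up[s]
                if np.isfinite(v):
                    sibs.append((m, v + self.rate[s] * t.lengths[s]))
            if sibs:
                # junction: an informative lineage branches off here; the
                # rest of the (pruned) tree joins through the usual Gaussian
                # outside-message along real reference branches
                m, v = self.side[u] if u != t.root else _INVALID
                if u != t.root and np.isfinite(v):
                    sibs.append((m, v + self.rate[u] * t.lengths[u]))
                return (*_combine(sibs), pend_len, pend_int)
            node = u
        raise ValueError("no reference information available for the query")

    def at_point(self, edge_node: int, distal_position: float) -> tuple[float, float]:
        """Conditional (mean, variance) at a point on the edge above
        ``edge_node``, ``distal_position`` away from that node."""
        t = self.tree
        l = t.lengths[edge_node]
        r = self.rate[edge_node]
        inc = []
        m, v = self.up[edge_node]
        if np.isfinite(v):
            inc.append((m, v + r * distal_position))
        m, v = self.side[edge_node]
        if np.isfinite(v):
            inc.append((m, v + r * max(l - distal_position, 0.0)))
        mean, var = _combine(inc)
        if not np.isfinite(var):
            raise ValueError("attachment point has no reference information")
        return mean, var


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _integer_pmf(mean: float, base_var: float, pois_intensity: float,
                 sigma2_jump: float) -> IntegerPMF:
    """Integrate the predictive mixture over unit intervals centred on the
    integers; mass below 1.5 folds into k = 1."""
    spread = np.sqrt(base_var + (pois_intensity + 10.0 * np.sqrt(pois_intensity) + 3.0)
                     * sigma2_jump)
    kmax = max(_round_half_up(mean + 9.0 * spread) + 1, 2)
    ks = np.arange(1, kmax + 1)
    upper = mixture_cdf(ks + 0.5, mean, base_var, pois_intensity, sigma2_jump)
    probs = np.diff(np.concatenate([[0.0], upper]))
    probs[-1] += max(1.0 - upper[-1], 0.0)  # fold residual upper tail
    total = probs.sum()
    if not (abs(total - 1.0) <= 1e-9):
        probs = probs / total
    return IntegerPMF({int(k): p for k, p in zip(ks, probs) if p > 0})


def _predict_from_attachment(
    query: str,
    mean: float,
    var: float,
    group: str,
    pendant_length: float,
    model: HeterogeneousPEModel,
    intensity: float | None = None,
) -> PredictionResult:
    p = model.group_params(group)
    if intensity is None:
        intensity = p.lambda_ * pendant_length
    base_var = var + p.sigma2_eps
    pmf = _integer_pmf(mean, base_var, intensity, model.sigma2_jump)
    point = max(_round_half_up(mean), 1)
    confidence = pmf.get(point, 0.0)
    cont_var = var + p.sigma2_eps + intensity * model.sigma2_jump
    return PredictionResult(
        query=query,
        point_estimate=point,
        continuous_mean=mean,
        continuous_variance=cont_var,
        pmf=pmf,
        confidence=confidence,
        reliable=confidence >= CONFIDENCE_THRESHOLD,
        group=group,
        pmf_argmax=pmf.mode,
    )


def predict_tip(
    placement: Placement,
    tree: Phylogeny,
    traits: dict[str, float],
    model: HeterogeneousPEModel,
    reconstructor: AncestralReconstructor | None = None,
) -> PredictionResult:
    """Predict a query's copy number from its placement on the reference tree.

    The query's group is the attachment branch's; see the module docstring
    for the three-step construction.  A prebuilt ``reconstructor`` may be
    passed to amortise message passing over many placements.
    """
    placement.validate(tree)
    if not traits:
        raise ValueError("empty reference trait table")
    rec = reconstructor or AncestralReconstructor(tree, traits, model)
    mean, var = rec.at_point(placement.edge_node, placement.distal_position)
    group = model.assignment.group(placement.edge_node)
    return _predict_from_attachment(placement.query, mean, var, group,
                                    placement.pendant_length, model)


def predict_holdout(
    tree: Phylogeny,
    traits: dict[str, float],
    model: HeterogeneousPEModel,
    query_tips,
    masked_tips=None,
    rescaled: Phylogeny | None = None,
    distance_cache: tuple[np.ndarray, np.ndarray] | None = None,
    adjusted_cache: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[PredictionResult]:
    """Predict tips already present in the tree (cross-validation mode).

    Each query tip is converted to a placement on the informative part of
    the tree: queries and ``masked_tips`` contribute no reference
    information, and the pendant runs from the query to the junction with
    the first informative lineage (so reference thinning lengthens the
    pendant exactly as pruning would, and the jump mixture — with its
    stasis atom — applies over the whole path, each branch at its own
    group's jump frequency).  Raw and adjusted NSTDs (to the unmasked
    references, the latter on the rescaled tree) are attached to every
    result.
    """
    query_tips = list(query_tips)
    mask = set(query_tips) | set(masked_tips or ())
    rec = AncestralReconstructor(tree, traits, model, masked=mask)

    tips, D = distance_cache or tree.tip_distance_matrix()
    if rescaled is None:
        rescaled = rescale_reference(tree, model)
    tips_adj, D_adj = adjusted_cache or rescaled.tip_distance_matrix()
    pos = {tree.labels[t]: k for k, t in enumerate(tips)}
    ref_cols = np.array([pos[lab] for lab in tree.tip_labels if lab not in mask])
    if len(ref_cols) == 0:
        raise ValueError("no reference tips left after masking")

    out = []
    for q in query_tips:
        node = tree.tip_id(q)
        m, v, pend_len, pend_int = rec.holdout_attachment(node)
        group = model.assignment.group(node)
        res = _predict_from_attachment(q, m, v, group, pend_len, model,
                                       intensity=pend_int)
        res.raw_nstd = float(np.min(D[pos[q], ref_cols]))
        res.adjusted_nstd = float(np.min(D_adj[pos[q], ref_cols]))
        out.append(res)
    return out


# --------------------------------------------------------------------------
# jplace ingestion
# --------------------------------------------------------------------------

_TOKEN = re.compile(r"\{(\d+)\}")


def _parse_jplace_tree(text: str) -> tuple[Phylogeny, dict[int, int]]:
    """Parse the jplace tree string, whose edges carry ``{edge_num}`` tags.

    No installed library reads jplace trees, so the tagged newick is parsed
    directly with a small recursive-descent reader.  Returns the tree and a
    mapping edge_num -> child-end node id.
    """
    parent: list[int] = []
    lengths: list[float] = []
    children: list[list[int]] = []
    labels: list[str | None] = []
    edge_map: dict[int, int] = {}

    s = text.strip().rstrip(";")
    pos = 0

    def new_node(par: int) -> int:
        idx = len(parent)
        parent.append(par)
        lengths.append(0.0)
        children.append([])
        labels.append(None)
        if par >= 0:
            children[par].append(idx)
        return idx

    def parse_clade(par: int) -> int:
        nonlocal pos
        node = new_node(par)
        if s[pos] == "(":
            pos += 1
            while True:
                parse_clade(node)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise TreeError(f"jplace tree parse error at position {pos}")
        # label
        m = re.match(r"[^():,;{\[\]]*", s[pos:])
        label = m.group(0).strip() if m else ""
        pos += m.end()
        if label:
            labels[node] = label.strip("'")
        # branch length
        if pos < len(s) and s[pos] == ":":
            m = re.match(r":([0-9eE.+-]+)", s[pos:])
            if not m:
                raise TreeError(f"jplace tree parse error at position {pos}")
            lengths[node] = float(m.group(1))
            pos += m.end()
        # edge number tag
        m = _TOKEN.match(s[pos:])
        if m:
            edge_map[int(m.group(1))] = node
            pos += m.end()
        return node

    root = parse_clade(-1)
    if pos != len(s):
        raise TreeError(f"jplace tree parse error: trailing text at position {pos}")
    tree = Phylogeny(parent=np.array(parent, dtype=int),
                     lengths=np.array(lengths, dtype=float),
                     children=children, labels=labels, root=root)
    from .tree import resolve_polytomies

    return resolve_polytomies(tree), edge_map


def read_jplace(path_or_text: str) -> tuple[Phylogeny, list[Placement]]:
    """Read a jplace file: the reference tree and one best placement per query.

    For queries with multiple candidate placements the one with the highest
    likelihood weight ratio is used; the others are ignored.  Standard field
    order variants are handled through the ``fields`` array.
    """
    if "\n" not in path_or_text and not path_or_text.lstrip().startswith("{"):
        with open(path_or_text) as fh:
            doc = json.load(fh)
    else:
        doc = json.loads(path_or_text)
    tree, edge_map = _parse_jplace_tree(doc["tree"])
    fields = doc["fields"]
    idx = {name: i for i, name in enumerate(fields)}
    need = {"edge_num", "pendant_length"}
    if not need <= set(fields):
        raise ValueError(f"jplace fields missing {need - set(fields)}")

    placements = []
    for entry in doc["placements"]:
        names = entry.get("n") or [nm[0] for nm in entry.get("nm", [])]
        rows = entry["p"]
        if "like_weight_ratio" in idx and len(rows) > 1:
            rows = sorted(rows, key=lambda r: -r[idx["like_weight_ratio"]])
        best = rows[0]
        for name in names:
            placements.append(Placement(
                query=str(name),
                edge_node=edge_map[int(best[idx["edge_num"]])],
                distal_position=float(best[idx["distal_length"]])
                if "distal_length" in idx else 0.0,
                pendant_length=float(best[idx["pendant_length"]]),
            ))
    return tree, placements
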