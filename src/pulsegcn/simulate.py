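"""Synthetic trees, pulsed-evolution copy numbers, and community designs.

Every stage of the pipeline is testable end-to-end from these generators:
birth-death reference trees (branch lengths scaled to a 16S-like depth in
substitutions/site), integer copy numbers evolved under the two-group pulsed
evolution model, and two community designs — SC1-style single-environment
communities with log-normal cell abundances and multinomially sampled gene
reads, and SC2-style two-environment designs with signature OTUs and
per-sample OTU turnover for beta-diversity experiments.

The generator defaults are the study conditions: the regularly-evolving
group's white-noise sd 0.3473 caps unit-interval confidence at 85%, the
shared jump sd is that value / 0.4 (time-independent variation ~40% of a
jump), the slow group jumps 145-fold less frequently and carries no white
noise, and roughly half of the tips sit in slowly-evolving clades.  All are
overridable; everything is deterministic under its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correction import CommunityTable
from .model import GroupAssignment, HeterogeneousPEModel
from .tree import Phylogeny, parse_tree

__all__ = [
    "SimConfig",
    "SC1Design",
    "SC2Design",
    "DEFAULT_PE",
    "simulate_tree",
    "assign_rate_groups",
    "default_model",
    "simulate_gcn",
    "simulate_reference",
    "simulate_sc1",
    "simulate_sc2",
]

#: study-condition pulsed-evolution parameters (see module docstring)
DEFAULT_PE = {
    "sigma_eps_regular": 0.3473,          # caps regular-group confidence at 85%
    "jump_to_noise_sd_ratio": 0.4,        # noise sd ~= 40% of a jump sd
    "lambda_regular": 20.0,               # jumps per substitution/site
    "frequency_ratio": 145.0,             # regular/slow jump frequency
    "sigma_eps_slow": 0.0,
}


@dataclass
class SimConfig:
    """Reference-simulation configuration (reproducible under ``seed``)."""

    n_tips: int = 500
    depth: float = 0.4            # mean root-to-tip length, substitutions/site
    fraction_slow: float = 0.48   # fraction of tips in slowly-evolving clades
    root_value: float = 4.0
    lambda_regular: float = DEFAULT_PE["lambda_regular"]
    frequency_ratio: float = DEFAULT_PE["frequency_ratio"]
    sigma_eps_regular: float = DEFAULT_PE["sigma_eps_regular"]
    sigma_eps_slow: float = DEFAULT_PE["sigma_eps_slow"]
    seed: int = 0

    @property
    def sigma2_jump(self) -> float:
        sd_jump = self.sigma_eps_regular / DEFAULT_PE["jump_to_noise_sd_ratio"] \
            if self.sigma_eps_regular > 0 else 0.8683
        return sd_jump ** 2


@dataclass
class SC1Design:
    """Single-environment community design (reconstructed; all overridable).

    ``read_sampling``: "multinomial" draws gene reads multinomially at
    ``depth``; "expected" uses rounded expected counts (noise-free reads,
    isolating copy-number effects from sequencing noise).
    """

    n_otus: int = 200
    n_samples: int = 1
    depth: int = 100_000
    lognormal_sigma: float = 1.0
    read_sampling: str = "multinomial"
    seed: int = 0


@dataclass
class SC2Design:
    """Two-environment design with signature OTUs and per-sample turnover."""

    n_otus: int = 2000
    n_samples: int = 20            # per environment
    signature_fraction: float = 0.01
    enrichment_fold: float = 4.0
    turnover_rate: float = 0.20
    depth: int = 100_000
    lognormal_sigma: float = 1.0
    seed: int = 0

    @property
    def n_signature(self) -> int:
        return int(round(self.n_otus * self.signature_fraction))


# --------------------------------------------------------------------------
# trees and trait evolution
# --------------------------------------------------------------------------

def simulate_tree(n_tips: int = 500, depth: float = 0.4, seed: int = 0) -> Phylogeny:
    """Birth-death (pure-birth) tree with ``n_tips`` extant tips, branch
    lengths rescaled so the mean root-to-tip path equals ``depth``
    substitutions/site.  Deterministic under ``seed``."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    from dendropy.simulate import treesim

    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = parse_tree(newick)
    tips = tree.tip_ids
    mean_depth = float(np.mean(tree.depths()[tips]))
    tree.lengths *= depth / mean_depth
    # the birth-death start can emit exact-zero internal edges; floor them so
    # patristic distances and Gaussian contrast variances stay positive
    floor = 1e-6 * depth
    nonroot = np.arange(tree.n_nodes) != tree.root
    tree.lengths[nonroot & (tree.lengths <= 0)] = floor
    return tree


def assign_rate_groups(tree: Phylogeny, fraction_slow: float, seed: int = 0,
                       clade_size: tuple[int, int] = (10, 60)) -> GroupAssignment:
    """Label disjoint clades (sizes within ``clade_size``) slow until roughly
    ``fraction_slow`` of the tips are covered; all other branches regular."""
    rng = np.random.default_rng(seed)
    ntips = np.zeros(tree.n_nodes, dtype=int)
    for node in tree.postorder:
        ntips[node] = 1 if tree.is_tip(node) else sum(ntips[c] for c in tree.children[node])
    candidates = [n for n in range(tree.n_nodes)
                  if clade_size[0] <= ntips[n] <= clade_size[1]]
    rng.shuffle(candidates)
    target = int(fraction_slow * tree.n_tips)
    regular = np.ones(tree.n_nodes, dtype=bool)
    covered = 0
    taken: list[int] = []
    for cand in candidates:
        if covered >= target:
            break
        inside = any(_is_ancestor(tree, t, cand) or _is_ancestor(tree, cand, t) or t == cand
                     for t in taken)
        if inside:
            continue
        taken.append(cand)
        stack = [cand]
        while stack:  # the clade root's own branch stays regular; descendants slow
            v = stack.pop()
            for c in tree.children[v]:
                regular[c] = False
                stack.append(c)
        covered += ntips[cand]
    return GroupAssignment(tree, regular)


def _is_ancestor(tree: Phylogeny, anc: int, node: int) -> bool:
    while node != -1:
        if node == anc:
            return True
        node = int(tree.parent[node])
    return False


def default_model(tree: Phylogeny, config: SimConfig | None = None,
                  assignment: GroupAssignment | None = None) -> HeterogeneousPEModel:
    """Study-condition heterogeneous PE model on ``tree`` (see module
    docstring for where each default comes from)."""
    cfg = config or SimConfig()
    if assignment is None:
        assignment = assign_rate_groups(tree, cfg.fraction_slow, seed=cfg.seed)
    return HeterogeneousPEModel(
        sigma2_jump=cfg.sigma2_jump,
        lambda_slow=cfg.lambda_regular / cfg.frequency_ratio,
        lambda_regular=cfg.lambda_regular,
        sigma2_eps_slow=cfg.sigma_eps_slow ** 2,
        sigma2_eps_regular=cfg.sigma_eps_regular ** 2,
        assignment=assignment,
    )


def simulate_gcn(
    tree: Phylogeny,
    model: HeterogeneousPEModel,
    root_value: float = 4.0,
    seed: int = 0,
    discretize: bool = True,
) -> dict[str, float]:
    """Evolve copy numbers along the tree under the heterogeneous PE model.

    Along each branch ``N ~ Poisson(lambda_group * l)`` jumps of size
    ``Normal(0, sigma2_jump)`` accumulate; each tip adds its group's white
    noise.  With ``discretize`` the tip values are rounded (half up) and
    clamped to >= 1 — the observable integer copy numbers; disable it to
    study the continuous latent process.
    """
    if root_value < 1:
        raise ValueError("root value must be >= 1")
    rng = np.random.default_rng(seed)
    lam, _, eps = model.branch_arrays(tree)
    sd_jump = np.sqrt(model.sigma2_jump)
    value = np.empty(tree.n_nodes)
    value[tree.root] = root_value
    for node in tree.postorder[::-1]:  # preorder
        if node == tree.root:
            continue
        n_jumps = rng.poisson(lam[node] * tree.lengths[node])
        step = rng.normal(0.0, sd_jump, size=n_jumps).sum() if n_jumps else 0.0
        value[node] = value[tree.parent[node]] + step
    out: dict[str, float] = {}
    for t in tree.tip_ids:
        x = value[t]
        if eps[t] > 0:
            x += rng.normal(0.0, np.sqrt(eps[t]))
        if discretize:
            x = max(1, int(np.floor(x + 0.5)))
        out[tree.labels[t]] = x
    return out


def simulate_reference(config: SimConfig | None = None):
    """Convenience bundle: tree, true group assignment, generating model and
    integer copy numbers, all from one config/seed."""
    cfg = config or SimConfig()
    tree = simulate_tree(cfg.n_tips, cfg.depth, seed=cfg.seed)
    assignment = assign_rate_groups(tree, cfg.fraction_slow, seed=cfg.seed)
    model = default_model(tree, cfg, assignment)
    traits = simulate_gcn(tree, model, root_value=cfg.root_value, seed=cfg.seed + 1)
    return tree, assignment, model, traits


# --------------------------------------------------------------------------
# community designs
# --------------------------------------------------------------------------

def simulate_sc1(
    tree: Phylogeny,
    traits: dict[str, float],
    design: SC1Design | None = None,
    nstd_thresholds: tuple[float, ...] = (0.002, 0.005, 0.010, 0.022, 0.046,
                                          0.100, 0.215, 0.464, 1.000),
):
    """Single-environment communities for abundance-correction experiments.

    Cell abundances are log-normal; gene read counts are multinomial with
    probabilities proportional to ``cell_fraction * GCN`` at the design
    depth.  Also returns, per NSTD threshold, the reference tips at patristic
    distance >= threshold from every community OTU (thinned reference sets
    spanning the evaluation bins).

    Returns ``(CommunityTable, true_cell_abundance DataFrame, references)``.
    """
    d = design or SC1Design()
    if d.depth <= 0:
        raise ValueError("sequencing depth must be positive")
    rng = np.random.default_rng(d.seed)
    tips = list(tree.tip_labels)
    if d.n_otus > len(tips):
        raise ValueError("more community OTUs than tips")
    otus = sorted(rng.choice(tips, size=d.n_otus, replace=False))
    gcn = np.array([traits[o] for o in otus], dtype=float)

    counts = {}
    true_cell = {}
    for s in range(d.n_samples):
        cells = rng.lognormal(0.0, d.lognormal_sigma, size=d.n_otus)
        p = cells / cells.sum()
        g = p * gcn / np.dot(p, gcn)
        if d.read_sampling == "expected":
            counts[f"S{s + 1}"] = np.round(d.depth * g).astype(int)
        elif d.read_sampling == "multinomial":
            counts[f"S{s + 1}"] = rng.multinomial(int(d.depth), g)
        else:
            raise ValueError(f"unknown read_sampling: {d.read_sampling!r}")
        true_cell[f"S{s + 1}"] = p
    idx = pd.Index(otus, name="otu")
    community = CommunityTable(pd.DataFrame(counts, index=idx))
    truth = pd.DataFrame(true_cell, index=idx)

    tip_ids, D = tree.tip_distance_matrix()
    pos = {tree.labels[t]: k for k, t in enumerate(tip_ids)}
    otu_rows = np.array([pos[o] for o in otus])
    others = [lab for lab in tips if lab not in set(otus)]
    other_rows = np.array([pos[o] for o in others])
    min_dist = D[np.ix_(other_rows, otu_rows)].min(axis=1)
    references = {thr: [others[i] for i in np.flatnonzero(min_dist >= thr)]
                  for thr in nstd_thresholds}
    return community, truth, references


def simulate_sc2(tree: Phylogeny, traits: dict[str, float],
                 design: SC2Design | None = None):
    """Two-environment communities with signature OTUs for beta-diversity.

    Both environments share one OTU pool; each has ``n_signature`` disjoint
    signature OTUs whose expected cell abundance is multiplied by
    ``enrichment_fold`` at home.  Per sample, a ``turnover_rate`` fraction of
    the non-signature pool is replaced by OTUs from outside the pool
    (turnover = fraction of the core set replaced per sample).  Gene reads
    are multinomial proportional to ``cell * GCN``.

    Returns a dict with gene-count and true-cell-abundance tables (OTU x
    sample over the union of used OTUs), sample -> environment labels, and
    the signature OTUs per environment.
    """
    d = design or SC2Design()
    if d.n_signature == 0:
        raise ValueError("signature count is zero; increase signature_fraction")
    rng = np.random.default_rng(d.seed)
    tips = list(tree.tip_labels)
    if d.n_otus > len(tips):
        raise ValueError("pool larger than the tree's tip count")
    pool = list(rng.choice(tips, size=d.n_otus, replace=False))
    reserve = [t for t in tips if t not in set(pool)]
    sig_a = pool[: d.n_signature]
    sig_b = pool[d.n_signature: 2 * d.n_signature]
    signatures = {"A": sig_a, "B": sig_b}
    core = pool[2 * d.n_signature:]

    base = {t: rng.lognormal(0.0, d.lognormal_sigma) for t in tips}
    n_replace = int(round(d.turnover_rate * len(core)))

    gene = {}
    cell = {}
    labels = {}
    for env in ("A", "B"):
        for s in range(d.n_samples):
            name = f"{env}{s + 1}"
            labels[name] = env
            keep = list(rng.choice(core, size=len(core) - n_replace, replace=False)) \
                if n_replace else list(core)
            incoming = list(rng.choice(reserve, size=n_replace, replace=False)) \
                if n_replace else []
            members = sig_a + sig_b + keep + incoming
            ab = np.array([base[m] for m in members], dtype=float)
            home = set(signatures[env])
            for j, m in enumerate(members):
                if m in home:
                    ab[j] *= d.enrichment_fold
            p = ab / ab.sum()
            g = np.array([traits[m] for m in members], dtype=float)
            pg = p * g / np.dot(p, g)
            reads = rng.multinomial(int(d.depth), pg)
            gene[name] = dict(zip(members, reads))
            cell[name] = dict(zip(members, p))

    gene_df = pd.DataFrame(gene).fillna(0.0).sort_index()
    cell_df = pd.DataFrame(cell).fillna(0.0).sort_index()
    gene_df.index.name = cell_df.index.name = "otu"
    return {
        "gene_counts": CommunityTable(gene_df),
        "true_cell_abundance": cell_df,
        "labels": labels,
        "signatures": signatures,
    }
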