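"""Validation machinery: NSTD-binned cross-validation and beta-diversity.

Cross-validation follows the reference protocol: 2% of tips held out per
repeat (non-overlapping test sets within a bin), references thinned by an
NSTD threshold, and predictions scored by R^2, exact-integer accuracy, and
the precision/recall of the 95%-confidence reliability classification.

Beta-diversity support covers Bray-Curtis, normalised weighted UniFrac and
Aitchison (CLR/Euclidean) distances, classical-scaling PCoA, a seeded
PERMANOVA reporting the proportion of variance explained, and the
ordination-shift reduction achieved by copy-number correction (all three
abundance versions of every sample embedded in one joint PCoA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .model import HeterogeneousPEModel
from .predict import predict_holdout, rescale_reference
from .tree import Phylogeny

__all__ = [
    "CVResult",
    "DistanceMatrix",
    "PermanovaResult",
    "CV_THRESHOLDS",
    "cross_validate",
    "distance_matrix",
    "pcoa",
    "permanova",
    "shift_reduction",
    "ci_coverage_experiment",
    "precision_experiment",
]

#: NSTD thresholds delineating the cross-validation bins (substitutions/site)
CV_THRESHOLDS = (0.0, 0.002, 0.005, 0.010, 0.022, 0.046, 0.100, 0.215, 0.464, 1.000)


@dataclass
class CVResult:
    """Cross-validation summary (one row per NSTD bin) plus the raw
    per-prediction records the summary is computed from."""

    summary: pd.DataFrame
    records: pd.DataFrame

    def __repr__(self) -> str:  # pragma: no cover
        return f"CVResult\n{self.summary}"


@dataclass
class DistanceMatrix:
    """Sample x sample distances with a metric tag."""

    data: np.ndarray
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-8) or not np.allclose(np.diag(d), 0, atol=1e-8):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.data = d


@dataclass
class PermanovaResult:
    pseudo_f: float
    pve: float              # SS_between / SS_total
    p_value: float
    n_permutations: int
    permuted_f: np.ndarray = field(repr=False, default=None)  # type: ignore


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def _default_predictor(tree, traits, model, queries, mask, rescaled, dcache, acache):
    return predict_holdout(tree, traits, model, queries, masked_tips=mask,
                           rescaled=rescaled, distance_cache=dcache,
                           adjusted_cache=acache)


def cross_validate(
    tree: Phylogeny,
    traits: dict[str, float],
    model: HeterogeneousPEModel,
    thresholds=CV_THRESHOLDS[:-1],
    test_fraction: float = 0.02,
    repeats: int = 50,
    seed: int = 0,
    predictor=None,
) -> CVResult:
    """NSTD-binned cross-validation of copy-number prediction quality.

    Per repeat within a bin: hold out ``test_fraction`` of the tips (test
    sets are disjoint across a bin's repeats), remove every reference tip
    closer than the bin's threshold to any test tip, predict the test tips,
    and score.  R^2 is the fraction of variance in the true copy numbers
    explained by the point predictions; precision is the proportion of exact
    predictions among those flagged reliable (confidence >= 95%); recall the
    proportion of reliable predictions among the exact ones.  Bins whose
    thinning leaves fewer than 2 references are skipped with a warning.
    Repeat-level means are averaged per bin with a normal-theory 95% CI.

    ``predictor(queries, mask) -> list[PredictionResult]`` may be injected
    (e.g. an oracle) in place of the model-based hidden-state predictor.
    """
    tips = sorted(tree.tip_labels)
    n = len(tips)
    n_test = max(1, int(round(test_fraction * n)))
    tip_ids, D = tree.tip_distance_matrix()
    pos = {tree.labels[t]: k for k, t in enumerate(tip_ids)}
    rescaled = rescale_reference(tree, model)
    acache = rescaled.tip_distance_matrix()

    rows = []
    records = []
    for b, thr in enumerate(thresholds):
        rng = np.random.default_rng(seed + 1000 * b)
        pool = list(tips)
        rng.shuffle(pool)
        max_rep = min(repeats, len(pool) // n_test)
        used_repeats = 0
        skipped = False
        for rep in range(max_rep):
            test = pool[rep * n_test:(rep + 1) * n_test]
            test_rows = np.array([pos[t] for t in test])
            others = [t for t in tips if t not in set(test)]
            other_rows = np.array([pos[t] for t in others])
            dmin = D[np.ix_(other_rows, test_rows)].min(axis=1)
            thinned = [others[i] for i in np.flatnonzero(dmin < thr)]
            if len(others) - len(thinned) < 2:
                skipped = True
                break
            mask = set(thinned)
            if predictor is None:
                preds = _default_predictor(tree, traits, model, test, mask,
                                           rescaled, (tip_ids, D), acache)
            else:
                preds = predictor(test, mask)
            for p in preds:
                records.append({
                    "bin": b, "threshold": thr, "repeat": rep, "query": p.query,
                    "true": traits[p.query], "point": p.point_estimate,
                    "confidence": p.confidence, "reliable": p.reliable,
                    "nstd": p.raw_nstd, "adjusted_nstd": p.adjusted_nstd,
                })
            used_repeats += 1
        if skipped or used_repeats == 0:
            warnings.warn(f"bin {b} (threshold {thr}) skipped: "
                          "fewer than 2 reference tips after thinning", stacklevel=2)
            continue
        rec = pd.DataFrame([r for r in records if r["bin"] == b])
        per_rep = rec.groupby("repeat").apply(_score_repeat, include_groups=False)
        mean = per_rep.mean()
        sem = per_rep.std(ddof=1) / np.sqrt(len(per_rep)) if len(per_rep) > 1 else per_rep.std()
        row = {"bin": b, "threshold": thr, "n_repeats": used_repeats,
               "mean_nstd": rec["nstd"].mean(),
               "mean_adjusted_nstd": rec["adjusted_nstd"].mean()}
        for k in ("r2", "accuracy", "precision", "recall"):
            row[k] = mean[k]
            row[f"ci_{k}"] = 1.96 * (sem[k] if np.isfinite(sem[k]) else 0.0)
        rows.append(row)
    return CVResult(summary=pd.DataFrame(rows), records=pd.DataFrame(records))


def _score_repeat(g: pd.DataFrame) -> pd.Series:
    true = g["true"].to_numpy(dtype=float)
    point = g["point"].to_numpy(dtype=float)
    correct = point == true
    reliable = g["reliable"].to_numpy(dtype=bool)
    ss_tot = np.sum((true - true.mean()) ** 2)
    r2 = 1.0 - np.sum((true - point) ** 2) / ss_tot if ss_tot > 0 \
        else float(np.all(correct))
    precision = np.mean(correct[reliable]) if reliable.any() else np.nan
    recall = np.mean(reliable[correct]) if correct.any() else np.nan
    return pd.Series({"r2": r2, "accuracy": correct.mean(),
                      "precision": precision, "recall": recall})


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

def _relative(table: pd.DataFrame) -> pd.DataFrame:
    tot = table.sum(axis=0)
    if (tot <= 0).any():
        bad = list(tot.index[tot <= 0])
        raise ValueError(f"samples with zero total abundance: {bad[:5]}")
    return table / tot


def distance_matrix(abundances: pd.DataFrame, metric: str,
                    tree: Phylogeny | None = None) -> DistanceMatrix:
    """Pairwise sample distances from an OTU x sample abundance table.

    ``bray_curtis`` and ``aitchison`` operate on per-sample relative
    abundances (Aitchison adds 0.5x the smallest nonzero relative abundance
    to zeros, renormalises, then takes Euclidean distance of CLR
    transforms); ``weighted_unifrac`` is the normalised weighted UniFrac and
    requires the phylogeny (delegated to scikit-bio).
    """
    rel = _relative(abundances)
    ids = list(rel.columns)
    if metric == "bray_curtis":
        D = squareform(pdist(rel.values.T, metric="braycurtis"))
    elif metric == "aitchison":
        X = rel.values.T.copy()
        nz = X[X > 0]
        if nz.size == 0:
            raise ValueError("empty table")
        X[X == 0] = 0.5 * nz.min()
        X = X / X.sum(axis=1, keepdims=True)
        clr = np.log(X) - np.log(X).mean(axis=1, keepdims=True)
        D = squareform(pdist(clr, metric="euclidean"))
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted UniFrac requires a tree")
        import io as _io

        from skbio import TreeNode
        from skbio.diversity import beta_diversity

        sk_tree = TreeNode.read(_io.StringIO(tree.to_newick()))
        # scikit-bio's unifrac drivers truncate counts to integers; the
        # normalised metric is per-sample scale-invariant, so integerise the
        # relative abundances at 1e-6 granularity
        X = np.round(rel.values.T * 1_000_000).astype(np.int64)
        dm = beta_diversity("weighted_unifrac", X, ids=ids,
                            taxa=list(rel.index), tree=sk_tree, normalized=True,
                            validate=True)
        D = dm.data
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return DistanceMatrix(data=D, ids=ids, metric=metric)


def pcoa(dm: DistanceMatrix, eig_floor: float = 1e-8):
    """Classical-scaling principal coordinates analysis.

    Delegates to scikit-bio's eigendecomposition of the double-centred Gower
    matrix; axes with eigenvalue <= ``eig_floor`` (including negative
    eigenvalues, which are reported) are dropped.

    Returns ``(coordinates DataFrame, retained eigenvalues, negative
    eigenvalues)``.
    """
    if len(dm.ids) < 3:
        raise ValueError("PCoA requires at least 3 samples")
    from skbio import DistanceMatrix as SkDM
    from skbio.stats.ordination import pcoa as sk_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = sk_pcoa(SkDM(dm.data, ids=dm.ids), method="eigh")
    eig = res.eigvals.values
    keep = eig > eig_floor
    coords = res.samples.values[:, keep]
    return (pd.DataFrame(coords, index=dm.ids,
                         columns=[f"PC{i + 1}" for i in range(keep.sum())]),
            eig[keep], eig[eig < 0])


def permanova(dm: DistanceMatrix, labels: dict[str, str] | pd.Series,
              n_permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F from squared distances).

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``;
    ``PVE = SS_between / SS_total``.  Deterministic under ``seed``.
    """
    grouping = np.array([labels[s] for s in dm.ids])
    groups, counts = np.unique(grouping, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    n = len(dm.ids)
    a = len(groups)
    D2 = dm.data ** 2

    def f_and_pve(gr: np.ndarray):
        ss_total = D2.sum() / (2.0 * n)
        ss_within = 0.0
        for g in groups:
            m = gr == g
            ss_within += D2[np.ix_(m, m)].sum() / (2.0 * m.sum())
        ss_between = ss_total - ss_within
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        return f, ss_between / ss_total

    f_obs, pve = f_and_pve(grouping)
    rng = np.random.default_rng(seed)
    perm_f = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_f[i] = f_and_pve(rng.permutation(grouping))[0]
    p = (1.0 + np.sum(perm_f >= f_obs)) / (1.0 + n_permutations)
    return PermanovaResult(pseudo_f=float(f_obs), pve=float(pve), p_value=float(p),
                           n_permutations=n_permutations, permuted_f=perm_f)


# --------------------------------------------------------------------------
# ordination shift
# --------------------------------------------------------------------------

def shift_reduction(
    true_tab: pd.DataFrame,
    gene_tab: pd.DataFrame,
    corrected_tab: pd.DataFrame,
    metric: str,
    tree: Phylogeny | None = None,
):
    """How much of the gene-abundance ordination shift correction removes.

    The true, gene and corrected versions of every sample are embedded in a
    single joint PCoA of the chosen metric; a version's shift is the
    Euclidean distance (over all retained axes) between its point and the
    true-abundance point of the same sample.  The reduction fraction is
    ``1 - mean shift(corrected) / mean shift(gene)``.

    Returns ``(per-sample DataFrame with shift_gene / shift_corrected,
    reduction fraction)``.
    """
    samples = list(true_tab.columns)
    if list(gene_tab.columns) != samples or list(corrected_tab.columns) != samples:
        raise ValueError("sample sets differ between tables")
    otus = true_tab.index
    if not (gene_tab.index.equals(otus) and corrected_tab.index.equals(otus)):
        raise ValueError("OTU sets differ between tables")

    joint = pd.concat(
        {
            "true": true_tab,
            "gene": gene_tab,
            "corrected": corrected_tab,
        },
        axis=1,
    )
    joint.columns = [f"{v}::{s}" for v, s in joint.columns]
    dm = distance_matrix(joint, metric, tree=tree)
    coords, _, _ = pcoa(dm)

    rows = []
    for s in samples:
        p_true = coords.loc[f"true::{s}"].values
        rows.append({
            "sample": s,
            "shift_gene": float(np.linalg.norm(coords.loc[f"gene::{s}"].values - p_true)),
            "shift_corrected": float(
                np.linalg.norm(coords.loc[f"corrected::{s}"].values - p_true)),
        })
    df = pd.DataFrame(rows).set_index("sample")
    mean_gene = df["shift_gene"].mean()
    reduction = 1.0 - df["shift_corrected"].mean() / mean_gene if mean_gene > 0 else 0.0
    return df, float(reduction)


# --------------------------------------------------------------------------
# calibration experiments
# --------------------------------------------------------------------------

def ci_coverage_experiment(
    tree: Phylogeny,
    traits: dict[str, float],
    model: HeterogeneousPEModel,
    thresholds=(0.002, 0.005, 0.010, 0.022, 0.046, 0.100, 0.215, 0.3),
    communities_per_threshold: int = 12,
    n_otus: int = 200,
    depth: int = 100_000,
    n_draws: int = 1000,
    seed: int = 0,
    extra_communities: int = 0,
) -> pd.DataFrame:
    """Coverage of true relative cell abundances by the Monte-Carlo 95% CIs.

    Per community: sample ``n_otus`` tips, draw log-normal cell abundances,
    sample multinomial gene reads at ``depth``, thin references at the NSTD
    threshold (every reference within the threshold of any community OTU is
    removed), predict integer-GCN PMFs for the community OTUs with the given
    model, draw ``n_draws`` GCN sets, correct, and record the fraction of
    true relative cell abundances inside their 95% CIs.  Returns one row per
    community (threshold, coverage).
    """
    from .correction import (CommunityTable, correct_counts,
                             coverage_probability, draw_gcn_sets)

    rng = np.random.default_rng(seed)
    tip_cache = tree.tip_distance_matrix()
    rescaled = rescale_reference(tree, model)
    adj_cache = rescaled.tip_distance_matrix()
    tips, D = tip_cache
    pos = {tree.labels[t]: k for k, t in enumerate(tips)}
    labels = sorted(tree.tip_labels)

    rows = []
    counts_per_thr = [communities_per_threshold] * len(thresholds)
    for k in range(extra_communities):
        counts_per_thr[k % len(thresholds)] += 1
    for thr, n_comm in zip(thresholds, counts_per_thr):
        for _ in range(n_comm):
            otus = sorted(rng.choice(labels, size=n_otus, replace=False))
            others = [t for t in labels if t not in set(otus)]
            orow = np.array([pos[o] for o in others])
            crow = np.array([pos[o] for o in otus])
            dmin = D[np.ix_(orow, crow)].min(axis=1)
            thinned = {others[i] for i in np.flatnonzero(dmin < thr)}
            if len(others) - len(thinned) < 2:
                warnings.warn(f"threshold {thr}: fewer than 2 references "
                              "remain; community skipped", stacklevel=2)
                continue
            preds = predict_holdout(tree, traits, model, otus,
                                    masked_tips=thinned, rescaled=rescaled,
                                    distance_cache=tip_cache,
                                    adjusted_cache=adj_cache)
            cells = rng.lognormal(0.0, 1.0, size=n_otus)
            p_true = cells / cells.sum()
            gcn = np.array([traits[o] for o in otus], dtype=float)
            g = p_true * gcn / np.dot(p_true, gcn)
            reads = rng.multinomial(int(depth), g)
            ct = CommunityTable(pd.DataFrame({"S1": reads}, index=pd.Index(otus)))
            draws = draw_gcn_sets({p.query: p.pmf for p in preds},
                                  n_draws=n_draws,
                                  seed=int(rng.integers(2 ** 31 - 1)))
            corr = correct_counts(ct, draws)
            ref = pd.DataFrame({"S1": p_true}, index=pd.Index(otus))
            rows.append({"threshold": thr,
                         "coverage": coverage_probability(corr, ref)})
    return pd.DataFrame(rows)


def precision_experiment(
    tree: Phylogeny,
    traits: dict[str, float],
    model: HeterogeneousPEModel,
    thresholds=(0.002, 0.005, 0.010, 0.022, 0.046, 0.100, 0.215, 0.464),
    repeats: int = 20,
    test_fraction: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validation precision of the 95%-confidence reliability flag.

    Thin wrapper over :func:`cross_validate` returning the per-bin summary;
    the headline number is the mean of the per-bin precisions (bins that
    never produce a reliable prediction contribute nothing).
    """
    cv = cross_validate(tree, traits, model, thresholds=thresholds,
                        repeats=repeats, test_fraction=test_fraction,
                        seed=seed)
    return cv.summary
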