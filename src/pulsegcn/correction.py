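"""Copy-number correction of read-count tables with Monte-Carlo uncertainty.

Gene read counts over-represent taxa with many gene copies.  Given per-OTU
integer copy-number PMFs (from :mod:`pulsegcn.predict`), this module draws
Monte-Carlo sets of copy numbers, divides read counts by them, and propagates
the prediction uncertainty into relative cell abundances: a median-based
point estimate, 95% confidence intervals from the 2.5/97.5% quantiles of the
per-draw relative abundances, and a per-sample support value for the most
abundant OTU (the empirical probability that it truly has the highest
corrected abundance, ties split equally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "CorrectedAbundanceTable",
    "draw_gcn_sets",
    "correct_counts",
    "coverage_probability",
    "theoretical_gene_abundance",
]


@dataclass
class CommunityTable:
    """OTU x sample read counts (non-negative integers)."""

    counts: pd.DataFrame  # index: OTU ids, columns: sample ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")

    @property
    def otus(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class CorrectedAbundanceTable:
    """Corrected relative cell abundances with 95% CIs and support values."""

    point: pd.DataFrame    # OTU x sample relative abundance (sums to 1/sample)
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    support: dict[str, float]      # sample -> support of most-abundant OTU
    top_otu: dict[str, str]        # sample -> identity of that OTU
    seed: int | None = None

    def __post_init__(self) -> None:
        colsum = self.point.sum(axis=0).values
        if not np.allclose(colsum, 1.0, atol=1e-9):
            raise ValueError("point abundances must sum to 1 per sample")


def draw_gcn_sets(
    predictions: dict[str, dict[int, float]],
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n_draws`` copy-number vectors from per-OTU integer PMFs.

    Returns a draws x OTU DataFrame; fully deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    otus = list(predictions)
    out = np.empty((n_draws, len(otus)), dtype=np.int64)
    for j, otu in enumerate(otus):
        pmf = predictions[otu]
        if pmf is None or len(pmf) == 0:
            raise ValueError(f"OTU without prediction: {otu!r}")
        ks = np.array(sorted(pmf), dtype=np.int64)
        ps = np.array([pmf[int(k)] for k in ks], dtype=float)
        ps = ps / ps.sum()
        out[:, j] = rng.choice(ks, size=n_draws, p=ps)
    return pd.DataFrame(out, columns=otus)


def correct_counts(counts: CommunityTable, draws: pd.DataFrame) -> CorrectedAbundanceTable:
    """Copy-number-correct a read-count table using Monte-Carlo GCN draws.

    Per draw, corrected cell counts are ``reads / GCN``, normalised within
    each sample; the point estimate is the per-OTU median corrected count
    renormalised across OTUs, and the 95% CI comes from the 2.5/97.5%
    quantiles of the per-draw relative abundances (the per-draw
    normalisation happens before taking quantiles).
    """
    missing = [o for o in counts.otus if o not in draws.columns]
    if missing:
        raise ValueError(f"draws missing for OTUs: {missing[:5]}")
    G = draws[counts.otus].to_numpy(dtype=float)  # (n_draws, n_otu)
    n_draws = G.shape[0]

    point = {}
    lo = {}
    hi = {}
    support: dict[str, float] = {}
    top: dict[str, str] = {}
    otus = counts.otus
    for sample in counts.samples:
        reads = counts.counts[sample].to_numpy(dtype=float)
        if reads.sum() <= 0:
            raise ValueError(f"sample {sample!r} has zero total reads")
        cell = reads[None, :] / G                       # per-draw corrected counts
        rel = cell / cell.sum(axis=1, keepdims=True)    # per-draw rel abundance
        med = np.median(cell, axis=0)
        point[sample] = med / med.sum()
        lo[sample] = np.quantile(rel, 0.025, axis=0)
        hi[sample] = np.quantile(rel, 0.975, axis=0)
        # support: empirical probability of having the highest cell abundance,
        # exact ties within a draw split equally
        mx = rel.max(axis=1, keepdims=True)
        is_top = rel >= mx
        weights = is_top / is_top.sum(axis=1, keepdims=True)
        freq = weights.sum(axis=0) / n_draws
        k = int(np.argmax(point[sample]))
        top[sample] = otus[k]
        support[sample] = float(freq[k])

    idx = pd.Index(otus)
    return CorrectedAbundanceTable(
        point=pd.DataFrame(point, index=idx),
        ci_low=pd.DataFrame(lo, index=idx),
        ci_high=pd.DataFrame(hi, index=idx),
        support=support,
        top_otu=top,
    )


def coverage_probability(
    corrected: CorrectedAbundanceTable,
    reference_abundances: pd.DataFrame,
) -> float:
    """Fraction of OTU x sample entries whose reference value falls inside
    the estimated CI (closed interval)."""
    ref = reference_abundances
    if ref.shape != corrected.point.shape:
        raise ValueError("shape mismatch between reference and corrected table")
    ref = ref.loc[corrected.point.index, corrected.point.columns]
    inside = (corrected.ci_low.values <= ref.values + 1e-12) & \
             (ref.values <= corrected.ci_high.values + 1e-12)
    return float(np.mean(inside))


def theoretical_gene_abundance(cell_fractions: np.ndarray, gcns: np.ndarray) -> np.ndarray:
    """Expected relative gene abundance ``g_i = p_i c_i / sum_j p_j c_j``.

    The fold change ``g_i / p_i`` equals ``c_i / ACN`` with community average
    copy number ``ACN = sum_j p_j c_j``: taxa with above-average copy number
    are over-represented in read counts, below-average under-represented.
    """
    p = np.asarray(cell_fractions, dtype=float)
    c = np.asarray(gcns, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("cell fractions must sum to 1")
    if (c < 1).any():
        raise ValueError("copy numbers must be >= 1")
    pc = p * c
    return pc / pc.sum()
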