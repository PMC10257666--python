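"""Maximum-likelihood fitting of trait-evolution models on a phylogeny.

The entry point is :class:`GCNEvolutionModel`, built from a rooted tree and a
tip trait table of integer gene copy numbers.  ``fit(family=...)`` estimates
one of four nested families by bounded quasi-Newton optimisation on
log-transformed parameters and returns a :class:`GCNFitResult` carrying the
estimates, log-likelihood, AIC and a ``summary()`` table:

``BM``
    Brownian motion, 1 parameter (``sigma2_bm``).
``BM+eps``
    Brownian motion plus tip white noise, 2 parameters.
``PE+eps``
    Homogeneous pulsed evolution plus tip white noise, 3 parameters
    (``lambda_``, ``sigma2_jump``, ``sigma2_eps``).
``het-PE+eps``
    Two-group pulsed evolution sharing one jump size: slowly- and
    regularly-evolving branch groups with separate jump frequencies and white
    noises, 5 parameters plus a fixed branch-group assignment.

The likelihood is evaluated over phylogenetically independent contrasts: each
raw contrast is scored by the compound-Poisson mixture with the Poisson
intensity summed along its two sister branches, while descendant-node
uncertainty and tip white noise propagate through the recursion as Gaussian
variance (exact for BM, moment-matched for pulsed evolution).
``fit_heterogeneous()`` classifies branches into the two rate groups by
alternating parameter refits with per-node reassignment to a likelihood fixed
point, and accepts the heterogeneous model only when its AIC beats the
homogeneous pulsed-evolution fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .contrasts import ContrastPlan, compute_pics
from .pulsed import BMParams, PEParams, log_pe_contrast_density
from .tree import Phylogeny

__all__ = [
    "SLOW",
    "REGULAR",
    "GroupAssignment",
    "HeterogeneousPEModel",
    "ModelFit",
    "GCNEvolutionModel",
    "GCNFitResult",
    "pe_loglik",
    "fit_model",
    "classify_rate_groups",
]

SLOW = "slow"
REGULAR = "regular"

FAMILIES = ("BM", "BM+eps", "PE+eps", "het-PE+eps")

_LOG_BOUNDS = (-30.0, 15.0)


class GroupAssignment:
    """Branch-group labels: each non-root node's label governs the branch
    above it ({"slow", "regular"}).  Internally a boolean array
    (True = regular)."""

    def __init__(self, tree: Phylogeny, regular: np.ndarray):
        self.tree = tree
        self.regular = np.asarray(regular, dtype=bool)
        if len(self.regular) != tree.n_nodes:
            raise ValueError("assignment length must equal node count")

    @classmethod
    def uniform(cls, tree: Phylogeny, group: str = REGULAR) -> "GroupAssignment":
        return cls(tree, np.full(tree.n_nodes, group == REGULAR))

    @classmethod
    def from_dict(cls, tree: Phylogeny, mapping: dict[str | int, str]) -> "GroupAssignment":
        reg = np.ones(tree.n_nodes, dtype=bool)
        for key, grp in mapping.items():
            node = tree.tip_id(key) if isinstance(key, str) else int(key)
            reg[node] = grp == REGULAR
        return cls(tree, reg)

    def group(self, node: int) -> str:
        return REGULAR if self.regular[node] else SLOW

    def counts(self) -> dict[str, int]:
        nonroot = np.ones(self.tree.n_nodes, dtype=bool)
        nonroot[self.tree.root] = False
        n_reg = int(np.sum(self.regular & nonroot))
        return {REGULAR: n_reg, SLOW: int(nonroot.sum()) - n_reg}

    def to_list(self) -> list[str]:
        return [REGULAR if r else SLOW for r in self.regular]

    def copy(self) -> "GroupAssignment":
        return GroupAssignment(self.tree, self.regular.copy())


def transfer_assignment(src_tree: Phylogeny, assignment: "GroupAssignment",
                        dst_tree: Phylogeny) -> "GroupAssignment":
    """Carry branch-group labels between two renderings of the same tree
    (e.g. a fitted reference tree and the jplace copy of it), matching
    branches by their descendant tip sets.  Unmatched branches (resolution
    differences) default to regular."""
    def tipsets(tree):
        out = {}
        below: dict[int, frozenset] = {}
        for node in tree.postorder:
            if tree.is_tip(node):
                below[node] = frozenset([tree.labels[node]])
            else:
                s = frozenset()
                for c in tree.children[node]:
                    s |= below[c]
                below[node] = s
            out[node] = below[node]
        return out

    src_sets = tipsets(src_tree)
    dst_sets = tipsets(dst_tree)
    by_set = {s: n for n, s in src_sets.items()}
    reg = np.ones(dst_tree.n_nodes, dtype=bool)
    for node, s in dst_sets.items():
        if node == dst_tree.root:
            continue
        match = by_set.get(s)
        if match is not None:
            reg[node] = assignment.regular[match]
    return GroupAssignment(dst_tree, reg)


@dataclass
class HeterogeneousPEModel:
    """Two-group pulsed-evolution model with a shared jump size."""

    sigma2_jump: float
    lambda_slow: float
    lambda_regular: float
    sigma2_eps_slow: float
    sigma2_eps_regular: float
    assignment: GroupAssignment

    def __post_init__(self) -> None:
        if self.lambda_regular < self.lambda_slow:
            raise ValueError("lambda_regular must be >= lambda_slow")

    @property
    def rate_ratio(self) -> float:
        """Slow-to-regular process-rate ratio, lambda_slow / lambda_regular
        (jump size is shared)."""
        return self.lambda_slow / self.lambda_regular

    def group_params(self, group: str) -> PEParams:
        if group == SLOW:
            return PEParams(self.lambda_slow, self.sigma2_jump, self.sigma2_eps_slow)
        return PEParams(self.lambda_regular, self.sigma2_jump, self.sigma2_eps_regular)

    def branch_arrays(self, tree: Phylogeny):
        """Per-node (lambda, process rate, tip white-noise) arrays."""
        reg = self.assignment.regular
        lam = np.where(reg, self.lambda_regular, self.lambda_slow)
        rate = lam * self.sigma2_jump
        eps = np.where(reg, self.sigma2_eps_regular, self.sigma2_eps_slow)
        return lam, rate, eps


@dataclass
class ModelFit:
    """A fitted model: parameters, log-likelihood and AIC."""

    family: str
    params: object  # PEParams | BMParams | HeterogeneousPEModel
    log_likelihood: float
    n_params: int
    converged: bool = True
    messages: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def _branch_arrays(tree, params, assignment):
    n = tree.n_nodes
    if isinstance(params, HeterogeneousPEModel):
        return params.branch_arrays(tree)
    if isinstance(params, PEParams):
        if assignment is None:
            lam = np.full(n, params.lambda_)
            eps = np.full(n, params.sigma2_eps)
        else:  # one PEParams applied per group is not supported; uniform only
            raise ValueError("pass a HeterogeneousPEModel for grouped parameters")
        return lam, lam * params.sigma2_jump, eps
    raise TypeError(f"unsupported params type: {type(params)!r}")


def pe_loglik(
    tree: Phylogeny,
    traits: dict[str, float],
    params: PEParams | HeterogeneousPEModel,
    assignment: GroupAssignment | None = None,
    plan: ContrastPlan | None = None,
) -> float:
    """Log-likelihood of tip traits under (possibly heterogeneous) pulsed
    evolution, evaluated over independent contrasts.

    Impossible data (a nonzero contrast over zero jump intensity with no
    Gaussian variance) yields ``-inf``.
    """
    lam, rate, eps = _branch_arrays(tree, params, assignment)
    s2j = params.sigma2_jump
    if plan is None:
        plan = ContrastPlan(tree, traits)
    dec = plan.decompose(rate, eps, lam)
    terms = log_pe_contrast_density(dec["d"], dec["pois"], s2j, dec["gauss_var"])
    return float(np.sum(terms))


def bm_loglik(
    tree: Phylogeny,
    traits: dict[str, float],
    params: BMParams,
    plan: ContrastPlan | None = None,
) -> float:
    """Gaussian contrast (restricted) log-likelihood under BM + tip noise.

    Exactly-zero contrasts are scored by the unit rounding-bin mass (the
    same integer-trait convention as the pulsed-evolution likelihood, so
    AIC comparisons across families stay commensurable); continuous data is
    unaffected since exact zeros have measure zero there.
    """
    from scipy.special import ndtr

    if plan is None:
        plan = ContrastPlan(tree, traits)
    dec = plan.decompose(params.sigma2_bm, params.sigma2_eps)
    var = dec["proc_var"] + dec["gauss_var"]
    d = dec["d"]
    out = np.empty_like(var)
    pos = var > 0
    zero = d == 0
    m = pos & ~zero
    out[m] = -0.5 * d[m] ** 2 / var[m] - 0.5 * np.log(2.0 * np.pi * var[m])
    m = pos & zero
    out[m] = np.log(2.0 * ndtr(0.5 / np.sqrt(var[m])) - 1.0)
    out[~pos] = np.where(zero[~pos], 0.0, -np.inf)
    return float(np.sum(out))


def _bm_closed_form(plan: ContrastPlan) -> ModelFit:
    """Closed-form ML for plain BM: contrast weights do not depend on the
    rate, so sigma2 = mean(d^2 / L) over positive contrast path lengths."""
    dec = plan.decompose(1.0, 0.0)
    d, L = dec["d"], dec["proc_var"]
    pos = L > 0
    if np.any(~pos & (d != 0)):
        return ModelFit(family="BM", params=BMParams(1e-300 + 1e-301, 0.0),
                        log_likelihood=-np.inf, n_params=1, converged=False,
                        messages=["nonzero contrast over zero path: BM impossible"])
    s2 = float(np.mean(d[pos] ** 2 / L[pos])) if pos.any() else 1e-12
    s2 = max(s2, 1e-12)
    ll = float(np.sum(-0.5 * d[pos] ** 2 / (s2 * L[pos])
                      - 0.5 * np.log(2.0 * np.pi * s2 * L[pos])))
    return ModelFit(family="BM", params=BMParams(s2, 0.0), log_likelihood=ll,
                    n_params=1)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _loglik_from_theta(tree, traits, family, theta, assignment, plan=None):
    p = np.exp(np.clip(theta, _LOG_BOUNDS[0], _LOG_BOUNDS[1]))
    if family == "BM":
        return bm_loglik(tree, traits, BMParams(p[0], 0.0), plan=plan)
    if family == "BM+eps":
        return bm_loglik(tree, traits, BMParams(p[0], p[1]), plan=plan)
    if family == "PE+eps":
        return pe_loglik(tree, traits, PEParams(p[0], p[1], p[2]), plan=plan)
    if family == "het-PE+eps":
        # theta: sigma2_jump, lambda_slow, lambda_regular, eps_slow, eps_regular
        lam_s, lam_r = min(p[1], p[2]), max(p[1], p[2])
        eps_s, eps_r = (p[3], p[4]) if p[1] <= p[2] else (p[4], p[3])
        model = HeterogeneousPEModel(p[0], lam_s, lam_r, eps_s, eps_r, assignment)
        return pe_loglik(tree, traits, model, plan=plan)
    raise ValueError(f"unknown family: {family!r}")


def _params_from_theta(family, theta, assignment):
    p = np.exp(np.clip(theta, _LOG_BOUNDS[0], _LOG_BOUNDS[1]))
    if family == "BM":
        return BMParams(p[0], 0.0)
    if family == "BM+eps":
        return BMParams(p[0], p[1])
    if family == "PE+eps":
        return PEParams(p[0], p[1], p[2])
    lam_s, lam_r = min(p[1], p[2]), max(p[1], p[2])
    eps_s, eps_r = (p[3], p[4]) if p[1] <= p[2] else (p[4], p[3])
    return HeterogeneousPEModel(p[0], lam_s, lam_r, eps_s, eps_r, assignment)


def _moment_start(tree, traits, family):
    """Moment-based central starting point in log-parameter space."""
    pics = compute_pics(tree, traits)
    vals = np.array([c.value for c in pics if not c.degenerate and np.isfinite(c.value)])
    paths = np.array([c.path_length for c in pics])
    s2 = max(float(np.mean(vals ** 2)), 1e-8) if len(vals) else 1e-4
    mean_path = max(float(np.mean(paths)), 1e-8)
    frac_nonzero = float(np.mean(np.abs([c.raw_difference for c in pics]) > 1e-12))
    lam0 = max(frac_nonzero, 0.02) / mean_path
    s2j0 = max(s2 / lam0, 1e-8)
    eps0 = max(0.05 * s2j0, 1e-4)
    if family == "BM":
        return np.log([s2])
    if family == "BM+eps":
        return np.log([s2, eps0])
    if family == "PE+eps":
        return np.log([lam0, s2j0, eps0])
    return np.log([s2j0, lam0 / 50.0, lam0, eps0 / 10.0, eps0])


def fit_model(
    tree: Phylogeny,
    traits: dict[str, float],
    model_family: str = "PE+eps",
    assignment: GroupAssignment | None = None,
    n_starts: int = 8,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model family.

    Bounded L-BFGS-B on log-transformed parameters with ``n_starts`` seeded
    restarts around a moment-based centre (or ``start``).  ``n_params`` counts
    free continuous parameters (1/2/3/5); a heterogeneous fit treats the
    branch-group assignment as fixed.
    """
    if model_family not in FAMILIES:
        raise ValueError(f"unknown model family: {model_family!r}")
    if model_family == "het-PE+eps" and assignment is None:
        raise ValueError("het-PE+eps requires a GroupAssignment")
    n_contrasts = tree.n_tips - 1
    msgs: list[str] = []
    if n_contrasts < 20:
        msgs.append(f"only {n_contrasts} contrasts; estimates may be unstable")
        warnings.warn(msgs[-1], stacklevel=2)

    plan = ContrastPlan(tree, traits)
    if model_family == "BM":
        # closed form is exact when no contrast is exactly zero (continuous
        # data); otherwise the zero-bin masses depend on the rate, so polish
        # the closed-form start numerically
        fit = _bm_closed_form(plan)
        dec = plan.decompose(1.0, 0.0)
        if not np.isfinite(fit.log_likelihood) or not np.any(dec["d"] == 0):
            fit.messages.extend(msgs)
            return fit
        start = np.log([max(fit.params.sigma2_bm, 1e-10)])

    center = np.asarray(start, dtype=float) if start is not None \
        else _moment_start(tree, traits, model_family)
    rng = np.random.default_rng(seed)
    k = len(center)

    def objective(theta):
        ll = _loglik_from_theta(tree, traits, model_family, theta, assignment, plan)
        return 1e12 if not np.isfinite(ll) else -ll

    # Screened multi-start: short runs from every start, full polish of the
    # best few.  Starts mix random log-space perturbations with deterministic
    # moves along the weakly identified (lambda, sigma2_jump) ridge: the
    # process rate lambda*sigma2_jump is well constrained long before the
    # frequency/size split is, so rate-preserving displacements explore the
    # direction plain restarts rarely reach.
    starts = [center]
    if model_family == "PE+eps":
        for f in (4.0, 2.0, 0.5, 0.25, 0.1):
            starts.append(center + np.array([-np.log(f), np.log(f), 0.0]))
    elif model_family == "het-PE+eps":
        for f in (4.0, 2.0, 0.5, 0.25, 0.1):
            starts.append(center + np.array([np.log(f), -np.log(f), -np.log(f),
                                             0.0, 0.0]))
    while len(starts) < max(1, n_starts):
        starts.append(center + rng.normal(0.0, 1.5, size=k))
    starts = starts[:max(1, n_starts)] if n_starts < len(starts) else starts

    best = None
    n_ok = 0
    screened = []
    for theta0 in starts:
        theta0 = np.clip(theta0, _LOG_BOUNDS[0] + 1, _LOG_BOUNDS[1] - 1)
        try:
            res = minimize(objective, theta0, method="L-BFGS-B",
                           bounds=[_LOG_BOUNDS] * k,
                           options={"maxiter": 30, "ftol": 1e-9})
        except Exception:
            continue
        if res.fun < 1e11:
            n_ok += 1
        screened.append(res)
    for res0 in sorted(screened, key=lambda r: r.fun)[:2]:
        if res0.fun >= 1e11:
            continue
        try:
            res = minimize(objective, res0.x, method="L-BFGS-B",
                           bounds=[_LOG_BOUNDS] * k,
                           options={"maxiter": 300, "ftol": 1e-10})
        except Exception:
            res = res0
        if best is None or res.fun < best.fun:
            best = res
    if best is None and screened:
        best = min(screened, key=lambda r: r.fun)
    if best is None or best.fun >= 1e11:
        raise RuntimeError(
            f"optimization failed for {model_family} after {n_starts} starts"
            + (f" (best partial objective {best.fun:.3g})" if best is not None else "")
        )
    # on likelihood-flat ridges prefer the parsimonious boundary: shrink each
    # parameter to its lower bound when the likelihood is indifferent
    theta = np.array(best.x, dtype=float)
    f_best = float(best.fun)
    for j in range(k):
        trial = theta.copy()
        trial[j] = _LOG_BOUNDS[0]
        f_trial = objective(trial)
        if f_trial <= f_best + 1e-9:
            theta, f_best = trial, min(f_best, f_trial)
    params = _params_from_theta(model_family, theta, assignment)
    n_params = {"BM": 1, "BM+eps": 2, "PE+eps": 3, "het-PE+eps": 5}[model_family]
    return ModelFit(family=model_family, params=params,
                    log_likelihood=-f_best, n_params=n_params,
                    converged=n_ok > 0, messages=msgs)


def select_by_aic(fits: list[ModelFit], tie_margin: float = 2.0) -> ModelFit:
    """Best fit by AIC; ties (within ``tie_margin``) resolve to the simpler
    model."""
    ordered = sorted(fits, key=lambda f: (f.n_params, f.aic))
    best = min(fits, key=lambda f: f.aic)
    for f in ordered:
        if f.aic <= best.aic + tie_margin:
            return f
    return best


# --------------------------------------------------------------------------
# rate-group classification
# --------------------------------------------------------------------------

def _subtree_local_rates(tree: Phylogeny, traits: dict[str, float],
                         min_tips: int = 10) -> np.ndarray:
    """Per-node local rate: mean squared standardised contrast over the
    smallest enclosing subtree with >= ``min_tips`` tips."""
    pics = compute_pics(tree, traits)
    sq = np.zeros(tree.n_nodes)
    cnt = np.zeros(tree.n_nodes)
    ntips = np.zeros(tree.n_nodes, dtype=int)
    by_node = {c.node: c for c in pics}
    for node in tree.postorder:
        if tree.is_tip(node):
            ntips[node] = 1
            continue
        for c in tree.children[node]:
            sq[node] += sq[c]
            cnt[node] += cnt[c]
            ntips[node] += ntips[c]
        c = by_node[node]
        if not c.degenerate and np.isfinite(c.value):
            sq[node] += c.value ** 2
            cnt[node] += 1

    rate = np.full(tree.n_nodes, np.nan)
    order = tree.postorder[::-1]  # preorder
    for node in order:
        if not tree.is_tip(node) and ntips[node] >= min_tips and cnt[node] > 0:
            rate[node] = sq[node] / cnt[node]
        elif node != tree.root:
            rate[node] = rate[tree.parent[node]]
    root_rate = sq[tree.root] / max(cnt[tree.root], 1)
    return np.where(np.isnan(rate), root_rate, rate)


def _antimode_threshold(log_rates: np.ndarray, min_separation: float = 1.0,
                        min_side_fraction: float = 0.08) -> float | None:
    """Split point of a bimodal 1-D sample of log10 local rates.

    The candidate split maximises the between-class variance (Otsu) subject
    to each side holding at least ``min_side_fraction`` of the sample (and
    two points); it is accepted only when the class means are at least
    ``min_separation`` decades apart.  The two-group jump-frequency ratios
    of interest are orders of magnitude, while the sampling spread of local
    rate estimates under a homogeneous model is a fraction of a decade, so
    the absolute-separation criterion cleanly distinguishes genuine
    bimodality from noise.  Returns None when no qualifying split exists.
    """
    x = np.sort(np.asarray(log_rates, dtype=float))
    n = len(x)
    lo = max(2, int(np.ceil(min_side_fraction * n)))
    if n < 2 * lo or np.ptp(x) < 1e-12:
        return None
    best_v, best_i = -np.inf, None
    for i in range(lo, n - lo + 1):
        v = i * (n - i) * (x[:i].mean() - x[i:].mean()) ** 2
        if v > best_v:
            best_v, best_i = v, i
    if best_i is None:
        return None
    sep = x[best_i:].mean() - x[:best_i].mean()
    if sep < min_separation:
        return None
    return float(0.5 * (x[best_i - 1] + x[best_i]))


def classify_rate_groups(
    tree: Phylogeny,
    traits: dict[str, float],
    n_starts: int = 8,
    seed: int = 0,
    max_iter: int = 50,
    min_clade_tips: int = 10,
    homogeneous_fit: ModelFit | None = None,
) -> tuple[HeterogeneousPEModel, ModelFit]:
    """Two-group rate-heterogeneity classification.

    1. Initialise branch groups by thresholding per-node local rates at the
       antimode of their log distribution.
    2. Alternate: refit the 5 shared/per-group parameters; reassign each
       internal node (its contrast, i.e. the two branches descending from
       it) to whichever group increases the total log-likelihood, using a
       vectorised local screen verified against the exact likelihood;
       iterate to a fixed point (cap ``max_iter``).
    3. Accept the heterogeneous model only if its AIC beats the homogeneous
       pulsed-evolution fit (ties resolve to the simpler model); otherwise a
       single-group model is returned with ``fit.messages`` noting rejection.
    """
    hom = homogeneous_fit or fit_model(tree, traits, "PE+eps", n_starts=n_starts, seed=seed)

    rates = _subtree_local_rates(tree, traits, min_tips=min_clade_tips)
    log_rates = np.log10(rates + 0.1)  # small offset keeps zero rates finite
    sweeper = _CladeGroupSweeper(tree, traits, min_clade_tips)
    thr = _antimode_threshold(log_rates[sweeper.minimal_decision_nodes])
    if thr is None:
        # unimodal local-rate distribution: no heterogeneity structure
        pe = hom.params
        uni = GroupAssignment.uniform(tree)
        collapsed = HeterogeneousPEModel(pe.sigma2_jump, pe.lambda_, pe.lambda_,
                                         pe.sigma2_eps, pe.sigma2_eps, uni)
        rej = ModelFit(family="PE+eps", params=collapsed,
                       log_likelihood=hom.log_likelihood, n_params=hom.n_params,
                       converged=hom.converged,
                       messages=[*hom.messages,
                                 "heterogeneous model rejected: local-rate "
                                 "distribution is unimodal"])
        return collapsed, rej
    g_reg = {int(n): bool(log_rates[n] > thr) for n in sweeper.decision_nodes}
    if all(g_reg.values()) or not any(g_reg.values()):
        med = float(np.median(log_rates[sweeper.decision_nodes]))
        g_reg = {int(n): bool(log_rates[n] >= med) for n in sweeper.decision_nodes}
    sweeper.g_reg = g_reg

    pe = hom.params
    start = np.log(np.maximum([pe.sigma2_jump, pe.lambda_ / 50.0, pe.lambda_,
                               pe.sigma2_eps / 10.0, pe.sigma2_eps], 1e-12))
    fit = fit_model(tree, traits, "het-PE+eps", assignment=sweeper.assignment(),
                    n_starts=n_starts, seed=seed, start=start)
    best = fit
    converged = False
    iteration = 0
    for outer in range(max_iter):
        model: HeterogeneousPEModel = fit.params
        changed_any = False
        while iteration < max_iter and sweeper.sweep(model):
            changed_any = True
            iteration += 1
        if not changed_any:
            converged = True
            break
        warm = np.log(np.maximum([model.sigma2_jump, model.lambda_slow,
                                  model.lambda_regular, model.sigma2_eps_slow,
                                  model.sigma2_eps_regular], 1e-12))
        fit = fit_model(tree, traits, "het-PE+eps", assignment=sweeper.assignment(),
                        n_starts=6, seed=seed + outer + 1, start=warm)
        if fit.log_likelihood > best.log_likelihood:
            best = fit
        if iteration >= max_iter:
            break
    fit = best
    if not converged:
        fit.messages.append("group reassignment did not reach a fixed point")
        warnings.warn(fit.messages[-1], stacklevel=2)

    if fit.aic < hom.aic - 1e-9 and not (hom.aic - fit.aic < 2.0):
        return fit.params, fit
    # heterogeneous model rejected: collapse to a single regular group
    uni = GroupAssignment.uniform(tree)
    collapsed = HeterogeneousPEModel(pe.sigma2_jump, pe.lambda_, pe.lambda_,
                                     pe.sigma2_eps, pe.sigma2_eps, uni)
    rej = ModelFit(family="PE+eps", params=collapsed,
                   log_likelihood=hom.log_likelihood, n_params=hom.n_params,
                   converged=hom.converged,
                   messages=[*hom.messages, "heterogeneous model rejected by AIC"])
    return collapsed, rej


class _CladeGroupSweeper:
    """Clade-granular reassignment machinery.

    Group labels live on *decision nodes* — internal nodes with at least
    ``min_clade_tips`` descendant tips (the same size floor as the local-rate
    screen); every other branch inherits the label of its nearest decision
    ancestor.  This matches the clade-structured nature of rate
    heterogeneity and prevents single stasis contrasts (which individually
    always lean slow) from fragmenting the assignment.  Each sweep flips one
    decision node at a time, accepting exactly those flips that increase the
    total log-likelihood.
    """

    def __init__(self, tree: Phylogeny, traits: dict[str, float],
                 min_clade_tips: int = 10):
        self.tree = tree
        self.traits = traits
        self.plan = ContrastPlan(tree, traits)
        ntips = np.zeros(tree.n_nodes, dtype=int)
        for node in tree.postorder:
            ntips[node] = 1 if tree.is_tip(node) else \
                sum(ntips[c] for c in tree.children[node])
        self.decision_nodes = np.array(
            [n for n in range(tree.n_nodes)
             if not tree.is_tip(n) and (ntips[n] >= min_clade_tips or n == tree.root)],
            dtype=int)
        dec = set(int(n) for n in self.decision_nodes)
        # minimal decision nodes: the genus-like layer (no decision-node
        # descendant); ancestors of these mix groups and blur rate modes
        has_dec_desc = set()
        for n in dec:
            p = int(tree.parent[n])
            while p != -1:
                if p in dec:
                    has_dec_desc.add(p)
                p = int(tree.parent[p])
        self.minimal_decision_nodes = np.array(
            sorted(dec - has_dec_desc), dtype=int)
        dec_set = set(int(n) for n in self.decision_nodes)
        # nearest decision ancestor-or-self per internal node (preorder)
        self.dec_of: dict[int, int] = {}
        for node in tree.postorder[::-1]:
            if tree.is_tip(node):
                continue
            if node in dec_set or node == tree.root:
                self.dec_of[node] = node
            else:
                self.dec_of[node] = self.dec_of[int(tree.parent[node])]
        self.g_reg: dict[int, bool] = {int(n): True for n in self.decision_nodes}

    def assignment(self) -> GroupAssignment:
        reg = np.ones(self.tree.n_nodes, dtype=bool)
        for node, dec in self.dec_of.items():
            g = self.g_reg[dec]
            for c in self.tree.children[node]:
                reg[c] = g
            if node == self.tree.root:
                reg[node] = g
        return GroupAssignment(self.tree, reg)

    def _loglik(self, model: HeterogeneousPEModel) -> float:
        return pe_loglik(self.tree, self.traits, model, plan=self.plan)

    #: minimum log-likelihood gain to accept a label flip: each decision-node
    #: label is a binary model choice, so gains below the AIC-equivalent cost
    #: of one parameter are treated as noise (guards against the selection
    #: bias that would otherwise let the two-group model always win on
    #: homogeneous data)
    FLIP_GAIN = 2.0

    def sweep(self, model: HeterogeneousPEModel) -> bool:
        """One pass over the decision nodes; mutates ``model.assignment`` in
        place.  Returns True if any label changed."""
        changed = False
        model.assignment.regular[:] = self.assignment().regular
        ll = self._loglik(model)
        for node in self.decision_nodes:
            node = int(node)
            self.g_reg[node] = not self.g_reg[node]
            model.assignment.regular[:] = self.assignment().regular
            alt = self._loglik(model)
            if alt > ll + self.FLIP_GAIN:
                ll = alt
                changed = True
            else:
                self.g_reg[node] = not self.g_reg[node]
        model.assignment.regular[:] = self.assignment().regular
        return changed


# --------------------------------------------------------------------------
# model object (statsmodels-style surface)
# --------------------------------------------------------------------------

class GCNEvolutionModel:
    """Gene-copy-number evolution model bound to a tree and trait table.

    Parameters
    ----------
    tree
        Rooted :class:`~pulsegcn.tree.Phylogeny` with branch lengths in
        substitutions/site.
    traits
        Mapping tip label -> integer copy number (>= 1).
    """

    def __init__(self, tree: Phylogeny, traits: dict[str, int]):
        self.tree = tree
        self.traits = {str(k): float(v) for k, v in traits.items()}
        tips = set(tree.tip_labels)
        extra = set(self.traits) - tips
        if extra:
            raise ValueError(f"traits for non-tip labels: {sorted(extra)[:5]}")
        bad = [k for k, v in self.traits.items() if v < 1]
        if bad:
            raise ValueError(f"copy numbers must be >= 1 (offending tips: {bad[:5]})")

    @classmethod
    def from_files(cls, newick_path: str, traits_path: str) -> "GCNEvolutionModel":
        from .io import read_traits
        from .tree import parse_tree

        with open(newick_path) as fh:
            tree = parse_tree(fh.read())
        return cls(tree, read_traits(traits_path))

    @classmethod
    def from_dataframe(cls, tree: Phylogeny, df) -> "GCNEvolutionModel":
        """Build from a DataFrame with columns ``label`` and ``gcn``."""
        return cls(tree, dict(zip(df["label"].astype(str), df["gcn"])))

    def loglike(self, params, assignment: GroupAssignment | None = None) -> float:
        if isinstance(params, BMParams):
            return bm_loglik(self.tree, self.traits, params)
        return pe_loglik(self.tree, self.traits, params, assignment)

    def fit(self, family: str = "PE+eps", n_starts: int = 8, seed: int = 0,
            assignment: GroupAssignment | None = None) -> "GCNFitResult":
        fit = fit_model(self.tree, self.traits, family, assignment=assignment,
                        n_starts=n_starts, seed=seed)
        return GCNFitResult(self, fit)

    def fit_heterogeneous(self, n_starts: int = 8, seed: int = 0,
                          max_iter: int = 50) -> "GCNFitResult":
        model, fit = classify_rate_groups(self.tree, self.traits,
                                          n_starts=n_starts, seed=seed,
                                          max_iter=max_iter)
        return GCNFitResult(self, fit)

    def compare_families(self, families=("BM", "BM+eps", "PE+eps"),
                         n_starts: int = 8, seed: int = 0) -> "GCNFitResult":
        """Fit several families and return the AIC-best (ties -> simpler)."""
        fits = [fit_model(self.tree, self.traits, f, n_starts=n_starts, seed=seed)
                for f in families]
        return GCNFitResult(self, select_by_aic(fits), candidates=fits)


class GCNFitResult:
    """Results wrapper: estimates, AIC, summary table and downstream verbs."""

    def __init__(self, model: GCNEvolutionModel, fit: ModelFit,
                 candidates: list[ModelFit] | None = None):
        self.model = model
        self.fit = fit
        self.candidates = candidates

    # -- statsmodels-ish accessors
    @property
    def params(self):
        return self.fit.params

    @property
    def llf(self) -> float:
        return self.fit.log_likelihood

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def family(self) -> str:
        return self.fit.family

    def het_model(self) -> HeterogeneousPEModel:
        """The fitted parameters as a heterogeneous model (single-group
        families are promoted to a uniform 'regular' assignment)."""
        p = self.fit.params
        if isinstance(p, HeterogeneousPEModel):
            return p
        uni = GroupAssignment.uniform(self.model.tree)
        if isinstance(p, PEParams):
            return HeterogeneousPEModel(p.sigma2_jump, p.lambda_, p.lambda_,
                                        p.sigma2_eps, p.sigma2_eps, uni)
        raise TypeError("BM fits cannot be promoted to a pulsed-evolution model")

    def rescaled_tree(self) -> Phylogeny:
        from .predict import rescale_reference

        return rescale_reference(self.model.tree, self.het_model())

    def predict_holdout(self, query_tips, masked_tips=None, **kw):
        from .predict import predict_holdout

        return predict_holdout(self.model.tree, self.model.traits, self.het_model(),
                               query_tips, masked_tips=masked_tips, **kw)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Gene copy number evolution model",
            "=" * 46,
            f"family:          {f.family}",
            f"n tips:          {self.model.tree.n_tips}",
            f"n contrasts:     {self.model.tree.n_tips - 1}",
            f"log-likelihood:  {f.log_likelihood:.4f}",
            f"n params:        {f.n_params}",
            f"AIC:             {f.aic:.4f}",
        ]
        p = f.params
        if isinstance(p, BMParams):
            lines += [f"sigma2_bm:       {p.sigma2_bm:.6g}",
                      f"sigma2_eps:      {p.sigma2_eps:.6g}"]
        elif isinstance(p, PEParams):
            lines += [f"lambda:          {p.lambda_:.6g}",
                      f"sigma2_jump:     {p.sigma2_jump:.6g}",
                      f"sigma2_eps:      {p.sigma2_eps:.6g}"]
        elif isinstance(p, HeterogeneousPEModel):
            counts = p.assignment.counts()
            lines += [
                f"sigma2_jump:     {p.sigma2_jump:.6g}",
                f"lambda_slow:     {p.lambda_slow:.6g}",
                f"lambda_regular:  {p.lambda_regular:.6g}",
                f"sigma2_eps_slow: {p.sigma2_eps_slow:.6g}",
                f"sigma2_eps_reg:  {p.sigma2_eps_regular:.6g}",
                f"branches slow/regular: {counts[SLOW]}/{counts[REGULAR]}",
                f"jump-frequency ratio (reg/slow): "
                f"{p.lambda_regular / max(p.lambda_slow, 1e-300):.4g}",
            ]
        for m in f.messages:
            lines.append(f"note: {m}")
        if self.candidates:
            lines.append("-" * 46)
            for c in sorted(self.candidates, key=lambda x: x.aic):
                lines.append(f"  AIC[{c.family:>10s}] = {c.aic:.2f}")
        return "\n".join(lines)

    # -- serialization
    def to_json(self) -> str:
        f = self.fit
        p = f.params
        d: dict = {"family": f.family, "log_likelihood": f.log_likelihood,
                   "n_params": f.n_params, "aic": f.aic}
        if isinstance(p, BMParams):
            d["params"] = {"sigma2_bm": p.sigma2_bm, "sigma2_eps": p.sigma2_eps}
        elif isinstance(p, PEParams):
            d["params"] = {"lambda": p.lambda_, "sigma2_jump": p.sigma2_jump,
                           "sigma2_eps": p.sigma2_eps}
        else:
            d["params"] = {
                "sigma2_jump": p.sigma2_jump,
                "lambda_slow": p.lambda_slow, "lambda_regular": p.lambda_regular,
                "sigma2_eps_slow": p.sigma2_eps_slow,
                "sigma2_eps_regular": p.sigma2_eps_regular,
            }
            d["assignment"] = p.assignment.to_list()
        return json.dumps(d, indent=1)
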