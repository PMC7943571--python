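"""Variable-rate Brownian-motion inference by reversible-jump MCMC.

Model: traits (principal components, assumed independent) evolve by
Brownian motion on a shared tree whose branch lengths are multiplied by
effective rate scalars. A rate configuration is a set of scalars, each
attached to a single branch ("branch" kind) or to a whole clade including
its stem ("node" kind); the effective rate of a branch is the product of
all scalars whose scope covers it. Each trait has its own base rate σ²_j.

Inference: reversible-jump MCMC over the number, location, and magnitude
of scalars. Priors: scalar count ~ Poisson(λ=1) with locations uniform
among unoccupied branch/node positions; scalar values log-uniform on
[1/100, 100]; base rates inverse-gamma (conjugate, updated by Gibbs). The
per-trait likelihood is evaluated by Felsenstein pruning with the root at
its GLS estimate. Marginal likelihoods for variable- vs equal-rate model
comparison come from a stepping-stone (power-posterior) sampler; Bayes
factors are reported as 2·Δ(log marginal likelihood).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import Phylogeny, TreeArrays, tree_arrays

__all__ = [
    "ChainSettings",
    "Chain",
    "rjmcmc_rates",
    "bm_profile_loglik",
    "stepping_stone",
    "bayes_factor",
    "detect_shifts",
    "branch_rate_table",
    "effective_sample_size",
    "rate_variance_test",
    "rate_level_test",
    "VarianceTestResult",
]


# ---------------------------------------------------------------------------
# likelihood


def _prune(ta: TreeArrays, elen: np.ndarray, Y: np.ndarray):
    """Felsenstein pruning for independent-trait BM with profiled root.

    Returns ``(logdet, ss, root_mean)`` where, with unit trait variance,
    ``log|C| = logdet`` and ``ss[j]`` is the GLS sum of squares of trait j.
    """
    n, p = Y.shape
    x = {i: Y[i].copy() for i in range(n)}
    v = {i: float(elen[i]) for i in range(n)}
    logdet = 0.0
    ss = np.zeros(p)
    for node in ta.postorder:
        kids = ta.children[node]
        if not kids:
            continue
        xk, vk = x[kids[0]], v[kids[0]]
        for c in kids[1:]:
            xc, vc = x[c], v[c]
            tot = vk + vc
            logdet += math.log(tot)
            d = xk - xc
            ss += d * d / tot
            xk = (vc * xk + vk * xc) / tot
            vk = vk * vc / tot
        x[node] = xk
        v[node] = vk + float(elen[node])
    root = ta.root
    # root edge length is 0 by construction; v[root] is the GLS root variance
    logdet += math.log(v[root])
    return logdet, ss, x[root]


def bm_profile_loglik(
    phy_or_ta: Phylogeny | TreeArrays,
    Y: np.ndarray,
    sigma2: np.ndarray | float = 1.0,
    edge_rates: np.ndarray | None = None,
) -> float:
    """Log-likelihood of independent-trait BM with the root profiled out.

    ``logL = Σ_j −½ (N log(2π σ²_j) + log|C_r| + SS_j/σ²_j)`` where ``C_r``
    is the tip covariance of the rate-scaled tree.
    """
    ta = phy_or_ta if isinstance(phy_or_ta, TreeArrays) else tree_arrays(phy_or_ta)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != ta.n_tips:
        Y = Y.T
    n, p = Y.shape
    elen = ta.length * (edge_rates if edge_rates is not None else 1.0)
    logdet, ss, _ = _prune(ta, elen, Y)
    s2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (p,))
    return float(
        -0.5 * np.sum(n * np.log(2 * np.pi * s2) + logdet + ss / s2)
    )


# ---------------------------------------------------------------------------
# chain machinery


@dataclass
class ChainSettings:
    """Desk-scale defaults; the scalar prior and kernel are declared, not
    inherited from any external implementation."""

    iterations: int = 500_000
    burnin: float = 0.2
    thinning: int = 100
    poisson_lambda: float = 1.0
    scalar_log_bound: float = math.log(100.0)  # log-uniform on [1/100, 100]
    proposal_sd: float = 0.35
    ig_alpha: float = 2.0
    ig_beta: np.ndarray | float | None = None  # default: per-trait empirical
    p_add: float = 0.2
    p_remove: float = 0.2
    p_perturb: float = 0.15
    p_relocate: float = 0.1
    p_merge_split: float = 0.1  # split evenly between merge and split
    split_sd: float = 0.5
    # remainder: Gibbs base-rate update


@dataclass
class Chain:
    """Thinned post-burn-in posterior sample of the rate model."""

    ta: TreeArrays
    settings: ChainSettings
    seed: int | None
    loglik: np.ndarray
    n_scalars: np.ndarray
    scalars: list[dict]  # per sample: {(kind, node_index): value}
    base_rates: np.ndarray  # samples × traits
    edge_log_rates: np.ndarray  # samples × nodes (log effective rate per edge)
    acceptance: dict[str, float]

    @property
    def n_samples(self) -> int:
        return len(self.loglik)

    def location_label(self, node: int) -> str:
        if node < self.ta.n_tips:
            return self.ta.tip_labels[node]
        return f"node{node}"

    def to_frame(self) -> pd.DataFrame:
        """Tab-separated-friendly trace log (one row per retained sample)."""
        df = pd.DataFrame(
            {"loglik": self.loglik, "n_scalars": self.n_scalars}
        )
        for j in range(self.base_rates.shape[1]):
            df[f"sigma2_{j+1}"] = self.base_rates[:, j]
        return df


def _init_sigma2(ta: TreeArrays, Y: np.ndarray) -> np.ndarray:
    logdet, ss, _ = _prune(ta, ta.length, Y)
    return ss / ta.n_tips


def rjmcmc_rates(
    Y_pcs: np.ndarray | pd.DataFrame,
    phy: Phylogeny,
    settings: ChainSettings | None = None,
    seed: int | None = None,
    power: float = 1.0,
    allow_scalars: bool = True,
) -> Chain:
    """Sample the variable-rates model by reversible-jump MCMC.

    ``Y_pcs`` is a species × retained-PCs matrix (rows ordered as the
    tree's tips when a bare array, or matched by index for a DataFrame).
    ``power`` tempers the likelihood (used by the stepping-stone sampler);
    ``allow_scalars=False`` constrains the chain to the equal-rates model.
    Returns the thinned post-burn-in chain.
    """
    settings = settings or ChainSettings()
    if isinstance(Y_pcs, pd.DataFrame):
        ta = tree_arrays(phy, tip_order=[str(i) for i in Y_pcs.index])
        Y = Y_pcs.to_numpy(dtype=float)
    else:
        ta = tree_arrays(phy)
        Y = np.atleast_2d(np.asarray(Y_pcs, dtype=float))
        if Y.shape[0] != ta.n_tips:
            raise ValueError("row count does not match tip count")
    n, p = Y.shape
    if p > 1:
        cc = np.corrcoef(Y, rowvar=False)
        off = np.abs(cc[np.triu_indices(p, k=1)])
        if off.max() > 0.01:
            warnings.warn(
                f"trait columns correlate up to {off.max():.3f}; the model "
                "assumes orthogonal (PC) traits",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    L = settings.scalar_log_bound
    lam = settings.poisson_lambda
    a0 = settings.ig_alpha
    if settings.ig_beta is None:
        b0 = (a0 - 1.0) * _init_sigma2(ta, Y) if a0 > 1 else _init_sigma2(ta, Y)
    else:
        b0 = np.broadcast_to(np.asarray(settings.ig_beta, dtype=float), (p,)).copy()
    b0 = np.maximum(b0, 1e-12)

    root = ta.root
    branch_locs = [("branch", int(v)) for v in range(ta.n_nodes) if v != root]
    node_locs = [
        ("node", int(v))
        for v in range(ta.n_tips, ta.n_nodes)
        if v != root
    ]
    all_locs = branch_locs + node_locs
    clade_cache = {v: np.asarray(ta.clade_edges(v)) for v in range(ta.n_nodes)}

    def loc_edges(loc) -> np.ndarray:
        kind, v = loc
        return np.asarray([v]) if kind == "branch" else clade_cache[v]

    # state
    scalars: dict[tuple, float] = {}
    log_edge = np.zeros(ta.n_nodes)  # log effective rate per edge (above node)
    sigma2 = _init_sigma2(ta, Y)
    sigma2 = np.maximum(sigma2, 1e-12)

    def components() -> tuple[float, np.ndarray]:
        elen = ta.length * np.exp(log_edge)
        logdet, ss, _ = _prune(ta, elen, Y)
        return logdet, ss

    def loglik_from(logdet: float, ss: np.ndarray, s2: np.ndarray) -> float:
        return float(-0.5 * np.sum(n * np.log(2 * np.pi * s2) + logdet + ss / s2))

    logdet, ss = components()
    cur = loglik_from(logdet, ss, sigma2)
    if not np.isfinite(cur):
        raise FloatingPointError(f"non-finite starting likelihood; state: {sigma2}")

    total = settings.iterations
    burn = int(settings.burnin * total)
    thin = settings.thinning
    keep = max((total - burn) // thin, 1)
    out_logl = np.empty(keep)
    out_k = np.empty(keep, dtype=np.int64)
    out_scalars: list[dict] = []
    out_sigma = np.empty((keep, p))
    out_edges = np.empty((keep, ta.n_nodes))
    n_kept = 0
    moves = ("add", "remove", "perturb", "relocate", "mergesplit")
    props = {m: 0 for m in moves}
    accs = {m: 0 for m in moves}
    pa, pr, pp = settings.p_add, settings.p_remove, settings.p_perturb
    pl, pm = settings.p_relocate, settings.p_merge_split
    if not allow_scalars:
        pa = pr = pp = pl = pm = 0.0
    n_loc = len(all_locs)

    def covering_loc(v: int) -> tuple:
        """The scalar location whose scope is exactly node v's clade."""
        return ("branch", int(v)) if v < ta.n_tips else ("node", int(v))

    def mergeable_nodes() -> list[int]:
        out = []
        for v in range(ta.n_tips, ta.n_nodes):
            if v == root or ("node", v) in scalars:
                continue
            kids = ta.children[v]
            if len(kids) == 2 and all(covering_loc(c) in scalars for c in kids):
                out.append(v)
        return out

    def splittable_nodes() -> list[int]:
        out = []
        for (kind, v), _ in list(scalars.items()):
            if kind != "node":
                continue
            kids = ta.children[v]
            if len(kids) == 2 and all(covering_loc(c) not in scalars for c in kids):
                out.append(v)
        return out

    for it in range(total):
        u = rng.random()
        if u < pa:
            props["add"] += 1
            free = [l for l in all_locs if l not in scalars]
            if free:
                loc = free[rng.integers(len(free))]
                val = math.exp(rng.uniform(-L, L))
                k = len(scalars)
                edges = loc_edges(loc)
                log_edge[edges] += math.log(val)
                nd2, ss2 = components()
                new = loglik_from(nd2, ss2, sigma2)
                logA = power * (new - cur) + math.log(lam / (k + 1))
                if math.log(rng.random() + 1e-300) < logA:
                    scalars[loc] = val
                    cur, logdet, ss = new, nd2, ss2
                    accs["add"] += 1
                else:
                    log_edge[edges] -= math.log(val)
        elif u < pa + pr:
            props["remove"] += 1
            if scalars:
                locs = list(scalars)
                loc = locs[rng.integers(len(locs))]
                val = scalars[loc]
                k = len(scalars)
                edges = loc_edges(loc)
                log_edge[edges] -= math.log(val)
                nd2, ss2 = components()
                new = loglik_from(nd2, ss2, sigma2)
                logA = power * (new - cur) + math.log(k / lam)
                if math.log(rng.random() + 1e-300) < logA:
                    del scalars[loc]
                    cur, logdet, ss = new, nd2, ss2
                    accs["remove"] += 1
                else:
                    log_edge[edges] += math.log(val)
        elif u < pa + pr + pp:
            props["perturb"] += 1
            if scalars:
                locs = list(scalars)
                loc = locs[rng.integers(len(locs))]
                old = scalars[loc]
                lu = math.log(old) + rng.normal(0, settings.proposal_sd)
                if abs(lu) <= L:
                    val = math.exp(lu)
                    edges = loc_edges(loc)
                    log_edge[edges] += lu - math.log(old)
                    nd2, ss2 = components()
                    new = loglik_from(nd2, ss2, sigma2)
                    if math.log(rng.random() + 1e-300) < power * (new - cur):
                        scalars[loc] = val
                        cur, logdet, ss = new, nd2, ss2
                        accs["perturb"] += 1
                    else:
                        log_edge[edges] -= lu - math.log(old)
        elif u < pa + pr + pp + pl:
            # relocate a scalar (value kept) to a uniformly chosen free
            # location; symmetric proposal
            props["relocate"] += 1
            if scalars:
                locs = list(scalars)
                loc = locs[rng.integers(len(locs))]
                free = [l for l in all_locs if l not in scalars]
                if free:
                    dest = free[rng.integers(len(free))]
                    val = scalars[loc]
                    lv = math.log(val)
                    log_edge[loc_edges(loc)] -= lv
                    log_edge[loc_edges(dest)] += lv
                    nd2, ss2 = components()
                    new = loglik_from(nd2, ss2, sigma2)
                    if math.log(rng.random() + 1e-300) < power * (new - cur):
                        del scalars[loc]
                        scalars[dest] = val
                        cur, logdet, ss = new, nd2, ss2
                        accs["relocate"] += 1
                    else:
                        log_edge[loc_edges(dest)] -= lv
                        log_edge[loc_edges(loc)] += lv
        elif u < pa + pr + pp + pl + pm:
            # reversible-jump merge/split: two covering scalars on sibling
            # clades <-> one scalar on their parent clade (log-space
            # geometric mean; the half-difference is the auxiliary)
            props["mergesplit"] += 1
            s_sd = settings.split_sd
            if rng.random() < 0.5:
                cand = mergeable_nodes()
                if cand:
                    k = len(scalars)
                    v = cand[rng.integers(len(cand))]
                    c1, c2 = ta.children[v]
                    lc1, lc2 = covering_loc(c1), covering_loc(c2)
                    l1, l2 = math.log(scalars[lc1]), math.log(scalars[lc2])
                    lm, du = (l1 + l2) / 2, (l1 - l2) / 2
                    n_m_old = len(cand)
                    log_edge[loc_edges(lc1)] -= l1
                    log_edge[loc_edges(lc2)] -= l2
                    newloc = ("node", int(v))
                    log_edge[loc_edges(newloc)] += lm
                    del scalars[lc1], scalars[lc2]
                    scalars[newloc] = math.exp(lm)
                    nd2, ss2 = components()
                    new = loglik_from(nd2, ss2, sigma2)
                    n_s_new = len(splittable_nodes())
                    logA = (
                        power * (new - cur)
                        - math.log(lam)
                        + math.log(n_loc - k + 1)
                        + math.log(2 * L)
                        - math.log(2.0)
                        - math.log(max(n_s_new, 1))
                        + math.log(n_m_old)
                        + stats.norm.logpdf(du, scale=s_sd)
                    )
                    if math.log(rng.random() + 1e-300) < logA:
                        cur, logdet, ss = new, nd2, ss2
                        accs["mergesplit"] += 1
                    else:
                        del scalars[newloc]
                        log_edge[loc_edges(newloc)] -= lm
                        scalars[lc1] = math.exp(l1)
                        scalars[lc2] = math.exp(l2)
                        log_edge[loc_edges(lc1)] += l1
                        log_edge[loc_edges(lc2)] += l2
            else:
                cand = splittable_nodes()
                if cand:
                    k = len(scalars)
                    v = cand[rng.integers(len(cand))]
                    oldloc = ("node", int(v))
                    lm = math.log(scalars[oldloc])
                    du = rng.normal(0, s_sd)
                    l1, l2 = lm + du, lm - du
                    if abs(l1) <= L and abs(l2) <= L:
                        c1, c2 = ta.children[v]
                        lc1, lc2 = covering_loc(c1), covering_loc(c2)
                        n_s_old = len(cand)
                        log_edge[loc_edges(oldloc)] -= lm
                        del scalars[oldloc]
                        scalars[lc1] = math.exp(l1)
                        scalars[lc2] = math.exp(l2)
                        log_edge[loc_edges(lc1)] += l1
                        log_edge[loc_edges(lc2)] += l2
                        nd2, ss2 = components()
                        new = loglik_from(nd2, ss2, sigma2)
                        n_m_new = len(mergeable_nodes())
                        logA = (
                            power * (new - cur)
                            + math.log(lam)
                            - math.log(n_loc - k)
                            - math.log(2 * L)
                            + math.log(2.0)
                            + math.log(n_s_old)
                            - math.log(max(n_m_new, 1))
                            - stats.norm.logpdf(du, scale=s_sd)
                        )
                        if math.log(rng.random() + 1e-300) < logA:
                            cur, logdet, ss = new, nd2, ss2
                            accs["mergesplit"] += 1
                        else:
                            del scalars[lc1], scalars[lc2]
                            log_edge[loc_edges(lc1)] -= l1
                            log_edge[loc_edges(lc2)] -= l2
                            scalars[oldloc] = math.exp(lm)
                            log_edge[loc_edges(oldloc)] += lm
        else:
            # Gibbs update of the base rates (conjugate inverse-gamma)
            shape = a0 + power * n / 2.0
            scale = b0 + power * ss / 2.0
            sigma2 = scale / rng.gamma(shape, 1.0, size=p)
            cur = loglik_from(logdet, ss, sigma2)
        if not np.isfinite(cur):
            raise FloatingPointError(
                f"non-finite likelihood at iteration {it}; "
                f"state: k={len(scalars)}, sigma2={sigma2}"
            )
        if it >= burn and (it - burn) % thin == 0 and n_kept < keep:
            out_logl[n_kept] = cur
            out_k[n_kept] = len(scalars)
            out_scalars.append(dict(scalars))
            out_sigma[n_kept] = sigma2
            out_edges[n_kept] = log_edge
            n_kept += 1

    acc_rate = {
        m: (accs[m] / props[m] if props[m] else float("nan")) for m in props
    }
    if allow_scalars:
        pert = acc_rate["perturb"]
        if np.isfinite(pert) and (pert < 0.05 or pert > 0.8):
            warnings.warn(
                f"perturb acceptance rate {pert:.2f} outside [0.05, 0.80]; "
                "consider tuning proposal_sd",
                stacklevel=2,
            )
    return Chain(
        ta=ta,
        settings=settings,
        seed=seed,
        loglik=out_logl[:n_kept],
        n_scalars=out_k[:n_kept],
        scalars=out_scalars,
        base_rates=out_sigma[:n_kept],
        edge_log_rates=out_edges[:n_kept],
        acceptance=acc_rate,
    )


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood


def stepping_stone(
    Y_pcs,
    phy: Phylogeny,
    model: str = "variable",
    n_stones: int = 16,
    iterations_per_stone: int = 20_000,
    settings: ChainSettings | None = None,
    seed: int | None = None,
    alpha: float = 0.3,
) -> float:
    """Log marginal likelihood by stepping-stone (power-posterior) sampling.

    Powers follow Beta(alpha, 1) quantiles ``β_k = (k/K)^(1/alpha)`` from
    the prior (β=0) to the posterior (β=1); each ratio is estimated as the
    mean of ``lik^(β_{k+1}−β_k)`` over samples from the power posterior at
    ``β_k``.
    """
    if model not in ("variable", "equal"):
        raise ValueError("model must be 'variable' or 'equal'")
    if n_stones < 10:
        raise ValueError("need at least 10 stones")
    settings = settings or ChainSettings(iterations=iterations_per_stone,
                                         burnin=0.3, thinning=5)
    settings = replace(settings, iterations=iterations_per_stone)
    rng = np.random.default_rng(seed)
    K = n_stones
    betas = (np.arange(K + 1) / K) ** (1.0 / alpha)
    log_ml = 0.0
    prev_logls = None
    for k in range(K):
        chain = rjmcmc_rates(
            Y_pcs,
            phy,
            settings=settings,
            seed=int(rng.integers(2**31 - 1)),
            power=float(betas[k]),
            allow_scalars=(model == "variable"),
        )
        logls = chain.loglik
        db = betas[k + 1] - betas[k]
        # log mean exp of db * logL
        w = db * logls
        m = w.max()
        log_ml += m + math.log(np.mean(np.exp(w - m)))
        if prev_logls is not None:
            lo, hi = np.percentile(logls, [2.5, 97.5])
            plo, phi = np.percentile(prev_logls, [2.5, 97.5])
            if hi < plo or phi < lo:
                warnings.warn(
                    f"non-overlapping likelihood ranges between stones "
                    f"{k-1} and {k}; increase n_stones",
                    stacklevel=2,
                )
        prev_logls = logls
    return float(log_ml)


def bayes_factor(log_ml_a: float, log_ml_b: float) -> float:
    """Bayes factor on the 2·Δ(log marginal likelihood) scale."""
    return 2.0 * (log_ml_a - log_ml_b)


# ---------------------------------------------------------------------------
# posterior summaries


def detect_shifts(
    chain: Chain, threshold: float = 0.5
) -> pd.DataFrame:
    """Rate-shift locations present in more than ``threshold`` of the
    posterior samples.

    Returns a table with location label, kind (branch vs node), presence
    frequency, and magnitude (posterior median scalar given presence).
    Monotone in threshold: raising it can only drop rows.
    """
    counts: dict[tuple, int] = {}
    values: dict[tuple, list[float]] = {}
    for s in chain.scalars:
        for loc, val in s.items():
            counts[loc] = counts.get(loc, 0) + 1
            values.setdefault(loc, []).append(val)
    nsamp = max(chain.n_samples, 1)
    rows = []
    for loc, c in counts.items():
        f = c / nsamp
        if f > threshold:
            rows.append(
                {
                    "location": chain.location_label(loc[1]),
                    "kind": loc[0],
                    "frequency": f,
                    "magnitude": float(np.median(values[loc])),
                }
            )
    df = pd.DataFrame(rows, columns=["location", "kind", "frequency", "magnitude"])
    return df.sort_values("frequency", ascending=False).reset_index(drop=True)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the autocorrelation time (Geyer initial-positive-sequence
    truncation): ``n / (1 + 2 Σ ρ_t)``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
        t += 2
    return float(min(n, n / (1 + 2 * s)))


def branch_rate_table(
    chains: Chain | list[Chain],
    branch_groups: dict[str, str] | None = None,
    ess_warn: float = 200.0,
) -> pd.DataFrame:
    """Per-branch posterior mean log relative evolutionary rate.

    Multiple independent chains (same tree) are averaged. Each branch is
    labeled by ``branch_groups`` (e.g. from ``phylo.ancestral_discrete``,
    keyed by the edge's child node: tip label or ``node{i}``). An ESS
    column (autocorrelation-time estimator on the per-branch log-rate
    series) is included; values below ``ess_warn`` trigger a warning.
    """
    if isinstance(chains, Chain):
        chains = [chains]
    ref = chains[0]
    for c in chains[1:]:
        if c.ta.n_nodes != ref.ta.n_nodes or c.ta.tip_labels != ref.ta.tip_labels:
            raise ValueError("chains were run on different trees")
    rows = []
    for v in range(ref.ta.n_nodes):
        if v == ref.ta.root:
            continue
        label = ref.location_label(v)
        per_chain_mean = [c.edge_log_rates[:, v].mean() for c in chains]
        ess = float(
            np.sum([effective_sample_size(c.edge_log_rates[:, v]) for c in chains])
        )
        rows.append(
            {
                "branch": label,
                "mean_log_rate": float(np.mean(per_chain_mean)),
                "group": branch_groups.get(label) if branch_groups else None,
                "ess": ess,
            }
        )
    df = pd.DataFrame(rows)
    low = df[df["ess"] < ess_warn]
    if len(low):
        warnings.warn(
            f"{len(low)} branch rate series below ESS {ess_warn:.0f} "
            f"(min {df['ess'].min():.0f})",
            stacklevel=2,
        )
    return df


# ---------------------------------------------------------------------------
# group tests on branch rates


@dataclass
class VarianceTestResult:
    F: float
    p_value: float
    group_medians: dict[str, float]
    deviations: pd.Series
    tukey: pd.DataFrame | None


def rate_variance_test(
    branch_table: pd.DataFrame,
    group_col: str = "group",
    rate_col: str = "mean_log_rate",
) -> VarianceTestResult:
    """Brown–Forsythe equality-of-variance test on branch rates.

    One-way ANOVA with the absolute deviations from the group median as
    the response; when significant (p < 0.05), Tukey HSD on the same
    deviations identifies the group pairs.
    """
    tab = branch_table.dropna(subset=[group_col])
    groups = sorted(tab[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    med = {g: float(tab.loc[tab[group_col] == g, rate_col].median()) for g in groups}
    dev = tab.apply(lambda r: abs(r[rate_col] - med[r[group_col]]), axis=1)
    samples = [dev[tab[group_col] == g].to_numpy() for g in groups]
    if any(len(s) < 3 for s in samples):
        raise ValueError("need at least 3 branches per group")
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0:
        means = [s.mean() for s in samples]
        same = np.allclose(means, means[0])
        return VarianceTestResult(
            F=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            group_medians=med,
            deviations=dev,
            tukey=None,
        )
    F, p = stats.f_oneway(*samples)
    tukey = None
    if p < 0.05:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(
            dev.to_numpy(), tab[group_col].to_numpy(), alpha=0.05
        )
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return VarianceTestResult(
        F=float(F), p_value=float(p), group_medians=med, deviations=dev, tukey=tukey
    )


def rate_level_test(
    branch_table: pd.DataFrame,
    group_col: str = "group",
    rate_col: str = "mean_log_rate",
    alpha: float = 0.05,
) -> dict:
    """Kruskal–Wallis test of rate level differences between groups, with
    pairwise mean-rank multiple comparisons at family-wise ``alpha``
    (mean-rank difference vs. the normal-approximation critical
    difference)."""
    tab = branch_table.dropna(subset=[group_col])
    groups = sorted(tab[group_col].unique())
    samples = [tab.loc[tab[group_col] == g, rate_col].to_numpy() for g in groups]
    x = np.concatenate(samples)
    if np.allclose(x, x[0]):
        return {"H": 0.0, "p_value": 1.0, "pairwise": pd.DataFrame()}
    H, p = stats.kruskal(*samples)
    ranks = stats.rankdata(x)
    splits = np.cumsum([len(s) for s in samples])[:-1]
    rank_groups = np.split(ranks, splits)
    N = len(x)
    k = len(groups)
    zcrit = stats.norm.ppf(1 - alpha / (k * (k - 1)))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(rank_groups[i].mean() - rank_groups[j].mean())
            crit = zcrit * math.sqrt(
                (N * (N + 1) / 12.0)
                * (1.0 / len(rank_groups[i]) + 1.0 / len(rank_groups[j]))
            )
            rows.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "mean_rank_diff": diff,
                    "critical_diff": crit,
                    "significant": diff > crit,
                }
            )
    return {"H": float(H), "p_value": float(p), "pairwise": pd.DataFrame(rows)}
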