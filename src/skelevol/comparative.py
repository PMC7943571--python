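"""Phylogenetic comparative statistics on the species-level trait table:
multivariate phylogenetic signal (K_mult), net group evolutionary rates,
Procrustes-variance disparity, phylogenetic ANOVA with residual-
randomization permutation, PCA with broken-stick retention, and
morphospace-extremity ranking.

All phylogeny-aware statistics run through the Brownian-motion covariance
machinery in :mod:`skelevol.phylo`: with ``C`` the expected tip covariance
and ``P`` its whitener, statistics are computed on ``P (Y - 1a)`` where
``a`` is the GLS root estimate. Permutation p-values are ``(b + 1) /
(n_perm + 1)`` counting the observed arrangement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, PhyloCovariance, bm_covariance, tree_arrays

__all__ = [
    "SignalResult",
    "GroupRateResult",
    "DisparityResult",
    "AnovaResult",
    "PcaResult",
    "k_mult",
    "group_evol_rates",
    "disparity_pv",
    "pgls_shape_anova",
    "broken_stick_proportions",
    "pca_broken_stick",
    "morphospace_extremity",
]


def _as_matrix(Y) -> tuple[np.ndarray, list[str]]:
    """Accept a TraitTable, DataFrame, or array (+ explicit species)."""
    if hasattr(Y, "values") and hasattr(Y, "block_of"):  # TraitTable
        return Y.values.to_numpy(dtype=float), list(Y.values.index)
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), [str(i) for i in Y.index]
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, [str(i) for i in range(Y.shape[0])]


# ---------------------------------------------------------------------------
# phylogenetic signal


@dataclass
class SignalResult:
    K_mult: float
    p_value: float
    n_perm: int


def _k_statistic(Y: np.ndarray, cov: PhyloCovariance) -> float:
    n = cov.n
    a = cov.gls_mean(Y)
    R = Y - a
    num = float((R**2).sum())
    den = float(np.einsum("ij,ik,kj->", R, cov.Cinv, R))
    one = np.ones(n)
    expected = (np.trace(cov.C) - n / (one @ cov.Cinv @ one)) / (n - 1)
    return (num / den) / expected


def k_mult(
    Y,
    phy: Phylogeny,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Multivariate phylogenetic signal K_mult.

    Ratio of observed to Brownian-expected mean-squared tip deviation
    (summed squared distances in raw vs phylogenetically whitened space);
    exactly 1 under pure Brownian motion on the given tree. The p-value is
    obtained by permuting species across the tips.
    """
    Ym, species = _as_matrix(Y)
    cov = bm_covariance(phy.prune_to(species), tips=species)
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a coarse p-value", stacklevel=2)
    obs = _k_statistic(Ym, cov)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(cov.n)
        if _k_statistic(Ym[perm], cov) >= obs:
            b += 1
    return SignalResult(K_mult=obs, p_value=(b + 1) / (n_perm + 1), n_perm=n_perm)


# ---------------------------------------------------------------------------
# net group evolutionary rates


@dataclass
class GroupRateResult:
    sigma2: dict[str, float]
    sigma2_overall: float
    rate_ratio: float
    p_value: float
    n_sim: int


def _group_sigma2(U: np.ndarray, idx: dict[str, np.ndarray]) -> dict[str, float]:
    p = U.shape[1]
    return {
        g: float((U[i] ** 2).sum() / (len(i) * p)) for g, i in idx.items()
    }


def group_evol_rates(
    Y,
    phy: Phylogeny,
    groups: dict[str, str] | pd.Series,
    n_sim: int = 999,
    seed: int | None = None,
) -> GroupRateResult:
    """Net Brownian-motion evolutionary rate σ² per group.

    σ²_g is the mean squared phylogenetically whitened deviation of the
    group's species, summed over traits and divided by the trait count.
    The max/min rate ratio is tested by simulating Brownian motion under a
    single common rate on the same tree.
    """
    Ym, species = _as_matrix(Y)
    groups = pd.Series(groups).reindex(species)
    if groups.isna().any():
        raise ValueError(
            f"species without group labels: {list(groups.index[groups.isna()])[:5]}"
        )
    counts = groups.value_counts()
    if (counts < 3).any() or len(counts) < 2:
        raise ValueError("need >=2 groups with >=3 species each")
    cov = bm_covariance(phy.prune_to(species), tips=species)
    a = cov.gls_mean(Ym)
    U = cov.P @ (Ym - a)
    idx = {g: np.flatnonzero((groups == g).to_numpy()) for g in counts.index}
    sig = _group_sigma2(U, idx)
    overall = float((U**2).sum() / (cov.n * Ym.shape[1]))
    obs_ratio = max(sig.values()) / min(sig.values())

    if n_sim == 0:
        return GroupRateResult(
            sigma2=sig, sigma2_overall=overall, rate_ratio=obs_ratio,
            p_value=float("nan"), n_sim=0,
        )
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov.C + 1e-12 * np.eye(cov.n))
    p = Ym.shape[1]
    b = 0
    for _ in range(n_sim):
        Z = rng.standard_normal((cov.n, p)) * np.sqrt(overall)
        Ysim = L @ Z
        Usim = cov.P @ (Ysim - cov.gls_mean(Ysim))
        s = _group_sigma2(Usim, idx)
        if max(s.values()) / min(s.values()) >= obs_ratio:
            b += 1
    return GroupRateResult(
        sigma2=sig,
        sigma2_overall=overall,
        rate_ratio=obs_ratio,
        p_value=(b + 1) / (n_sim + 1),
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# disparity


@dataclass
class DisparityResult:
    pv: dict[str, float]
    p_values: pd.DataFrame
    n_perm: int


def disparity_pv(
    Y,
    groups: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    standardized_ok: bool = False,
) -> DisparityResult:
    """Morphological disparity as Procrustes variance per group.

    ``PV_g = Σ_i ||y_i − ȳ_g||² / n_g`` on a raw-variance (mean-centered,
    unstandardized) block; pairwise differences ``|PV_a − PV_b|`` are tested
    by permuting group labels. Standardized input is refused unless
    explicitly overridden, because z-transformation deletes the trait
    variances this statistic measures.
    """
    if hasattr(Y, "standardized") and Y.standardized and not standardized_ok:
        raise ValueError(
            "disparity requires raw-variance (unstandardized) blocks; the "
            "z-transform removes the variances being compared"
        )
    Ym, species = _as_matrix(Y)
    groups = pd.Series(groups).reindex(species)
    labels = groups.to_numpy()
    uniq = sorted(pd.unique(labels[~pd.isna(labels)]))

    def pv_of(lab: np.ndarray) -> dict[str, float]:
        out = {}
        for g in uniq:
            i = np.flatnonzero(lab == g)
            if len(i) == 0:
                out[g] = np.nan
            elif len(i) == 1:
                out[g] = 0.0
            else:
                d = Ym[i] - Ym[i].mean(axis=0)
                out[g] = float((d**2).sum() / len(i))
        return out

    for g in uniq:
        if (labels == g).sum() == 1:
            warnings.warn(f"group {g!r} has a single member; PV = 0", stacklevel=2)
    obs = pv_of(labels)
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(uniq), len(uniq)))
    obs_diff = np.array(
        [[abs(obs[a] - obs[b]) for b in uniq] for a in uniq]
    )
    for _ in range(n_perm):
        lab = rng.permutation(labels)
        p = pv_of(lab)
        d = np.array([[abs(p[a] - p[b]) for b in uniq] for a in uniq])
        counts += d >= obs_diff - 1e-15
    pmat = (counts + 1) / (n_perm + 1)
    np.fill_diagonal(pmat, 1.0)
    return DisparityResult(
        pv=obs,
        p_values=pd.DataFrame(pmat, index=uniq, columns=uniq),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# phylogenetic ANOVA (PGLS with residual randomization)


@dataclass
class AnovaResult:
    R2: float
    F: float
    p_value: float
    n_perm: int


def pgls_shape_anova(
    Y,
    factor: dict[str, str] | pd.Series,
    phy: Phylogeny,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnovaResult:
    """Proportion of (multivariate) morphological variation explained by a
    categorical factor under Brownian-motion GLS.

    The tree and data are pruned to factor-labeled species; R² is the
    explained fraction of the total sum of squares in whitened space and
    significance comes from residual-randomization permutation (RRPP) of
    the reduced (intercept-only) model residuals.
    """
    Ym, species = _as_matrix(Y)
    factor = pd.Series(factor).reindex(species)
    keep = ~factor.isna()
    if not keep.all():
        species = [s for s, k in zip(species, keep) if k]
        Ym = Ym[keep.to_numpy()]
        factor = factor[keep]
    levels = sorted(factor.unique())
    if len(levels) < 2:
        return AnovaResult(R2=0.0, F=0.0, p_value=1.0, n_perm=n_perm)
    small = [l for l in levels if (factor == l).sum() < 2]
    if small:
        warnings.warn(f"factor levels with <2 species: {small}", stacklevel=2)
    cov = bm_covariance(phy.prune_to(species), tips=species)
    n, p = Ym.shape
    X = np.column_stack(
        [np.ones(n)] + [(factor == l).to_numpy(float) for l in levels[1:]]
    )
    Pw = cov.P
    Xw = Pw @ X
    Yw = Pw @ Ym
    k = X.shape[1]

    def fit_stats(Yw_: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
        B0, *_ = np.linalg.lstsq(Xw[:, :1], Yw_, rcond=None)
        R0 = Yw_ - Xw[:, :1] @ B0
        sst = float((R0**2).sum())
        B1, *_ = np.linalg.lstsq(Xw, Yw_, rcond=None)
        R1 = Yw_ - Xw @ B1
        sse = float((R1**2).sum())
        if sst <= 0:
            return 0.0, 0.0, Xw[:, :1] @ B0, R0
        F = ((sst - sse) / (k - 1)) / (sse / (n - k))
        return 1.0 - sse / sst, F, Xw[:, :1] @ B0, R0
    r2, F, fit0, resid0 = fit_stats(Yw)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, Fp, _, _ = fit_stats(fit0 + resid0[perm])
        if Fp >= F:
            b += 1
    return AnovaResult(R2=r2, F=F, p_value=(b + 1) / (n_perm + 1), n_perm=n_perm)


# ---------------------------------------------------------------------------
# PCA with broken-stick retention


def broken_stick_proportions(p: int) -> np.ndarray:
    """Expected ordered variance proportions from random unit-stick breaks:
    ``b_k = (1/p) Σ_{i=k..p} 1/i``."""
    return np.array(
        [np.sum(1.0 / np.arange(k, p + 1)) / p for k in range(1, p + 1)]
    )


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    loadings: np.ndarray
    broken_stick: np.ndarray
    n_retained: int

    @property
    def proportions(self) -> np.ndarray:
        t = self.eigenvalues.sum()
        return self.eigenvalues / t if t > 0 else self.eigenvalues


def pca_broken_stick(Y) -> PcaResult:
    """PCA of the trait covariance matrix, retaining the leading components
    whose variance proportion exceeds the broken-stick expectation
    (sequentially, stopping at the first failure)."""
    Ym, species = _as_matrix(Y)
    n, p = Ym.shape
    Xc = Ym - Ym.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (n - 1)
    bs = broken_stick_proportions(p)
    total = lam.sum()
    n_ret = 0
    if total > 0:
        props = lam / total
        for kk in range(len(lam)):
            if props[kk] > bs[kk]:
                n_ret += 1
            else:
                break
    scores = pd.DataFrame(
        U * s,
        index=species,
        columns=[f"PC{i+1}" for i in range(len(s))],
    )
    return PcaResult(
        eigenvalues=lam,
        scores=scores,
        loadings=Vt.T,
        broken_stick=bs,
        n_retained=n_ret,
    )


# ---------------------------------------------------------------------------
# morphospace extremity


def morphospace_extremity(
    pca: PcaResult, k: int = 3, exclude_top_fraction: float | None = None
) -> pd.Series | tuple[pd.Series, list[str]]:
    """Rank species by the distance of their mean PC1..PCk score from the
    grand mean of all species' scores (descending: most extreme first).

    With ``exclude_top_fraction`` set, also return the retained species
    after dropping the most extreme fraction.
    """
    if k > pca.scores.shape[1]:
        raise ValueError(f"k={k} exceeds available PCs ({pca.scores.shape[1]})")
    sub = pca.scores.iloc[:, :k]
    per_species = sub.mean(axis=1)
    dist = (per_species - per_species.mean()).abs().sort_values(ascending=False)
    dist.name = "extremity"
    if exclude_top_fraction is None:
        return dist
    n_drop = int(np.floor(exclude_top_fraction * len(dist)))
    retained = list(dist.index[n_drop:])
    return dist, retained
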