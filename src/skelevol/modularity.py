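"""Evolutionary modularity and integration.

Modularity of the four skeletal blocks (pectoral shape, pelvic shape,
forelimb, hindlimb; the size trait is excluded from all partitions) is
measured by the covariance ratio CR, which contrasts between-module to
within-module covariation: strong modularity gives CR near 0, absent
modularity gives CR near 1. Integration of block pairs is measured by
two-block partial least squares: r_PLS is the correlation of the first
pair of singular-vector scores of the cross-block covariance.

Both statistics are compared across datasets through permutation effect
sizes (z-scores): the observed value is standardized against an empirical
null built by permutation — random reassignment of variables to modules
(module variable counts preserved) for CR, row permutation of one block
for PLS. More negative CR z-scores mean stronger modularity; larger
PLS z-scores mean stronger integration. All computations run on
phylogenetically whitened data so they measure *evolutionary* covariation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphodata import TraitTable
from .phylo import Phylogeny, bm_covariance

__all__ = [
    "ModuleHypothesis",
    "HYPOTHESES",
    "ModularityResult",
    "IntegrationResult",
    "EmmliResult",
    "covariance_ratio",
    "cr_from_cov",
    "modularity_z",
    "compare_modular_hypotheses",
    "phylo_pls",
    "pls_z",
    "compare_pls",
    "rarefied_group_comparison",
    "emmli_fit",
]

NON_SIZE_BLOCKS = ("pectoral_shape", "pelvic_shape", "forelimb", "hindlimb")


@dataclass(frozen=True)
class ModuleHypothesis:
    """A partition of the four skeletal blocks into evolutionary modules."""

    name: str
    module_of: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        missing = set(NON_SIZE_BLOCKS) - set(self.module_of)
        if missing:
            raise ValueError(f"{self.name}: unassigned blocks {sorted(missing)}")
        if "size" in self.module_of:
            raise ValueError(f"{self.name}: the size block is excluded from partitions")
        if len(set(self.module_of.values())) < 2:
            raise ValueError(f"{self.name}: need at least 2 modules")

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.module_of.values()))


#: The five standard hypotheses for girdle/limb evolutionary modularity:
#: H1 limbs one module + separate girdles; H2 limbs vs girdles; H3
#: functional front (pectoral+forelimb) vs hind (pelvic+hindlimb) modules;
#: H4 all four blocks independent; H5 girdles one module + separate limbs.
HYPOTHESES: dict[str, ModuleHypothesis] = {
    "H1": ModuleHypothesis("H1", {
        "pectoral_shape": "pectoral", "pelvic_shape": "pelvic",
        "forelimb": "limbs", "hindlimb": "limbs"}),
    "H2": ModuleHypothesis("H2", {
        "pectoral_shape": "girdles", "pelvic_shape": "girdles",
        "forelimb": "limbs", "hindlimb": "limbs"}),
    "H3": ModuleHypothesis("H3", {
        "pectoral_shape": "front", "forelimb": "front",
        "pelvic_shape": "hind", "hindlimb": "hind"}),
    "H4": ModuleHypothesis("H4", {
        "pectoral_shape": "pectoral", "pelvic_shape": "pelvic",
        "forelimb": "fore", "hindlimb": "hind"}),
    "H5": ModuleHypothesis("H5", {
        "pectoral_shape": "girdles", "pelvic_shape": "girdles",
        "forelimb": "fore", "hindlimb": "hind"}),
}


# ---------------------------------------------------------------------------
# covariance ratio


def cr_from_cov(S: np.ndarray, modules: np.ndarray | list) -> float:
    """Covariance ratio of a trait covariance matrix under a partition.

    Pairwise ``CR(A,B) = sqrt( tr(S_AB S_ABᵀ) / sqrt( tr(S*_AA S*_AAᵀ) ·
    tr(S*_BB S*_BBᵀ) ) )`` with within-module diagonals zeroed (S*);
    the multi-module CR is the mean over module pairs.
    """
    S = np.asarray(S, dtype=float)
    modules = np.asarray(modules)
    uniq = sorted(set(modules.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least 2 modules")
    crs = []
    for a, b in itertools.combinations(uniq, 2):
        ia = np.flatnonzero(modules == a)
        ib = np.flatnonzero(modules == b)
        if len(ia) < 2 or len(ib) < 2:
            raise ValueError(f"module with a single variable: {a if len(ia) < 2 else b}")
        Sab = S[np.ix_(ia, ib)]
        Saa = S[np.ix_(ia, ia)].copy()
        Sbb = S[np.ix_(ib, ib)].copy()
        np.fill_diagonal(Saa, 0.0)
        np.fill_diagonal(Sbb, 0.0)
        num = np.trace(Sab @ Sab.T)
        den = math.sqrt(np.trace(Saa @ Saa.T) * np.trace(Sbb @ Sbb.T))
        if den <= 0:
            raise ValueError("zero within-module covariation; CR undefined")
        crs.append(math.sqrt(num / den))
    return float(np.mean(crs))


def _modules_and_units(
    table: TraitTable, hypothesis: ModuleHypothesis
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Map non-size traits to modules, and to permutation units.

    Landmark x/y/z triplets form one unit (they move together under
    permutation); each limb trait is its own unit.
    """
    cols = [c for c in table.values.columns if table.block_of[c] != "size"]
    modules = np.array([hypothesis.module_of[table.block_of[c]] for c in cols])
    units = []
    for c in cols:
        if table.block_of[c] in ("pectoral_shape", "pelvic_shape"):
            units.append(c.rsplit("_", 1)[0])  # strip the _x/_y/_z suffix
        else:
            units.append(c)
    return cols, modules, np.array(units)


def covariance_ratio(Yt: np.ndarray | TraitTable, hypothesis: ModuleHypothesis,
                     block_of: dict | None = None,
                     columns: list[str] | None = None) -> float:
    """CR of (already phylogenetically transformed) trait data."""
    if isinstance(Yt, TraitTable):
        cols, modules, _ = _modules_and_units(Yt, hypothesis)
        M = Yt.values[cols].to_numpy(dtype=float)
    else:
        if block_of is None or columns is None:
            raise ValueError("block_of and columns required for array input")
        cols = [c for c in columns if block_of[c] != "size"]
        idx = [columns.index(c) for c in cols]
        M = np.asarray(Yt, dtype=float)[:, idx]
        modules = np.array([hypothesis.module_of[block_of[c]] for c in cols])
    S = np.cov(M, rowvar=False)
    return cr_from_cov(S, modules)


# ---------------------------------------------------------------------------
# permutation effect sizes


@dataclass
class ModularityResult:
    hypothesis: str
    CR: float
    z: float
    p_value: float
    null_mean: float
    null_sd: float
    n_perm: int
    null_values: np.ndarray = field(repr=False, default=None)


def _permute_unit_modules(
    modules: np.ndarray, units: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle the unit→module assignment, preserving per-module unit counts."""
    uniq_units, first = np.unique(units, return_index=True)
    unit_modules = modules[first]
    perm = rng.permutation(unit_modules)
    lookup = dict(zip(uniq_units.tolist(), perm.tolist()))
    return np.array([lookup[u] for u in units])


def modularity_z(
    Y: TraitTable,
    phy: Phylogeny,
    hypothesis: ModuleHypothesis,
    n_perm: int = 1000,
    seed: int | None = None,
    log_transform: bool = True,
    permute_unit: str = "column",
    _rng: np.random.Generator | None = None,
    _pretransformed: np.ndarray | None = None,
) -> ModularityResult:
    """CR effect size from a permutation null.

    The data are phylogenetically whitened, the observed CR computed, and a
    null distribution built by randomly reassigning variables to modules of
    the same sizes. ``z = (CR_obs − mean(null)) / sd(null)``, computed by
    default on log CR (the CR null is right-skewed, and the log scale makes
    effect sizes comparable across partitions with different module
    counts); more negative z means stronger modularity. One-tailed p for
    small CR (computed on the raw CR scale either way).

    ``permute_unit`` is "column" (default: every trait column reassigned
    independently, keeping per-module variable counts fixed — the only
    scheme that leaves the null exchangeable when modules mix landmark
    triplets with single limb columns) or "triplet" (x/y/z triplets of one
    landmark move together; per-module unit counts fixed instead).
    """
    cols, modules, units = _modules_and_units(Y, hypothesis)
    if permute_unit == "column":
        units = np.asarray(cols)
    elif permute_unit != "triplet":
        raise ValueError("permute_unit must be 'column' or 'triplet'")
    if _pretransformed is not None:
        U = _pretransformed
    else:
        species = list(Y.values.index)
        cov = bm_covariance(phy.prune_to(species), tips=species)
        M = Y.values[cols].to_numpy(dtype=float)
        U = cov.P @ (M - cov.gls_mean(M))
    S = np.cov(U, rowvar=False)
    obs = cr_from_cov(S, modules)
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pm = _permute_unit_modules(modules, units, rng)
        null[i] = cr_from_cov(S, pm)
    vals = np.log(null) if log_transform else null
    ov = math.log(obs) if log_transform else obs
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    z = (ov - mu) / sd if sd > 0 else 0.0
    p = (np.sum(null <= obs) + 1) / (n_perm + 1)
    return ModularityResult(
        hypothesis=hypothesis.name, CR=obs, z=float(z), p_value=float(p),
        null_mean=mu, null_sd=sd, n_perm=n_perm, null_values=vals,
    )


def _two_sample_z(r1, r2) -> tuple[float, float]:
    """Pairwise comparison of two permutation effect sizes.

    Statistic ``(z1 − z2)/√(se1² + se2²)`` with the se of each z taken as
    the sd of its standardized null distribution (1 by construction, so the
    statistic reduces to Δz/√2); two-tailed normal p.
    """
    se1 = float(np.std((r1.null_values - r1.null_mean) / r1.null_sd, ddof=1))
    se2 = float(np.std((r2.null_values - r2.null_mean) / r2.null_sd, ddof=1))
    zstat = (r1.z - r2.z) / math.sqrt(se1**2 + se2**2)
    p = 2 * stats.norm.sf(abs(zstat))
    return float(zstat), float(p)


def compare_modular_hypotheses(
    Y: TraitTable,
    phy: Phylogeny,
    hypotheses: list[ModuleHypothesis] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate several modularity hypotheses on one dataset.

    Returns ``(ranking, pairwise)``: a table of per-hypothesis CR, z, p
    sorted by z ascending (best = most modular first), and pairwise
    two-sample z tests between hypotheses. A common permutation stream
    (same seed) is reused across hypotheses for variance reduction.
    """
    if hypotheses is None:
        hypotheses = list(HYPOTHESES.values())
    if len(hypotheses) < 2:
        raise ValueError("need at least 2 hypotheses")
    species = list(Y.values.index)
    cov = bm_covariance(phy.prune_to(species), tips=species)
    cols = [c for c in Y.values.columns if Y.block_of[c] != "size"]
    M = Y.values[cols].to_numpy(dtype=float)
    U = cov.P @ (M - cov.gls_mean(M))
    results = {}
    for h in hypotheses:
        rng = np.random.default_rng(seed)  # common stream across hypotheses
        results[h.name] = modularity_z(
            Y, phy, h, n_perm=n_perm, _rng=rng, _pretransformed=U
        )
    ranking = pd.DataFrame(
        [
            {"hypothesis": r.hypothesis, "CR": r.CR, "z": r.z, "p": r.p_value}
            for r in results.values()
        ]
    ).sort_values("z").reset_index(drop=True)
    rows = []
    for a, b in itertools.combinations(results, 2):
        zstat, p = _two_sample_z(results[a], results[b])
        rows.append({"hyp_a": a, "hyp_b": b, "z_stat": zstat, "p": p})
    return ranking, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-block PLS


@dataclass
class IntegrationResult:
    r_pls: float
    z: float | None
    p_value: float | None
    left_vector: np.ndarray
    right_vector: np.ndarray
    n_perm: int = 0
    null_values: np.ndarray = field(repr=False, default=None)
    null_mean: float = float("nan")
    null_sd: float = float("nan")


def _pls_r(U1: np.ndarray, U2: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    S12 = U1.T @ U2 / (U1.shape[0] - 1)
    if np.allclose(S12, 0):
        return 0.0, np.zeros(U1.shape[1]), np.zeros(U2.shape[1])
    u, s, vt = np.linalg.svd(S12, full_matrices=False)
    s1 = U1 @ u[:, 0]
    s2 = U2 @ vt[0]
    sd1, sd2 = s1.std(), s2.std()
    if sd1 == 0 or sd2 == 0:
        return 0.0, u[:, 0], vt[0]
    r = float(np.corrcoef(s1, s2)[0, 1])
    return abs(r), u[:, 0], vt[0]


def phylo_pls(
    Y1, Y2, phy: Phylogeny, _whitened: tuple | None = None
) -> IntegrationResult:
    """Phylogenetic two-block PLS integration.

    Both blocks are whitened under the Brownian covariance of the shared
    tree; r_PLS is the correlation of the projections onto the first left/
    right singular vectors of the cross-block covariance.
    """
    if _whitened is not None:
        U1, U2 = _whitened
    else:
        U1, U2 = _whiten_pair(Y1, Y2, phy)
    if np.allclose(U1.T @ U2, 0):
        warnings.warn("zero cross-covariance between blocks", stacklevel=2)
    r, u, v = _pls_r(U1, U2)
    return IntegrationResult(r_pls=r, z=None, p_value=None,
                             left_vector=u, right_vector=v)


def _whiten_pair(Y1, Y2, phy: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    from .comparative import _as_matrix

    M1, sp1 = _as_matrix(Y1)
    M2, sp2 = _as_matrix(Y2)
    if sp1 != sp2:
        raise ValueError("blocks must share the same species rows")
    cov = bm_covariance(phy.prune_to(sp1), tips=sp1)
    U1 = cov.P @ (M1 - cov.gls_mean(M1))
    U2 = cov.P @ (M2 - cov.gls_mean(M2))
    return U1, U2


def pls_z(
    Y1,
    Y2,
    phy: Phylogeny,
    n_perm: int = 1000,
    seed: int | None = None,
) -> IntegrationResult:
    """PLS integration effect size: permutation null from randomly
    permuting the rows of one whitened block; ``z = (r_obs − mean)/sd``,
    one-tailed p for large r."""
    U1, U2 = _whiten_pair(Y1, Y2, phy)
    r, u, v = _pls_r(U1, U2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _pls_r(U1, U2[rng.permutation(U2.shape[0])])[0]
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    z = (r - mu) / sd if sd > 0 else 0.0
    p = (np.sum(null >= r) + 1) / (n_perm + 1)
    return IntegrationResult(
        r_pls=r, z=float(z), p_value=float(p), left_vector=u, right_vector=v,
        n_perm=n_perm, null_values=null, null_mean=mu, null_sd=sd,
    )


def compare_pls(resA: IntegrationResult, resB: IntegrationResult) -> tuple[float, float]:
    """Two-sample comparison of PLS effect sizes (z statistic, two-tailed p)."""
    class _Wrap:
        pass

    a, b = _Wrap(), _Wrap()
    for w, r in ((a, resA), (b, resB)):
        w.z = r.z
        w.null_values = r.null_values
        w.null_mean = r.null_mean
        w.null_sd = r.null_sd
    return _two_sample_z(a, b)


# ---------------------------------------------------------------------------
# rarefied cross-group comparison


def rarefied_group_comparison(
    tables: dict[str, TraitTable],
    phy: Phylogeny,
    statistic: str = "pls_z",
    block_pair: tuple[str, str] = ("pectoral_shape", "forelimb"),
    hypothesis: ModuleHypothesis | None = None,
    fraction: float = 0.39,
    n_iter: int = 1000,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Equalize sampling across groups by rarefaction and compare effect
    sizes.

    Per iteration each group's species are subsampled without replacement
    to ``fraction`` of the group, the tree pruned accordingly, the chosen
    effect size (``pls_z`` on ``block_pair`` or ``cr_z`` under
    ``hypothesis``) recomputed, and every group pair compared by the
    two-sample z test. Reports the percentage of iterations with p < alpha
    per pair, plus effect-size distribution summaries.
    """
    if statistic not in ("pls_z", "cr_z"):
        raise ValueError("statistic must be 'pls_z' or 'cr_z'")
    if statistic == "cr_z" and hypothesis is None:
        raise ValueError("cr_z requires a hypothesis")
    sizes = {g: max(1, int(round(fraction * len(t.values)))) for g, t in tables.items()}
    small = {g: m for g, m in sizes.items() if m < 10}
    if small:
        raise ValueError(f"rarefied sample below 10 species: {small}")
    rng = np.random.default_rng(seed)
    groups = sorted(tables)
    pairs = list(itertools.combinations(groups, 2))
    sig = {pr: 0 for pr in pairs}
    zs: dict[str, list[float]] = {g: [] for g in groups}
    for _ in range(n_iter):
        res = {}
        for g in groups:
            t = tables[g]
            pick = sorted(
                rng.choice(len(t.values), size=sizes[g], replace=False).tolist()
            )
            sub = TraitTable(
                values=t.values.iloc[pick],
                block_of=dict(t.block_of),
                standardized=t.standardized,
            )
            sub_phy = phy.prune_to(list(sub.values.index))
            if statistic == "pls_z":
                res[g] = pls_z(
                    sub.subset(block_pair[0]).values,
                    sub.subset(block_pair[1]).values,
                    sub_phy,
                    n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                )
            else:
                res[g] = modularity_z(
                    sub, sub_phy, hypothesis, n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                )
            zs[g].append(res[g].z)
        for pr in pairs:
            if statistic == "pls_z":
                _, p = compare_pls(res[pr[0]], res[pr[1]])
            else:
                _, p = _two_sample_z(res[pr[0]], res[pr[1]])
            if p < alpha:
                sig[pr] += 1
    return {
        "percent_significant": {pr: 100.0 * c / n_iter for pr, c in sig.items()},
        "z_summary": {
            g: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
            for g, v in zs.items()
        },
        "n_iter": n_iter,
        "fraction": fraction,
        "sizes": sizes,
    }


# ---------------------------------------------------------------------------
# maximum-likelihood module-correlation model comparison (EMMLi-style)


@dataclass
class EmmliResult:
    table: pd.DataFrame  # per-model: logL, k, AICc, weight
    rho: dict[str, dict[str, float]]  # per-model per-class correlation


def _pair_classes(modules: np.ndarray) -> np.ndarray:
    """Class label for each trait pair: within-module (per module) or between."""
    p = len(modules)
    iu = np.triu_indices(p, k=1)
    cls = np.empty(len(iu[0]), dtype=object)
    for k, (i, j) in enumerate(zip(*iu)):
        cls[k] = (
            f"within_{modules[i]}" if modules[i] == modules[j] else "between"
        )
    return cls


def emmli_fit(
    corr: np.ndarray,
    hypotheses: dict[str, np.ndarray],
    n_eff: int,
) -> EmmliResult:
    """Maximum-likelihood comparison of module-correlation models.

    Each hypothesis maps traits to modules; its model assigns one
    correlation parameter ρ to every within-module class and one to the
    between-module class. Pairwise correlations are modeled as independent
    Fisher-z normals with variance 1/(n_eff − 3); the ML estimate of each
    class ρ is the back-transformed mean z. Models are ranked by AICc and
    given exp(−ΔAICc/2) posterior weights.
    """
    corr = np.asarray(corr, dtype=float)
    if n_eff <= 3:
        raise ValueError("n_eff must exceed 3")
    p = corr.shape[0]
    iu = np.triu_indices(p, k=1)
    r = np.clip(corr[iu], -0.999999, 0.999999)
    zr = np.arctanh(r)
    var = 1.0 / (n_eff - 3)
    n_pairs = len(r)
    rows = []
    rho_all: dict[str, dict[str, float]] = {}
    for name, modules in hypotheses.items():
        cls = _pair_classes(np.asarray(modules))
        logL = 0.0
        rho: dict[str, float] = {}
        for c in sorted(set(cls.tolist())):
            zi = zr[cls == c]
            zhat = float(zi.mean())
            rho_c = float(np.tanh(zhat))
            if abs(rho_c) > 0.995:
                warnings.warn(
                    f"{name}: class {c} correlation at boundary ({rho_c:.3f})",
                    stacklevel=2,
                )
            rho[c] = rho_c
            logL += float(stats.norm.logpdf(zi, loc=zhat, scale=math.sqrt(var)).sum())
        k = len(rho)
        aicc = -2 * logL + 2 * k + (2 * k * (k + 1)) / max(n_pairs - k - 1, 1)
        rows.append({"model": name, "logL": logL, "k": k, "AICc": aicc})
        rho_all[name] = rho
    tab = pd.DataFrame(rows).set_index("model")
    delta = tab["AICc"] - tab["AICc"].min()
    w = np.exp(-delta / 2)
    tab["weight"] = w / w.sum()
    return EmmliResult(table=tab.sort_values("AICc"), rho=rho_all)
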