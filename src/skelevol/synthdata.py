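"""Synthetic data generation for every pipeline stage.

The generator emulates the structure of a museum micro-CT morphometric
study of the anole locomotor skeleton: a dated phylogeny with three major
monophyletic biogeographic groups (Primary Mainland sister to (Greater
Antilles, Secondary Mainland)), species-level traits evolving by (possibly
rate-heterogeneous) Brownian motion with block-structured covariance
following one of the five modularity hypotheses, multi-specimen sampling
per species (~2–3 specimens), landmark configurations with rigid
transforms, a small fraction of right-sided (mirrored) girdles, sexual
dimorphism in pelvic shape, and sporadically missing limb measurements
(~0.5% of cells).

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .modularity import HYPOTHESES, ModuleHypothesis
from .morphodata import (
    FORELIMB_ELEMENTS,
    HINDLIMB_ELEMENTS,
    LIMB_ELEMENTS,
    LandmarkConfiguration,
    SpecimenRecord,
    TraitTable,
)
from .phylo import Phylogeny, bm_covariance, tree_arrays

__all__ = [
    "SimConfig",
    "default_template",
    "sim_tree",
    "sim_pure_birth",
    "sim_bm_traits",
    "sim_landmark_specimens",
    "inject_missing",
    "simulate_specimen_dataset",
    "hypothesis_correlation",
]

#: Default block sizes of the full trait table (54 + 54 + 7 + 8 + 1 = 124).
DEFAULT_BLOCK_SIZES = {
    "pectoral_shape": 54,
    "pelvic_shape": 54,
    "forelimb": 7,
    "hindlimb": 8,
}


@dataclass
class SimConfig:
    """Generative settings. Defaults mirror the structure of the empirical
    study: 110 / 29 / 107 species in the three groups (~2–3 specimens per
    species), 0.45% missing limb cells, and an H3 (front/hind module)
    covariance with within-module correlation 0.7 and between-module 0.1."""

    seed: int  # mandatory
    n_species: dict[str, int] = field(
        default_factory=lambda: {
            "GreaterAntilles": 110,
            "PrimaryMainland": 29,
            "SecondaryMainland": 107,
        }
    )
    root_age: float = 50.0
    inner_age: float = 40.0
    crown_age: float = 30.0
    block_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_SIZES)
    )
    hypothesis: str = "H3"
    r_within: float = 0.7
    r_between: float = 0.1
    base_sigma2: float = 1.0
    rate_scalars: dict[str, float] = field(default_factory=dict)  # group -> r
    specimens_per_species: float = 2.6
    shape_noise: float = 0.03
    side_flip_fraction: float = 0.035
    missing_fraction: float = 0.0045
    dimorphism_scale: float = 0.15
    female_fraction: float = 0.0  # males-only study design by default

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not -1 < self.r_within < 1 or not -1 < self.r_between < 1:
            raise ValueError("correlations must lie in (-1, 1)")
        # fail fast if the implied covariance is not positive definite
        np.linalg.cholesky(self.correlation_matrix())

    def correlation_matrix(self) -> np.ndarray:
        hyp = HYPOTHESES[self.hypothesis]
        return hypothesis_correlation(
            self.block_sizes, hyp, self.r_within, self.r_between
        )


def hypothesis_correlation(
    block_sizes: dict[str, int],
    hypothesis: ModuleHypothesis,
    r_within: float = 0.7,
    r_between: float = 0.1,
) -> np.ndarray:
    """Trait correlation matrix implied by a modularity hypothesis:
    ``r_within`` between traits of the same module, ``r_between``
    otherwise."""
    blocks = [b for b in block_sizes for _ in range(block_sizes[b])]
    mods = np.array([hypothesis.module_of[b] for b in blocks])
    R = np.where(mods[:, None] == mods[None, :], r_within, r_between)
    np.fill_diagonal(R, 1.0)
    return R


# ---------------------------------------------------------------------------
# trees


def sim_pure_birth(
    n: int, crown_age: float, rng: np.random.Generator, prefix: str = "sp"
) -> dendropy.Tree:
    """Yule (pure-birth) ultrametric tree with ``n`` tips, scaled so the
    crown (root) age equals ``crown_age``."""
    if n < 2:
        raise ValueError("need n >= 2")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # active lineages with their birth times
    t = 0.0
    root = tree.seed_node
    c1 = root.new_child()
    c2 = root.new_child()
    active = [(c1, 0.0), (c2, 0.0)]
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / len(active))
    for k, (node, born) in enumerate(active):
        node.edge.length = t_end - born
        node.taxon = taxa.new_taxon(label=f"{prefix}{k+1:03d}")
    # rescale to the requested crown age
    scale = crown_age / t_end
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= scale
    root.edge.length = None
    return tree


def sim_tree(config: SimConfig) -> tuple[Phylogeny, dict[str, str]]:
    """Dated tree with three monophyletic groups on the fixed backbone
    (PrimaryMainland, (GreaterAntilles, SecondaryMainland)).

    Returns the phylogeny and the tip → group mapping. Group name prefixes
    label the tips (``GA_``, ``PM_``, ``SM_``).
    """
    for g, n in config.n_species.items():
        if n < 4:
            raise ValueError(f"need >= 4 species per group, got {n} for {g}")
    rng = np.random.default_rng(config.seed)
    prefixes = {"GreaterAntilles": "GA_sp", "PrimaryMainland": "PM_sp",
                "SecondaryMainland": "SM_sp"}
    order = ["PrimaryMainland", "GreaterAntilles", "SecondaryMainland"]
    crowns = {}
    for g in order:
        crowns[g] = sim_pure_birth(
            config.n_species[g], config.crown_age, rng,
            prefix=prefixes.get(g, g + "_sp"),
        )
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node  # age root_age
    inner = root.new_child(edge_length=config.root_age - config.inner_age)

    def attach(parent, crown_tree, stem_len):
        sub = crown_tree.seed_node
        crown_tree.seed_node = None  # detach
        parent.add_child(sub)
        sub.edge.length = stem_len
        for lf in sub.leaf_iter():
            lf.taxon = taxa.new_taxon(label=lf.taxon.label)

    attach(root, crowns["PrimaryMainland"], config.root_age - config.crown_age)
    attach(inner, crowns["GreaterAntilles"], config.inner_age - config.crown_age)
    attach(inner, crowns["SecondaryMainland"], config.inner_age - config.crown_age)
    tree.update_taxon_namespace()
    phy = Phylogeny(tree)
    groups = {}
    for g, pre in prefixes.items():
        for lab in phy.tip_labels:
            if lab.startswith(pre):
                groups[lab] = g
    return phy, groups


# ---------------------------------------------------------------------------
# trait evolution


def _scaled_tip_covariance(
    phy: Phylogeny,
    groups: dict[str, str] | None,
    rate_scalars: dict[str, float] | None,
    tips: list[str],
) -> np.ndarray:
    """Tip covariance of the rate-scaled tree: each group's clade (stem
    included) has its branch lengths multiplied by the group's scalar."""
    if not rate_scalars:
        return bm_covariance(phy, tips=tips).C
    t = phy.copy()
    for g, r in rate_scalars.items():
        members = [lab for lab, gg in groups.items() if gg == g]
        mrca = t.tree.mrca(taxa=[t.tree.taxon_namespace.get_taxon(m) for m in members])
        for nd in mrca.preorder_iter():
            if nd.edge.length is not None:
                nd.edge.length *= r
    # eigen-whitening not needed; just the covariance
    ta = tree_arrays(Phylogeny(t.tree), tips)
    depths = ta.depths()
    n = ta.n_tips
    C = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for v in ta.postorder:
        if not ta.children[v]:
            tipsets[v] = [v]
            C[v, v] = depths[v]
        else:
            kids = [tipsets[c] for c in ta.children[v]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia, ib = np.asarray(kids[a]), np.asarray(kids[b])
                    C[np.ix_(ia, ib)] = depths[v]
                    C[np.ix_(ib, ia)] = depths[v]
            tipsets[v] = [x for k in kids for x in k]
    return C


def sim_bm_traits(
    phy: Phylogeny,
    Sigma: np.ndarray,
    base_sigma2: float = 1.0,
    rate_scalars: dict[str, float] | None = None,
    groups: dict[str, str] | None = None,
    seed: int | None = None,
    block_of: dict[str, str] | None = None,
    columns: list[str] | None = None,
) -> TraitTable | pd.DataFrame:
    """Exact multivariate Brownian-motion simulation on the tree.

    Species values are drawn jointly from ``N(0, C_r ⊗ base_sigma2·Σ)``
    where ``C_r`` is the tip covariance of the (optionally rate-scaled)
    tree, via Cholesky factors of both matrices. Returns a TraitTable when
    ``block_of``/``columns`` are given, else a DataFrame.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    try:
        Ls = np.linalg.cholesky(base_sigma2 * Sigma)
    except np.linalg.LinAlgError as e:
        raise ValueError("trait covariance must be positive definite") from e
    tips = phy.tip_labels
    C = _scaled_tip_covariance(phy, groups, rate_scalars, tips)
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(len(tips)))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((len(tips), Sigma.shape[0]))
    Y = Lc @ Z @ Ls.T
    cols = columns or [f"t{j+1}" for j in range(Sigma.shape[0])]
    df = pd.DataFrame(Y, index=tips, columns=cols)
    df.index.name = "species"
    if block_of is not None:
        return TraitTable(values=df, block_of=block_of, standardized=False)
    return df


def blocked_traits(
    phy: Phylogeny, config: SimConfig, groups: dict[str, str] | None = None
) -> TraitTable:
    """Convenience wrapper: block-labeled TraitTable (no size column) drawn
    under the config's hypothesis covariance and planted rate scalars."""
    sizes = config.block_sizes
    cols, block_of = [], {}
    for b, k in sizes.items():
        pre = {"pectoral_shape": "pec_lm", "pelvic_shape": "pel_lm"}.get(b)
        for i in range(k):
            if pre:  # name shape traits as landmark triplets
                name = f"{pre}{i // 3 + 1}_{'xyz'[i % 3]}"
            else:
                name = (FORELIMB_ELEMENTS + HINDLIMB_ELEMENTS)[
                    i if b == "forelimb" else len(FORELIMB_ELEMENTS) + i
                ]
            cols.append(name)
            block_of[name] = b
    R = config.correlation_matrix()
    return sim_bm_traits(
        phy,
        R,
        base_sigma2=config.base_sigma2,
        rate_scalars=config.rate_scalars,
        groups=groups,
        seed=config.seed + 1,
        block_of=block_of,
        columns=cols,
    )


# ---------------------------------------------------------------------------
# landmark specimens


def default_template(k: int = 18, size: float = 10.0) -> np.ndarray:
    """Deterministic non-degenerate landmark template: ``k`` points on a
    golden-spiral sphere of radius ``size`` (mm)."""
    i = np.arange(k)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    y = 1 - 2 * (i + 0.5) / k
    r = np.sqrt(1 - y**2)
    pts = np.column_stack([r * np.cos(phi * i), y, r * np.sin(phi * i)])
    return size * pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def sim_landmark_specimens(
    template: np.ndarray,
    species_deviation: dict[str, np.ndarray],
    n_per_species: dict[str, int],
    structure: str = "pelvic",
    noise: float = 0.03,
    side_flip_fraction: float = 0.0,
    sex_shift: np.ndarray | None = None,
    female_fraction: float = 0.0,
    mirror_axis: int = 0,
    seed: int | None = None,
) -> tuple[list[LandmarkConfiguration], pd.DataFrame]:
    """Simulate digitized girdle configurations.

    Each specimen = template + its species' shape deviation + isotropic
    landmark noise (sd = ``noise`` × template scale), then a random
    rotation, translation, and scale. A ``side_flip_fraction`` of specimens
    is emitted right-sided (reflected about ``mirror_axis``); females (a
    ``female_fraction``) receive the ``sex_shift`` added to their shape.
    Returns the configurations and a metadata table (specimen, species,
    sex, side).
    """
    rng = np.random.default_rng(seed)
    scale = float(np.sqrt((template - template.mean(0)) ** 2).sum())
    configs, meta = [], []
    for sp, nspec in n_per_species.items():
        dev = species_deviation.get(sp, 0.0)
        for r in range(nspec):
            sid = f"{sp}_ind{r+1}"
            sex = "female" if rng.random() < female_fraction else "male"
            coords = template + dev + rng.standard_normal(template.shape) * (
                noise * scale / math.sqrt(template.size)
            )
            if sex == "female" and sex_shift is not None:
                coords = coords + sex_shift
            coords = coords @ _random_rotation(rng).T
            coords = coords * rng.uniform(0.5, 2.0) + rng.uniform(-50, 50, size=3)
            side = "left"
            if rng.random() < side_flip_fraction:
                side = "right"
                coords = coords.copy()
                coords[:, mirror_axis] *= -1
            configs.append(
                LandmarkConfiguration(
                    specimen_id=sid, structure=structure, side=side, coords=coords
                )
            )
            meta.append({"specimen_id": sid, "species_id": sp, "sex": sex,
                         "side": side})
    return configs, pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# missingness


def inject_missing(
    table: pd.DataFrame | np.ndarray,
    fraction: float,
    seed: int | None = None,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Delete cells completely at random; returns (table, mask) with the
    boolean mask of deleted cells for recovery scoring. Columns left with
    fewer than 2 observed values are resampled."""
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    is_df = isinstance(table, pd.DataFrame)
    X = np.asarray(table, dtype=float)
    rng = np.random.default_rng(seed)
    if fraction == 0:
        return table, np.zeros(X.shape, dtype=bool)
    for _ in range(1000):
        mask = rng.random(X.shape) < fraction
        if ((~mask).sum(axis=0) >= 2).all():
            break
    else:  # pragma: no cover
        raise RuntimeError("could not place missing cells")
    out = X.copy()
    out[mask] = np.nan
    if is_df:
        df = table.copy().astype(float)
        df.iloc[:, :] = out
        return df, mask
    return out, mask


# ---------------------------------------------------------------------------
# full specimen-level dataset


def simulate_specimen_dataset(
    config: SimConfig,
) -> dict:
    """End-to-end specimen-level simulation for ingestion testing.

    Simulates the tree and species trait means, then per-species specimens:
    pectoral and pelvic landmark configurations (shape deviations drawn per
    species), limb lengths with factor-model correlation and injected
    missingness, group/sex metadata. Returns a dict with specimens,
    phylogeny, groups, and the generating truth.
    """
    rng = np.random.default_rng(config.seed)
    phy, groups = sim_tree(config)
    tips = phy.tip_labels
    template = default_template()
    scale = float(np.sqrt((template - template.mean(0)) ** 2).sum())
    # species-level shape deviations (BM-free isotropic here; the BM trait
    # machinery is exercised at the trait-table level)
    dev_pec = {sp: rng.standard_normal(template.shape) * 0.02 * scale for sp in tips}
    dev_pel = {sp: rng.standard_normal(template.shape) * 0.02 * scale for sp in tips}
    n_per = {
        sp: int(2 + (rng.random() < (config.specimens_per_species - 2)))
        for sp in tips
    }
    sex_shift = rng.standard_normal(template.shape)
    sex_shift *= config.dimorphism_scale * scale / np.linalg.norm(sex_shift)
    pec_configs, _ = sim_landmark_specimens(
        template, dev_pec, n_per, structure="pectoral", noise=config.shape_noise,
        side_flip_fraction=config.side_flip_fraction,
        seed=config.seed + 11,
    )
    pel_configs, meta = sim_landmark_specimens(
        template, dev_pel, n_per, structure="pelvic", noise=config.shape_noise,
        side_flip_fraction=config.side_flip_fraction,
        sex_shift=sex_shift, female_fraction=config.female_fraction,
        seed=config.seed + 12,
    )
    # limb lengths: species size effect × element effect + noise (rank-1-ish)
    elements = list(LIMB_ELEMENTS)
    elem_effect = np.exp(rng.uniform(-1.0, 1.5, size=len(elements)))
    sp_effect = {sp: math.exp(rng.normal(2.0, 0.3)) for sp in tips}
    rows, index = [], []
    for cfg_pec, cfg_pel in zip(pec_configs, pel_configs):
        sid = cfg_pel.specimen_id
        sp = sid.rsplit("_ind", 1)[0]
        lengths = sp_effect[sp] * elem_effect * np.exp(
            rng.normal(0, 0.05, size=len(elements))
        )
        rows.append(lengths)
        index.append(sid)
    limb = pd.DataFrame(rows, index=index, columns=elements)
    limb_missing, mask = inject_missing(limb, config.missing_fraction,
                                        seed=config.seed + 13)
    meta = meta.set_index("specimen_id")
    specimens = []
    for cfg_pec, cfg_pel in zip(pec_configs, pel_configs):
        sid = cfg_pel.specimen_id
        sp = sid.rsplit("_ind", 1)[0]
        ll = limb_missing.loc[sid]
        specimens.append(
            SpecimenRecord(
                specimen_id=sid,
                species_id=sp,
                group=groups[sp],
                sex=meta.loc[sid, "sex"],
                limb_lengths={e: v for e, v in ll.items() if np.isfinite(v)},
                pectoral=cfg_pec,
                pelvic=cfg_pel,
            )
        )
    return {
        "specimens": specimens,
        "phylogeny": phy,
        "groups": groups,
        "limb_truth": limb,
        "limb_missing_mask": mask,
        "template": template,
        "sex_shift": sex_shift,
    }
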