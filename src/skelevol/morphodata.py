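"""Specimen-level morphometrics: landmark configurations, generalized
Procrustes analysis, side mirroring, limb-length imputation, assembly of the
species-level trait table, and LDA-based sex assignment.

The measurement model follows standard 3D geometric-morphometric practice:
girdle shape is captured by fixed anatomical landmarks (18 per girdle),
limb morphology by maximum lengths of 15 named long-bone/phalangeal
elements, and body size by the centroid size of the pelvic girdle. The
assembled trait table therefore holds 2*18*3 + 15 + 1 = 124 traits in five
labeled blocks (pectoral shape, pelvic shape, forelimb, hindlimb, size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "Structure",
    "Side",
    "LandmarkConfiguration",
    "SpecimenRecord",
    "TraitTable",
    "GpaResult",
    "SexAssignment",
    "FORELIMB_ELEMENTS",
    "HINDLIMB_ELEMENTS",
    "LIMB_ELEMENTS",
    "centroid_size",
    "gpa_align",
    "procrustes_distance",
    "reflect_axis",
    "mirror_to_left",
    "impute_limb_lengths",
    "build_trait_table",
    "assign_sex_lda",
]


class Structure(str, Enum):
    pectoral = "pectoral"
    pelvic = "pelvic"


class Side(str, Enum):
    left = "left"
    right = "right"


#: Default 15-element limb vocabulary: humerus + ulna + 5 fore-digit
#: elements (4 phalanges + claw of the longest digit) and femur + tibia +
#: 6 hind-digit elements (5 phalanges + claw), matching anole digit-IV
#: phalangeal formulas. Configurable wherever it is consumed.
FORELIMB_ELEMENTS = (
    "humerus",
    "ulna",
    "fore_phalanx_1",
    "fore_phalanx_2",
    "fore_phalanx_3",
    "fore_phalanx_4",
    "fore_claw",
)
HINDLIMB_ELEMENTS = (
    "femur",
    "tibia",
    "hind_phalanx_1",
    "hind_phalanx_2",
    "hind_phalanx_3",
    "hind_phalanx_4",
    "hind_phalanx_5",
    "hind_claw",
)
LIMB_ELEMENTS = FORELIMB_ELEMENTS + HINDLIMB_ELEMENTS

BLOCKS = ("pectoral_shape", "pelvic_shape", "forelimb", "hindlimb", "size")


def centroid_size(coords: np.ndarray) -> float:
    """√(Σ squared landmark distances to the configuration centroid)."""
    coords = np.asarray(coords, dtype=float)
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


@dataclass
class LandmarkConfiguration:
    """One digitized girdle: an ordered set of 3D landmarks (mm)."""

    specimen_id: str
    structure: Structure
    side: Side
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.structure = Structure(self.structure)
        self.side = Side(self.side)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"{self.specimen_id}: coords must be k×3, got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError(f"{self.specimen_id}: non-finite landmark coordinates")
        if centroid_size(self.coords) <= 0:
            raise ValueError(
                f"{self.specimen_id}: degenerate configuration "
                "(all landmarks coincident, zero centroid size)"
            )

    @property
    def centroid_size(self) -> float:
        return centroid_size(self.coords)

    def validate_landmark_count(self, expected: int = 18) -> None:
        if self.coords.shape[0] != expected:
            raise ValueError(
                f"{self.specimen_id}: expected {expected} landmarks, "
                f"got {self.coords.shape[0]}"
            )


@dataclass
class SpecimenRecord:
    """Specimen metadata plus its measured girdles and limb lengths."""

    specimen_id: str
    species_id: str
    group: str
    sex: str = "unknown"
    ecomorph: str | None = None
    limb_lengths: dict[str, float] = field(default_factory=dict)
    pectoral: LandmarkConfiguration | None = None
    pelvic: LandmarkConfiguration | None = None
    element_vocabulary: tuple[str, ...] = LIMB_ELEMENTS

    def __post_init__(self) -> None:
        bad = set(self.limb_lengths) - set(self.element_vocabulary)
        if bad:
            raise ValueError(f"{self.specimen_id}: unknown limb elements {sorted(bad)}")
        for name, v in self.limb_lengths.items():
            if np.isfinite(v) and v <= 0:
                raise ValueError(f"{self.specimen_id}: nonpositive length {name}={v}")


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


def _center_scale(coords: np.ndarray, specimen_id: str = "?") -> tuple[np.ndarray, float]:
    c = coords - coords.mean(axis=0)
    cs = float(np.sqrt((c**2).sum()))
    if cs <= 1e-12:
        raise ValueError(
            f"degenerate configuration for specimen {specimen_id}: zero centroid size"
        )
    return c / cs, cs


def _optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, reflections disallowed) minimizing ||X R − target||."""
    U, _, Vt = np.linalg.svd(X.T @ target)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.eye(X.shape[1])
    D[-1, -1] = d
    return U @ D @ Vt


@dataclass
class GpaResult:
    """Procrustes shape variables from a generalized Procrustes analysis."""

    aligned: list[np.ndarray]
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    specimen_ids: list[str]
    ss_history: list[float] = field(default_factory=list)

    def flat(self) -> np.ndarray:
        """Specimens × (k*3) matrix of shape variables."""
        return np.stack([a.ravel() for a in self.aligned])


def gpa_align(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GpaResult:
    """Generalized Procrustes analysis: translation, scaling to unit
    centroid size, and iterative rotation to the updating mean shape
    (reflections disallowed) until the mean changes by less than ``tol``.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    structures = {c.structure for c in configs}
    if len(structures) > 1:
        raise ValueError(f"mixed structures in one alignment: {structures}")
    k = configs[0].coords.shape[0]
    if any(c.coords.shape[0] != k for c in configs):
        raise ValueError("configurations differ in landmark count")
    ids = [c.specimen_id for c in configs]
    shapes, sizes = [], []
    for c in configs:
        s, cs = _center_scale(c.coords, c.specimen_id)
        shapes.append(s)
        sizes.append(cs)
    shapes = [s @ _optimal_rotation(s, shapes[0]) for s in shapes]
    mean = np.mean(shapes, axis=0)
    mean, _ = _center_scale(mean, "mean")
    it = 0
    ss_history = []
    for it in range(1, max_iter + 1):
        shapes = [s @ _optimal_rotation(s, mean) for s in shapes]
        new_mean = np.mean(shapes, axis=0)
        new_mean, _ = _center_scale(new_mean, "mean")
        ss_history.append(
            float(sum(((s - new_mean) ** 2).sum() for s in shapes))
        )
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if delta < tol:
            break
    return GpaResult(
        aligned=shapes,
        mean_shape=mean,
        centroid_sizes=np.asarray(sizes),
        iterations=it,
        specimen_ids=ids,
        ss_history=ss_history,
    )


def procrustes_distance(A: np.ndarray, B: np.ndarray, align: bool = True) -> float:
    """Partial Procrustes distance between two configurations.

    With ``align=True`` both are centered/scaled and optimally rotated
    first; otherwise the plain Frobenius distance of the given coordinates.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if align:
        A, _ = _center_scale(A)
        B, _ = _center_scale(B)
        A = A @ _optimal_rotation(A, B)
    return float(np.sqrt(((A - B) ** 2).sum()))


# ---------------------------------------------------------------------------
# mirroring


_AXES = {"x": 0, "y": 1, "z": 2}


def reflect_axis(coords: np.ndarray, axis: str = "x") -> np.ndarray:
    """Negate one coordinate axis (an involution; centroid size preserved)."""
    out = np.asarray(coords, dtype=float).copy()
    out[:, _AXES[axis]] *= -1
    return out


def mirror_to_left(
    config: LandmarkConfiguration, axis: str = "x"
) -> LandmarkConfiguration:
    """Mirror a right-sided configuration onto the left side.

    The mirroring axis is the (approximately) midsagittal one and is a
    per-dataset setting; ``x`` by default.
    """
    if Side(config.side) is Side.left:
        raise ValueError(f"{config.specimen_id}: configuration is already left-sided")
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        structure=config.structure,
        side=Side.left,
        coords=reflect_axis(config.coords, axis),
    )


# ---------------------------------------------------------------------------
# limb-length imputation


def _broken_stick_count(eigvals: np.ndarray) -> int:
    p = len(eigvals)
    if p == 0:
        return 0
    bs = np.array([np.sum(1.0 / np.arange(k, p + 1)) / p for k in range(1, p + 1)])
    total = eigvals.sum()
    if total <= 0:
        return 0
    props = eigvals / total
    n = 0
    for k in range(p):
        if props[k] > bs[k]:
            n += 1
        else:
            break
    return n


def impute_limb_lengths(
    table: np.ndarray | pd.DataFrame,
    n_components: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray | pd.DataFrame, bool]:
    """Fill missing limb lengths by iterative low-rank (PPCA-style)
    reconstruction.

    A rank-``n_components`` principal-component model is fit to the current
    completion, missing cells are replaced by the model reconstruction, and
    the two steps alternate to convergence. Observed cells are returned
    bit-identical. If ``n_components`` is None the rank is chosen by the
    broken-stick rule applied to the complete-case correlation matrix (at
    least 1). Returns ``(completed, converged)``.
    """
    is_df = isinstance(table, pd.DataFrame)
    X = np.asarray(table, dtype=float).copy()
    orig = X.copy()
    miss = np.isnan(X)
    if not miss.any():
        return table, True
    if miss.mean() >= 0.5:
        raise ValueError("more than 50% of cells missing")
    if (np.sum(~miss, axis=0) < 2).any():
        raise ValueError("every column needs at least 2 observed values")

    if n_components is None:
        cc = X[~miss.any(axis=1)]
        if cc.shape[0] > 3:
            corr = np.corrcoef(cc, rowvar=False)
            ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
            n_components = max(1, _broken_stick_count(ev))
        else:
            n_components = 1
    n_components = min(n_components, min(X.shape) - 1)

    col_means = np.nanmean(X, axis=0)
    X[miss] = np.take(col_means, np.where(miss)[1])
    scale = max(np.nanstd(orig), 1.0)
    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        s_trunc = s.copy()
        s_trunc[n_components:] = 0.0
        recon = (U * s_trunc) @ Vt + mu
        delta = np.max(np.abs(recon[miss] - X[miss]))
        X[miss] = recon[miss]
        if delta < tol * scale:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"imputation did not converge in {max_iter} iterations; "
            "returning last iterate",
            stacklevel=2,
        )
    X[~miss] = orig[~miss]  # observed cells bit-identical
    if is_df:
        out = table.copy()
        out.iloc[:, :] = X
        return out, converged
    return X, converged


# ---------------------------------------------------------------------------
# trait table


@dataclass
class TraitTable:
    """Species × trait matrix with a 5-way block labeling."""

    values: pd.DataFrame  # index: species ids, columns: trait names
    block_of: dict[str, str]
    standardized: bool = False

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.block_of)
        if missing:
            raise ValueError(f"traits without block labels: {sorted(missing)[:5]}")
        bad = set(self.block_of.values()) - set(BLOCKS)
        if bad:
            raise ValueError(f"unknown blocks: {bad}")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def block_columns(self, *blocks: str) -> list[str]:
        want = set(blocks)
        return [c for c in self.values.columns if self.block_of[c] in want]

    def subset(self, *blocks: str) -> "TraitTable":
        cols = self.block_columns(*blocks)
        return TraitTable(
            values=self.values[cols].copy(),
            block_of={c: self.block_of[c] for c in cols},
            standardized=self.standardized,
        )

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def standardize(self) -> "TraitTable":
        """z-transform every column (mean 0, sd 1); idempotent."""
        v = self.values.copy()
        sd = v.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant traits cannot be standardized: "
                             f"{list(sd.index[sd == 0])[:5]}")
        v = (v - v.mean(axis=0)) / sd
        return TraitTable(values=v, block_of=dict(self.block_of), standardized=True)

    def center(self) -> "TraitTable":
        """Column mean-centering only (original variances preserved)."""
        v = self.values - self.values.mean(axis=0)
        return TraitTable(values=v, block_of=dict(self.block_of),
                          standardized=self.standardized)


def build_trait_table(
    specimens: list[SpecimenRecord],
    pectoral_gpa: GpaResult,
    pelvic_gpa: GpaResult,
    standardize: bool = True,
    males_only: bool = True,
    forelimb_elements: tuple[str, ...] = FORELIMB_ELEMENTS,
) -> TraitTable:
    """Assemble the species-level trait table.

    Per specimen: 54 pectoral + 54 pelvic Procrustes shape variables, 15
    limb lengths divided by the specimen's pelvic centroid size (relative
    limb length), and the pelvic centroid size itself (body-size proxy).
    Values are averaged across a species' specimens (females excluded by
    default; specimens lacking either girdle are dropped), then optionally
    z-standardized across species.
    """
    pec_by_id = {sid: i for i, sid in enumerate(pectoral_gpa.specimen_ids)}
    pel_by_id = {sid: i for i, sid in enumerate(pelvic_gpa.specimen_ids)}
    vocab = specimens[0].element_vocabulary if specimens else LIMB_ELEMENTS
    k_pec = pectoral_gpa.mean_shape.shape[0]
    k_pel = pelvic_gpa.mean_shape.shape[0]
    cols = (
        [f"pec_lm{i+1}_{ax}" for i in range(k_pec) for ax in "xyz"]
        + [f"pel_lm{i+1}_{ax}" for i in range(k_pel) for ax in "xyz"]
        + list(vocab)
        + ["centroid_size"]
    )
    rows: dict[str, list[np.ndarray]] = {}
    for sp in specimens:
        if males_only and sp.sex != "male":
            continue
        if sp.specimen_id not in pec_by_id or sp.specimen_id not in pel_by_id:
            continue
        i_pec = pec_by_id[sp.specimen_id]
        i_pel = pel_by_id[sp.specimen_id]
        pel_cs = pelvic_gpa.centroid_sizes[i_pel]
        limbs = np.array(
            [sp.limb_lengths.get(e, np.nan) for e in vocab], dtype=float
        )
        vec = np.concatenate(
            [
                pectoral_gpa.aligned[i_pec].ravel(),
                pelvic_gpa.aligned[i_pel].ravel(),
                limbs / pel_cs,
                [pel_cs],
            ]
        )
        rows.setdefault(sp.species_id, []).append(vec)

    all_species = sorted({sp.species_id for sp in specimens})
    unusable = [s for s in all_species if s not in rows]
    if unusable:
        warnings.warn(
            f"species with no usable (male, both-girdle) specimens excluded: "
            f"{unusable}",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no usable specimens")
    data = {sp: np.nanmean(np.stack(v), axis=0) for sp, v in sorted(rows.items())}
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    df.index.name = "species"
    block_of = {}
    for c in cols:
        if c.startswith("pec_"):
            block_of[c] = "pectoral_shape"
        elif c.startswith("pel_"):
            block_of[c] = "pelvic_shape"
        elif c in forelimb_elements:
            block_of[c] = "forelimb"
        elif c == "centroid_size":
            block_of[c] = "size"
        else:
            block_of[c] = "hindlimb"
    tt = TraitTable(values=df, block_of=block_of, standardized=False)
    return tt.standardize() if standardize else tt


# ---------------------------------------------------------------------------
# sex assignment


@dataclass
class SexAssignment:
    calls: pd.Series  # per-specimen: male / female / unassigned (or known label)
    posteriors: pd.Series
    validation_accuracy: float | None
    n_train: int
    n_test: int


def assign_sex_lda(
    pelvic_shapes: pd.DataFrame,
    sex: pd.Series,
    posterior_threshold: float = 0.8,
    train_fraction: float = 0.6,
    reduce_dims: bool = True,
    seed: int | None = None,
) -> SexAssignment:
    """Classify specimens of unknown sex from pelvic shape by LDA.

    Specimens with known sex train the discriminant; unknowns are labeled
    only when the winning posterior probability reaches
    ``posterior_threshold`` (else "unassigned"). Held-out accuracy is
    estimated on a ``train_fraction`` / ``1-train_fraction`` split of the
    labeled specimens. When ``reduce_dims`` is set (or required because
    variables ≥ training samples), shape is first reduced to PCA scores
    retaining 95% of variance.
    """
    if not 0 < posterior_threshold <= 1:
        raise ValueError("posterior_threshold must be in (0, 1]")
    X = pelvic_shapes.to_numpy(dtype=float)
    sex = sex.reindex(pelvic_shapes.index)
    labeled = sex.isin(["male", "female"]).to_numpy()
    if min((sex[labeled] == "male").sum(), (sex[labeled] == "female").sum()) < 2:
        raise ValueError("need at least 2 specimens per sex in the training set")
    rng = np.random.default_rng(seed)

    n_labeled = labeled.sum()
    if not reduce_dims and X.shape[1] >= n_labeled:
        raise ValueError(
            "within-class covariance is singular (variables >= labeled "
            "specimens); rerun with reduce_dims=True to fit the LDA on PCA "
            "scores"
        )
    if reduce_dims:
        pca = PCA(n_components=0.95, svd_solver="full")
        Xr = pca.fit_transform(X)
    else:
        Xr = X

    # held-out validation on the labeled specimens
    lab_idx = np.flatnonzero(labeled)
    perm = rng.permutation(lab_idx)
    n_train = max(2, int(round(train_fraction * len(lab_idx))))
    train, test = perm[:n_train], perm[n_train:]
    acc = None
    y = sex.to_numpy()
    if len(test) > 0 and len(np.unique(y[train])) == 2:
        lda_v = LinearDiscriminantAnalysis()
        lda_v.fit(Xr[train], y[train])
        acc = float((lda_v.predict(Xr[test]) == y[test]).mean())

    lda = LinearDiscriminantAnalysis()
    lda.fit(Xr[lab_idx], y[lab_idx])
    proba = lda.predict_proba(Xr)
    # a finite training set never justifies exact certainty
    proba = np.clip(proba, 1e-12, 1 - 1e-12)
    best = proba.max(axis=1)
    pred = lda.classes_[proba.argmax(axis=1)]
    calls = []
    for i, known in enumerate(y):
        if known in ("male", "female"):
            calls.append(known)
        elif best[i] >= posterior_threshold:
            calls.append(str(pred[i]))
        else:
            calls.append("unassigned")
    return SexAssignment(
        calls=pd.Series(calls, index=pelvic_shapes.index, name="sex_call"),
        posteriors=pd.Series(best, index=pelvic_shapes.index, name="posterior"),
        validation_accuracy=acc,
        n_train=len(train),
        n_test=len(test),
    )
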