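"""Module detection, eigengenes, merging, and module/pathway-trait relations.

Modules are detected by average-linkage hierarchical clustering on the
topological-overlap dissimilarity (1 - TOM), a static branch cut, a minimum
module size (default 30), and a module-membership (kME) reattachment pass.
Each module is summarized per sample by its eigengene — the first principal
component of the standardized member profiles — which is then correlated
with clinical traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .netbuild import ExpressionMatrix, OverlapMatrix

MIN_MODULE_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.99
DEFAULT_MERGE_THRESHOLD = 0.25
DEFAULT_KME_REATTACH = 0.3
TRAIT_P_FLAG = 0.01


@dataclass
class ModuleAssignment:
    """Feature -> module labels; 0 marks unassigned ('grey') features.

    Nonzero labels are renumbered 1..M in order of decreasing module size.
    """

    feature_ids: list[str]
    labels: np.ndarray
    dendrogram: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def members(self, module_id: int) -> list[str]:
        return [f for f, l in zip(self.feature_ids, self.labels) if l == module_id]

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels.tolist()) - {0})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_ids, "module": self.labels})


@dataclass
class EigengeneMatrix:
    """Per-module, per-sample summary profiles (modules x samples).

    Each eigengene has unit variance and is sign-oriented so that its
    correlation with the module's mean standardized expression is >= 0,
    making downstream trait correlations sign-deterministic.
    """

    module_ids: list[int]
    sample_ids: list[str]
    values: np.ndarray
    variance_explained: dict[int, float] = field(default_factory=dict)

    def eigengene(self, module_id: int) -> np.ndarray:
        return self.values[self.module_ids.index(module_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[f"ME{m}" for m in self.module_ids],
            columns=self.sample_ids,
        )


@dataclass
class TraitTable:
    """Per-sample clinical traits and covariates for one cohort."""

    data: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in trait table")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def numeric_traits(self) -> list[str]:
        skip = {"age", "BMI", "batch"}
        return [
            c
            for c in self.data.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def group_indicator(self) -> pd.Series:
        return (self.data["group"] == "case").astype(float)


# ---------------------------------------------------------------------------
# dendrogram and branch cutting


def build_dendrogram(tom: OverlapMatrix) -> np.ndarray:
    """Average-linkage tree on the overlap dissimilarity 1 - TOM."""
    if len(tom.feature_ids) < 2:
        raise ValueError("need at least 2 features to cluster")
    d = tom.dissimilarity()
    condensed = squareform(np.clip((d + d.T) / 2.0, 0.0, None), checks=False)
    return hierarchy.linkage(condensed, method="average")


def cut_modules(
    dendrogram: np.ndarray,
    feature_ids: list[str],
    min_size: int = MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    X: ExpressionMatrix | None = None,
    kme_reattach: float = DEFAULT_KME_REATTACH,
) -> ModuleAssignment:
    """Static branch cut with minimum size and optional kME reattachment.

    The tree is cut at ``cut_height`` times the maximum merge height;
    clusters smaller than ``min_size`` are relabeled 0. When an expression
    matrix is supplied, unassigned features are attached to the module
    maximizing |kME| provided |kME| >= ``kme_reattach``.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must be in (0, 1]")
    max_h = dendrogram[:, 2].max()
    raw = hierarchy.fcluster(dendrogram, t=cut_height * max_h, criterion="distance")
    labels = _enforce_min_size(raw, min_size)
    assignment = ModuleAssignment(
        feature_ids=list(feature_ids),
        labels=labels,
        dendrogram=dendrogram,
        params={
            "min_size": min_size,
            "cut_height": cut_height,
            "kme_reattach": kme_reattach,
        },
    )
    if X is not None and assignment.module_ids and (labels == 0).any():
        assignment = _reattach_by_kme(X, assignment, kme_reattach)
    assignment.labels = _renumber_by_size(assignment.labels)
    return assignment


def _enforce_min_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    labels = np.zeros_like(raw)
    next_id = 1
    counts = pd.Series(raw).value_counts()
    for cl in counts.index:
        if counts[cl] >= min_size:
            labels[raw == cl] = next_id
            next_id += 1
    return labels


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    counts = pd.Series(labels[labels != 0]).value_counts()
    # stable tie-break on the old label keeps renumbering deterministic
    ordered = sorted(counts.index, key=lambda m: (-counts[m], m))
    for new, old in enumerate(ordered, start=1):
        out[labels == old] = new
    return out


def _reattach_by_kme(
    X: ExpressionMatrix, assignment: ModuleAssignment, threshold: float
) -> ModuleAssignment:
    egs = module_eigengenes(X, assignment)
    kme = module_membership(X, egs)  # features x modules
    labels = assignment.labels.copy()
    unassigned = np.where(labels == 0)[0]
    abs_kme = np.abs(kme.to_numpy())
    for i in unassigned:
        j = int(np.argmax(abs_kme[i]))
        if abs_kme[i, j] >= threshold:
            labels[i] = egs.module_ids[j]
    return ModuleAssignment(
        feature_ids=assignment.feature_ids,
        labels=labels,
        dendrogram=assignment.dendrogram,
        params=assignment.params,
    )


# ---------------------------------------------------------------------------
# eigengenes


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def _first_pc(std_values: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component across samples of standardized member rows.

    Returns the unit-variance, sign-oriented score vector (one value per
    sample) and the fraction of variance it explains (leading eigenvalue of
    the member covariance over its trace).
    """
    u, s, vt = np.linalg.svd(std_values, full_matrices=False)
    pc = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    sd = pc.std()
    if sd > 0:
        pc = pc / sd
    mean_profile = std_values.mean(axis=0)
    if np.dot(pc, mean_profile - mean_profile.mean()) < 0:
        pc = -pc
    return pc, var_explained


def module_eigengenes(
    X: ExpressionMatrix, assignment: ModuleAssignment
) -> EigengeneMatrix:
    """First principal component of each module's standardized members."""
    ids = assignment.module_ids
    if not ids:
        raise ValueError("no modules to summarize")
    feat_index = {f: i for i, f in enumerate(X.feature_ids)}
    values = np.zeros((len(ids), X.n_samples))
    varexp: dict[int, float] = {}
    for row, m in enumerate(ids):
        members = assignment.members(m)
        missing = [f for f in members if f not in feat_index]
        if missing:
            raise ValueError("module members absent from expression: " + ", ".join(missing))
        if len(members) < 2:
            raise ValueError(f"module {m} has fewer than 2 members")
        sub = _standardize_rows(X.values[[feat_index[f] for f in members]])
        values[row], varexp[m] = _first_pc(sub)
    return EigengeneMatrix(
        module_ids=list(ids),
        sample_ids=list(X.sample_ids),
        values=values,
        variance_explained=varexp,
    )


def merge_modules(
    X: ExpressionMatrix,
    assignment: ModuleAssignment,
    eigengenes: EigengeneMatrix | None = None,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
) -> ModuleAssignment:
    """Merge module pairs whose eigengene dissimilarity 1 - cor is below
    ``merge_threshold``, greedily smallest-dissimilarity-first, recomputing
    eigengenes after each merge until no pair qualifies."""
    labels = assignment.labels.copy()
    if merge_threshold <= 0:
        return assignment
    while True:
        current = ModuleAssignment(assignment.feature_ids, labels, assignment.dendrogram, assignment.params)
        ids = current.module_ids
        if len(ids) < 2:
            break
        egs = module_eigengenes(X, current)
        r = np.corrcoef(egs.values)
        diss = 1.0 - r
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_threshold:
            break
        a, b = ids[i], ids[j]
        keep, drop = min(a, b), max(a, b)
        labels[labels == drop] = keep
    labels = _renumber_by_size(labels)
    return ModuleAssignment(
        feature_ids=assignment.feature_ids,
        labels=labels,
        dendrogram=assignment.dendrogram,
        params={**assignment.params, "merge_threshold": merge_threshold},
    )


# ---------------------------------------------------------------------------
# trait relations


def correlation_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided Student-t p at n-2 degrees of freedom."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, np.finfo(float).tiny
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(max(p, np.finfo(float).tiny))


def module_trait_table(
    eigengenes: EigengeneMatrix,
    traits: TraitTable,
    trait_names: list[str] | None = None,
    p_flag: float = TRAIT_P_FLAG,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each clinical trait.

    Modules with p below ``p_flag`` (default 0.01) are flagged as
    trait-correlated.
    """
    shared = [s for s in eigengenes.sample_ids if s in set(traits.sample_ids)]
    if len(shared) < 10:
        raise ValueError("need at least 10 overlapping samples")
    names = trait_names if trait_names is not None else traits.numeric_traits()
    col = {s: i for i, s in enumerate(eigengenes.sample_ids)}
    idx = [col[s] for s in shared]
    rows = []
    for trait in names:
        y = traits.data.loc[shared, trait].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValueError(f"trait {trait!r} is constant")
        for row_i, m in enumerate(eigengenes.module_ids):
            r, p = correlation_with_p(eigengenes.values[row_i, idx], y)
            rows.append(
                {
                    "module": m,
                    "trait": trait,
                    "r": r,
                    "p": p,
                    "n": len(shared),
                    "significant": p < p_flag,
                }
            )
    return pd.DataFrame(rows)


def module_membership(X: ExpressionMatrix, eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """kME: correlation of every feature profile with every module eigengene."""
    xs = _standardize_rows(X.values)
    es = _standardize_rows(eigengenes.values)
    kme = xs @ es.T / X.n_samples
    return pd.DataFrame(
        kme, index=X.feature_ids, columns=[f"ME{m}" for m in eigengenes.module_ids]
    )


def membership_and_significance(
    X: ExpressionMatrix,
    eigengenes: EigengeneMatrix,
    trait: np.ndarray,
    assignment: ModuleAssignment | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """kME matrix, trait significance GS_i = |cor(x_i, trait)|, and soft
    connectivity (sum of a feature's correlations with the other members of
    its module; NaN for unassigned features)."""
    kme = module_membership(X, eigengenes)
    trait = np.asarray(trait, dtype=float)
    xs = _standardize_rows(X.values)
    ts = (trait - trait.mean()) / trait.std()
    gs = pd.Series(np.abs(xs @ ts / X.n_samples), index=X.feature_ids, name="GS")
    soft = pd.Series(np.nan, index=X.feature_ids, name="soft_connectivity")
    if assignment is not None:
        r = np.corrcoef(X.values)
        for m in assignment.module_ids:
            idx = [i for i, l in enumerate(assignment.labels) if l == m]
            sub = r[np.ix_(idx, idx)]
            soft.iloc[idx] = sub.sum(axis=1) - 1.0
    return kme, gs, soft


def pathway_sample_scores(X: ExpressionMatrix, members: list[str]) -> pd.Series:
    """Per-sample pathway score: first principal component of the
    standardized member submatrix, sign-oriented like an eigengene.

    Collapses the members x samples block to one value per sample, so a
    pathway ends up with a single score vector that can be correlated with
    severity scales.
    """
    feat_index = {f: i for i, f in enumerate(X.feature_ids)}
    present = [f for f in members if f in feat_index]
    missing = [f for f in members if f not in feat_index]
    if len(present) < 2:
        raise ValueError(
            "need >= 2 pathway members present in expression; missing: "
            + ", ".join(missing)
        )
    sub = _standardize_rows(X.values[[feat_index[f] for f in sorted(present)]])
    pc, _ = _first_pc(sub)
    return pd.Series(pc, index=X.sample_ids, name="score")
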