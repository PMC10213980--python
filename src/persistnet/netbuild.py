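"""Soft-thresholded correlation networks and topological overlap.

Builds, per cohort, an unsigned weighted co-expression network
``a_ij = |cor(x_i, x_j)|**beta`` from a features x samples abundance matrix,
transforms it into the topological overlap matrix (TOM), and combines TOMs
across cohorts into a consensus by the component-wise ("parallel") minimum,
so that the consensus overlap of two features is only large when it is large
in every cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BETA = 4.0


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table for one cohort.

    ``values[i, j]`` is the abundance of ``feature_ids[i]`` in
    ``sample_ids[j]``. Missing values are not allowed at the network stage;
    validation raises rather than silently using pairwise-complete
    correlations, which would break TOM guarantees.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    cohort: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = pd.Index(self.feature_ids)
            raise ValueError(
                "duplicate feature ids: "
                + ", ".join(sorted(set(dupes[dupes.duplicated()])))
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort: str = "") -> "ExpressionMatrix":
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            cohort=cohort,
        )

    def validate_complete(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "expression matrix contains missing/non-finite values; "
                "impute first (e.g. impute='mean') before network construction"
            )

    def impute_mean(self) -> "ExpressionMatrix":
        """Replace missing values by the feature's mean over observed samples."""
        vals = self.values.copy()
        row_mean = np.nanmean(vals, axis=1)
        idx = np.where(~np.isfinite(vals))
        vals[idx] = row_mean[idx[0]]
        return ExpressionMatrix(self.feature_ids, self.sample_ids, vals, self.cohort)


@dataclass
class Adjacency:
    """Symmetric unsigned adjacency ``|r|**beta`` with unit diagonal."""

    feature_ids: list[str]
    values: np.ndarray
    beta: float = DEFAULT_BETA
    mode: str = "unsigned"

    @property
    def connectivity(self) -> np.ndarray:
        """Soft connectivity k_i = sum_{j != i} a_ij."""
        return self.values.sum(axis=1) - np.diag(self.values)


@dataclass
class OverlapMatrix:
    """Topological overlap matrix; ``kind`` is 'single' or 'consensus'."""

    feature_ids: list[str]
    values: np.ndarray
    kind: str = "single"

    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


def correlation_matrix(X: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation across samples for every feature pair.

    Raises for zero-variance features by name: their correlation is
    undefined and would propagate NaN through the whole network.
    """
    X.validate_complete()
    sd = X.values.std(axis=1)
    if np.any(sd == 0):
        bad = [X.feature_ids[i] for i in np.where(sd == 0)[0]]
        raise ValueError("zero-variance features: " + ", ".join(bad))
    r = np.corrcoef(X.values)
    return np.clip(r, -1.0, 1.0)


def adjacency_from_expression(
    X: ExpressionMatrix, beta: float = DEFAULT_BETA, mode: str = "unsigned"
) -> Adjacency:
    """Unsigned soft-thresholded adjacency ``a_ij = |cor(x_i, x_j)|**beta``.

    ``mode='signed'`` uses ``((1 + r)/2)**beta`` instead; the unsigned form
    is the default network type here.
    """
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = correlation_matrix(X)
    if mode == "unsigned":
        a = np.abs(r) ** beta
    elif mode == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(a, 1.0)
    return Adjacency(feature_ids=list(X.feature_ids), values=a, beta=beta, mode=mode)


def soft_threshold_scan(
    X: ExpressionMatrix, powers: list[float], n_bins: int = 10, mode: str = "unsigned"
) -> pd.DataFrame:
    """Scale-free topology fit index and mean connectivity per candidate power.

    For each power, connectivities are binned into ``n_bins`` equal-count
    bins and R^2 of log10(mean p(k)) on log10(mean k) is computed; the fit
    index is signed negative when the slope is positive (a rising degree
    distribution is the opposite of scale-free).
    """
    if not powers:
        raise ValueError("powers must be nonempty")
    if X.n_features < 2 * n_bins:
        raise ValueError(
            f"need at least {2 * n_bins} features for {n_bins}-bin scale-free fit"
        )
    r = correlation_matrix(X)
    rows = []
    for beta in powers:
        if mode == "unsigned":
            a = np.abs(r) ** beta
        else:
            a = ((1.0 + r) / 2.0) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append(
            {
                "power": beta,
                "sft_r2": _scale_free_fit(k, n_bins),
                "mean_connectivity": float(k.mean()),
                "median_connectivity": float(np.median(k)),
                "max_connectivity": float(k.max()),
            }
        )
    return pd.DataFrame(rows)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of the log-log degree-distribution fit over equal-count bins.

    Each bin's p(k) is the empirical density (fraction of nodes divided by
    the bin's connectivity span), so equal-count bins still trace the shape
    of the degree distribution.
    """
    order = np.argsort(k)
    bins = np.array_split(order, n_bins)
    mean_k = np.array([k[b].mean() for b in bins])
    width = np.array([k[b].max() - k[b].min() for b in bins])
    frac = np.array([len(b) / len(k) for b in bins])
    with np.errstate(divide="ignore", invalid="ignore"):
        p_k = np.where(width > 0, frac / width, np.nan)
    keep = (mean_k > 0) & np.isfinite(p_k) & (p_k > 0)
    if keep.sum() < 3:
        return 0.0
    x = np.log10(mean_k[keep])
    y = np.log10(p_k[keep])
    if np.allclose(x, x[0]):
        return 0.0
    slope, _ = np.polyfit(x, y, 1)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return -r2 if slope > 0 else r2


def topological_overlap(adj: Adjacency) -> OverlapMatrix:
    """Topological overlap: shared-neighbor strength blended with adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu.
    Diagonal is set to 1 by convention (dissimilarity diagonal 0).
    """
    a = np.asarray(adj.values, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    # With zero diagonal, (a0 @ a0)_ij sums over all u excluding the i and j
    # terms automatically, which is exactly L_ij.
    L = a0 @ a0
    k = a0.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a0) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return OverlapMatrix(feature_ids=list(adj.feature_ids), values=tom, kind="single")


def consensus_overlap(toms: list[OverlapMatrix]) -> OverlapMatrix:
    """Component-wise minimum of per-cohort TOMs."""
    if len(toms) < 2:
        raise ValueError("consensus requires at least 2 overlap matrices")
    ref = toms[0].feature_ids
    for t in toms[1:]:
        if t.feature_ids != ref:
            diff = set(t.feature_ids) ^ set(ref)
            raise ValueError(
                "feature sets differ between overlap matrices; symmetric "
                "difference: " + ", ".join(sorted(diff)[:20])
            )
    vals = np.minimum.reduce([t.values for t in toms])
    return OverlapMatrix(feature_ids=list(ref), values=vals, kind="consensus")
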