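"""Per-cohort differential abundance, cross-cohort meta-analysis, and the
persistent-feature intersection.

The persistence filter intersects three routes: (1) membership in preserved,
trait-correlated modules; (2) per-feature FDR in the training cohort
(q < 0.1); (3) meta-analytic significance across cohorts (weighted-Z
combined p with Benjamini-Yekutieli correction at q < 0.05, and/or a
DerSimonian-Laird random-effects model), further restricted to features
whose effect direction is identical in every cohort at p < 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netbuild import ExpressionMatrix
from .modules import TraitTable

logger = logging.getLogger(__name__)

DIRECTION_P = 0.1
TRAINING_Q = 0.1
META_Q = 0.05


@dataclass
class CohortDEResult:
    """Per-feature covariate-adjusted case-vs-control statistics for one cohort."""

    cohort: str
    table: pd.DataFrame  # indexed by feature id
    n_case: int
    n_control: int
    covariates: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.n_case + self.n_control


@dataclass
class MetaResult:
    """Cross-cohort combined statistics per feature."""

    table: pd.DataFrame  # indexed by feature id
    cohorts: list[str] = field(default_factory=list)


@dataclass
class PersistentSet:
    """Features passing every enabled persistence route, with provenance."""

    table: pd.DataFrame  # indexed by feature id, boolean route columns
    rule: str

    @property
    def features(self) -> list[str]:
        return [str(f) for f in self.table.index[self.table["persistent"]]]


# ---------------------------------------------------------------------------
# normalization


def median_normalize(X: ExpressionMatrix, log2: bool = False) -> ExpressionMatrix:
    """Median signal normalization: scale each sample so its median equals
    the global median of sample medians, removing inter-sample level shifts.

    ``log2=True`` applies a log2 transform after scaling (requires positive
    values).
    """
    vals = X.values.copy()
    medians = np.median(vals, axis=0)
    if np.any(medians <= 0):
        raise ValueError("median normalization requires positive sample medians")
    target = np.median(medians)
    vals = vals * (target / medians)
    if log2:
        if np.any(vals <= 0):
            raise ValueError("log2 transform requires positive values")
        vals = np.log2(vals)
    return ExpressionMatrix(list(X.feature_ids), list(X.sample_ids), vals, X.cohort)


# ---------------------------------------------------------------------------
# per-cohort differential expression


def _design_matrix(
    traits: TraitTable, samples: list[str], covariates: list[str]
) -> np.ndarray:
    group = traits.group_indicator().loc[samples].to_numpy()
    cols = [np.ones(len(samples)), group]
    for c in covariates:
        v = traits.data.loc[samples, c]
        if not pd.api.types.is_numeric_dtype(v):
            v = pd.Categorical(v).codes
        cols.append(np.asarray(v, dtype=float))
    D = np.column_stack(cols)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        bad = []
        for j, name in enumerate(["intercept", "group"] + list(covariates)):
            others = np.delete(D, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise ValueError("collinear design columns: " + ", ".join(bad))
    return D


def differential_expression(
    X: ExpressionMatrix,
    traits: TraitTable,
    covariates: list[str] | None = None,
    hedges_correction: bool = False,
) -> CohortDEResult:
    """OLS of standardized abundance on group + covariates, per feature.

    Returns the group coefficient (case minus control on the standardized
    scale), its SE, t and two-sided p from the residual degrees of freedom,
    and Cohen's d (adjusted group-mean difference over the pooled residual
    SD; Hedges' small-sample correction optional).
    """
    covariates = list(covariates or [])
    samples = [s for s in X.sample_ids if s in set(traits.sample_ids)]
    groups = traits.data.loc[samples, "group"]
    n_case = int((groups == "case").sum())
    n_control = int((groups == "control").sum())
    if min(n_case, n_control) < 3:
        raise ValueError("need at least 3 samples per group")
    D = _design_matrix(traits, samples, covariates)

    col = {s: i for i, s in enumerate(X.sample_ids)}
    Y = X.values[:, [col[s] for s in samples]]
    mu = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Y = ((Y - mu) / sd).T  # samples x features

    n, k = D.shape
    dof = n - k
    XtX_inv = np.linalg.inv(D.T @ D)
    B = XtX_inv @ D.T @ Y  # k x features
    resid = Y - D @ B
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    coef = B[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)

    # Cohen's d: adjusted mean difference over the pooled residual SD
    pooled_sd = np.sqrt(sigma2)
    pooled_sd[pooled_sd == 0] = np.nan
    d = coef / pooled_sd
    if hedges_correction:
        d = d * (1.0 - 3.0 / (4.0 * (n_case + n_control) - 9.0))
    # sampling variance of d (standard two-group approximation)
    d_var = (n_case + n_control) / (n_case * n_control) + d**2 / (
        2.0 * (n_case + n_control)
    )

    table = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "t": t,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "d": d,
            "d_var": d_var,
        },
        index=pd.Index(X.feature_ids, name="feature_id"),
    )
    return CohortDEResult(
        cohort=X.cohort,
        table=table,
        n_case=n_case,
        n_control=n_control,
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# combining p values and effect sizes


def stouffer_combine(
    p: np.ndarray, sign: np.ndarray, n: np.ndarray
) -> tuple[float, float]:
    """Weighted-Z combination of two-sided p-values with direction.

    Each cohort contributes Z_k = sign_k * Phi^-1(1 - p_k/2), weighted by
    w_k = sqrt(n_k); Z = sum(w Z) / sqrt(sum w^2), and the combined p is the
    two-sided normal tail of Z. Zero p-values are clamped to the smallest
    representable positive float with a warning.
    """
    p = np.asarray(p, dtype=float)
    sign = np.asarray(sign, dtype=float)
    n = np.asarray(n, dtype=float)
    if not (len(p) == len(sign) == len(n)):
        raise ValueError("p, sign, n must have equal length")
    if np.any((sign != 1) & (sign != -1)):
        raise ValueError("signs must be +1 or -1")
    if np.any(p == 0):
        logger.warning("p=0 input clamped to smallest representable float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in (0, 1]")
    z = sign * stats.norm.isf(p / 2.0)
    w = np.sqrt(n)
    z_comb = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p_comb = float(2.0 * stats.norm.sf(abs(z_comb)))
    return z_comb, max(p_comb, np.finfo(float).tiny)


def adjust_pvalues(p: np.ndarray, method: str = "BY") -> np.ndarray:
    """Multiple-testing adjustment: BY, BH step-up, or Bonferroni.

    Output order matches input order (rank-based step-up applied internally).
    """
    p = np.asarray(p, dtype=float)
    codes = {"BY": "fdr_by", "BH": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in codes:
        raise ValueError(f"unknown method {method!r}; use BY, BH or bonferroni")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method=codes[method])[1]


def random_effects_meta(
    d: np.ndarray, variance: np.ndarray
) -> dict[str, float]:
    """DerSimonian-Laird random-effects pooling with Cochran's Q.

    Fixed weights w_k = 1/v_k give Q = sum w_k (d_k - d_FE)^2;
    tau^2 = max(0, (Q - (K-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(v_k + tau^2) give the pooled effect, its SE, z and two-sided
    p; Q is referred to chi-square with K-1 degrees of freedom.
    """
    d = np.asarray(d, dtype=float)
    v = np.asarray(variance, dtype=float)
    K = len(d)
    if K < 2:
        raise ValueError("random-effects meta-analysis requires K >= 2 cohorts")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / v
    d_fe = np.sum(w * d) / np.sum(w)
    Q = float(np.sum(w * (d - d_fe) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (K - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * d) / np.sum(w_re))
    se = float(1.0 / np.sqrt(np.sum(w_re)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q_p = float(stats.chi2.sf(Q, df=K - 1))
    return {
        "d": pooled,
        "se": se,
        "z": z,
        "p": max(p, np.finfo(float).tiny),
        "Q": Q,
        "Q_df": K - 1,
        "Q_p": q_p,
        "tau2": tau2,
    }


def direction_consistency(
    results: list[CohortDEResult], p_threshold: float = DIRECTION_P
) -> pd.Series:
    """Flag features whose effect sign is identical in every cohort and at
    least somewhat significant (p below ``p_threshold``) in each."""
    if len(results) < 2:
        raise ValueError("direction consistency requires >= 2 cohorts")
    idx = results[0].table.index
    signs = np.column_stack([np.sign(r.table.loc[idx, "coef"]) for r in results])
    ps = np.column_stack([r.table.loc[idx, "p"] for r in results])
    same_sign = (signs == signs[:, [0]]).all(axis=1) & (signs[:, 0] != 0)
    all_sig = (ps < p_threshold).all(axis=1)
    return pd.Series(same_sign & all_sig, index=idx, name="direction_consistent")


def meta_analyze(
    results: list[CohortDEResult],
    adjust_method: str = "BY",
    p_threshold: float = DIRECTION_P,
) -> MetaResult:
    """Per-feature Stouffer + BY and DerSimonian-Laird REM across cohorts."""
    if len(results) < 2:
        raise ValueError("meta-analysis requires >= 2 cohorts")
    idx = results[0].table.index
    for r in results[1:]:
        if not r.table.index.equals(idx):
            raise ValueError("cohort DE results must share the feature universe")
    ps = np.column_stack([r.table["p"] for r in results])
    signs = np.sign(np.column_stack([r.table["coef"] for r in results]))
    signs[signs == 0] = 1
    ns = np.array([r.n for r in results], dtype=float)
    ds = np.column_stack([r.table["d"] for r in results])
    vs = np.column_stack([r.table["d_var"] for r in results])
    K = len(results)
    tiny = np.finfo(float).tiny

    # vectorized weighted-Z combination (features x cohorts)
    ps_c = np.clip(ps, tiny, 1.0)
    z_k = signs * stats.norm.isf(ps_c / 2.0)
    w = np.sqrt(ns)
    z_comb = (z_k * w).sum(axis=1) / np.sqrt((w**2).sum())
    p_comb = np.clip(2.0 * stats.norm.sf(np.abs(z_comb)), tiny, 1.0)

    # vectorized DerSimonian-Laird pooling
    wf = 1.0 / vs
    sw = wf.sum(axis=1)
    d_fe = (wf * ds).sum(axis=1) / sw
    Q = (wf * (ds - d_fe[:, None]) ** 2).sum(axis=1)
    denom = sw - (wf**2).sum(axis=1) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(denom > 0, np.maximum(0.0, (Q - (K - 1)) / denom), 0.0)
    w_re = 1.0 / (vs + tau2[:, None])
    pooled = (w_re * ds).sum(axis=1) / w_re.sum(axis=1)
    se = 1.0 / np.sqrt(w_re.sum(axis=1))
    rem_z = pooled / se
    rem_p = np.clip(2.0 * stats.norm.sf(np.abs(rem_z)), tiny, 1.0)
    q_p = stats.chi2.sf(Q, df=K - 1)

    table = pd.DataFrame(
        {
            "stouffer_z": z_comb,
            "stouffer_p": p_comb,
            "rem_d": pooled,
            "rem_se": se,
            "rem_z": rem_z,
            "rem_p": rem_p,
            "Q": Q,
            "Q_df": K - 1,
            "Q_p": q_p,
            "tau2": tau2,
        },
        index=idx,
    )
    table["stouffer_q"] = adjust_pvalues(table["stouffer_p"].to_numpy(), adjust_method)
    table["direction_consistent"] = direction_consistency(results, p_threshold)
    return MetaResult(table=table, cohorts=[r.cohort for r in results])


# ---------------------------------------------------------------------------
# the persistence intersection


def persistent_feature_set(
    module_route: set[str],
    training_de: CohortDEResult,
    meta: MetaResult,
    training_q: float = TRAINING_Q,
    training_adjust: str = "BH",
    meta_q: float = META_Q,
    rem_p: float = 0.05,
    meta_rule: str = "or",
    use_module_route: bool = True,
) -> PersistentSet:
    """Intersect the persistence routes over a shared feature universe.

    Default rule: member of a preserved, trait-correlated module AND
    training-cohort FDR q < ``training_q`` AND (Stouffer BY q < ``meta_q``
    OR REM p < ``rem_p``) AND direction-consistent. ``meta_rule='and'``
    requires both meta methods; ``use_module_route=False`` drops route 1
    (e.g. when preservation was not run).
    """
    idx = training_de.table.index
    if not meta.table.index.equals(idx):
        raise ValueError("training DE and meta results must share the feature universe")
    unknown = module_route - set(idx)
    if unknown:
        raise ValueError(
            "module-route features outside the universe: " + ", ".join(sorted(unknown)[:10])
        )
    if meta_rule not in ("or", "and"):
        raise ValueError("meta_rule must be 'or' or 'and'")

    in_module = pd.Series([f in module_route for f in idx], index=idx)
    train_q = pd.Series(
        adjust_pvalues(training_de.table["p"].to_numpy(), training_adjust), index=idx
    )
    train_pass = train_q < training_q
    stouffer_pass = meta.table["stouffer_q"] < meta_q
    rem_pass = meta.table["rem_p"] < rem_p
    meta_pass = (stouffer_pass | rem_pass) if meta_rule == "or" else (stouffer_pass & rem_pass)
    direction_pass = meta.table["direction_consistent"]

    routes = {
        "training_route": train_pass,
        "stouffer_route": stouffer_pass,
        "rem_route": rem_pass,
        "meta_route": meta_pass,
        "direction_route": direction_pass,
    }
    persistent = train_pass & meta_pass & direction_pass
    rule = f"training_q<{training_q}({training_adjust}) & meta({meta_rule}: " \
           f"stouffer_q<{meta_q} | rem_p<{rem_p}) & direction"
    if use_module_route:
        routes = {"module_route": in_module, **routes}
        persistent = persistent & in_module
        rule = "module & " + rule
    table = pd.DataFrame({**routes, "training_q": train_q}, index=idx)
    table["persistent"] = persistent
    return PersistentSet(table=table, rule=rule)
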