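"""Permutation-based module preservation between cohorts.

Modules defined in a reference cohort are scored in a test cohort with two
statistics — density (mean within-module adjacency in the test network) and
connectivity (correlation of reference and test intramodular connectivity
over members) — each converted to a permutation Z against random feature
sets of the same size, and summarized as Z_summary = median of the two.
Z_summary > 10 is classified as highly preserved, 5-10 as moderately
preserved, below 5 as weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netbuild import Adjacency, ExpressionMatrix, adjacency_from_expression
from .modules import ModuleAssignment

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 300
Z_HIGH = 10.0
Z_MODERATE = 5.0


@dataclass
class PreservationResult:
    """Per-module preservation statistics for one (reference, test) pair."""

    table: pd.DataFrame  # module, statistic rows
    n_permutations: int
    seed: int
    test_cohort: str = ""

    def zsummary(self, module_id: int) -> float:
        sub = self.table[self.table["module"] == module_id]
        return float(sub["Z_summary"].iloc[0])

    def classification(self, module_id: int) -> str:
        sub = self.table[self.table["module"] == module_id]
        return str(sub["class"].iloc[0])


def classify_zsummary(z: float) -> str:
    if z > Z_HIGH:
        return "high"
    if z >= Z_MODERATE:
        return "moderate"
    return "weak"


def preservation_statistics(
    member_idx: np.ndarray,
    test_adj: np.ndarray,
    ref_adj: np.ndarray,
) -> tuple[float, float]:
    """Density and connectivity preservation of one module.

    ``member_idx`` indexes the module's features in both adjacency matrices
    (shared feature universe). Density is the mean off-diagonal test
    adjacency among members; the connectivity statistic is the Pearson
    correlation between reference and test intramodular connectivity (kIM)
    vectors over the members.
    """
    m = len(member_idx)
    if m < 3:
        raise ValueError("module must have at least 3 members")
    sub_test = test_adj[np.ix_(member_idx, member_idx)]
    sub_ref = ref_adj[np.ix_(member_idx, member_idx)]
    density = float((sub_test.sum() - np.trace(sub_test)) / (m * (m - 1)))
    kim_test = sub_test.sum(axis=1) - np.diag(sub_test)
    kim_ref = sub_ref.sum(axis=1) - np.diag(sub_ref)
    # guard with a tolerance: a numerically constant kIM vector would make
    # the correlation an artifact of floating-point round-off
    tol = 1e-10
    if (
        kim_test.std() <= tol * max(1.0, abs(kim_test.mean()))
        or kim_ref.std() <= tol * max(1.0, abs(kim_ref.mean()))
    ):
        conn = 0.0
    else:
        conn = float(np.corrcoef(kim_ref, kim_test)[0, 1])
    return density, conn


def preservation_zsummary(
    ref_assignment: ModuleAssignment,
    ref_X: ExpressionMatrix,
    test_X: ExpressionMatrix,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    beta: float | None = None,
    null_pool: str = "all",
) -> PreservationResult:
    """Permutation Z_summary of every reference module in the test cohort.

    The null distribution draws, for each permutation, a uniform random
    feature set of the module's size. ``null_pool='all'`` (default) draws
    from the whole feature universe, which is what permuting module labels
    over the entire network amounts to; ``null_pool='assigned'`` restricts
    draws to nonzero-module features, a stricter null that penalizes modules
    merely for being denser than the module-bearing background. Adjacencies
    are computed at the same soft power used for network construction
    (default beta from netbuild).
    """
    if n_permutations < 50:
        logger.warning(
            "n_permutations=%d is low; permutation Z estimates will be noisy",
            n_permutations,
        )
    if ref_X.feature_ids != test_X.feature_ids:
        raise ValueError("reference and test cohorts must share the feature universe")
    kwargs = {} if beta is None else {"beta": beta}
    ref_adj = adjacency_from_expression(ref_X, **kwargs).values
    test_adj = adjacency_from_expression(test_X, **kwargs).values

    if null_pool == "all":
        pool = np.arange(len(ref_assignment.labels))
    elif null_pool == "assigned":
        pool = np.where(ref_assignment.labels != 0)[0]
    else:
        raise ValueError("null_pool must be 'all' or 'assigned'")
    rng = np.random.default_rng(seed)
    rows = []
    for m in ref_assignment.module_ids:
        member_idx = np.where(ref_assignment.labels == m)[0]
        obs_d, obs_c = preservation_statistics(member_idx, test_adj, ref_adj)
        null_d = np.empty(n_permutations)
        null_c = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.choice(pool, size=len(member_idx), replace=False)
            null_d[b], null_c[b] = preservation_statistics(perm, test_adj, ref_adj)
        z_d = _permutation_z(obs_d, null_d)
        z_c = _permutation_z(obs_c, null_c)
        z_summary = float(np.median([z_d, z_c]))
        rows.append(
            {
                "module": m,
                "size": len(member_idx),
                "density_obs": obs_d,
                "density_null_mean": null_d.mean(),
                "density_null_sd": null_d.std(ddof=1),
                "Z_density": z_d,
                "connectivity_obs": obs_c,
                "connectivity_null_mean": null_c.mean(),
                "connectivity_null_sd": null_c.std(ddof=1),
                "Z_connectivity": z_c,
                "Z_summary": z_summary,
                "class": classify_zsummary(z_summary),
            }
        )
    return PreservationResult(
        table=pd.DataFrame(rows),
        n_permutations=n_permutations,
        seed=seed,
        test_cohort=test_X.cohort,
    )


def _permutation_z(observed: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate permutation null (SD=0); reporting Z=+inf")
        return float("inf") if observed > null.mean() else float("-inf")
    return float((observed - null.mean()) / sd)
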