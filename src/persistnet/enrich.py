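"""Pathway over-representation, directional activation scoring, and
pathway-score/trait correlation.

Over-representation uses the one-sided hypergeometric tail with Bonferroni
family-wise correction by default; the reference universe is the assayed
feature panel (panel-based assays make the assayed set, not the genome, the
correct background). Activation is scored by a transparent sign-consistency
z: the mean agreement between observed effect directions and the pathway's
annotated expected directions, scaled by sqrt(N). It is a documented
stand-in for proprietary pathway-activation algorithms and is not equivalent
to their output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import ExpressionMatrix
from .modules import TraitTable, correlation_with_p, pathway_sample_scores

MIN_OVERLAP = 3


@dataclass
class PathwayDB:
    """Named feature sets with optional per-member direction annotations."""

    sets: dict[str, list[str]]
    directions: dict[str, dict[str, int]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in set {name!r}")
        for name, dirs in self.directions.items():
            bad = {v for v in dirs.values()} - {-1, 1}
            if bad:
                raise ValueError(f"directions for {name!r} must be -1/+1, got {bad}")

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.source or "na"
                fh.write("\t".join([name, desc] + list(members)) + "\n")

    @classmethod
    def read_gmt(cls, path, source: str = "") -> "PathwayDB":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = parts[2:]
        return cls(sets=sets, source=source)


def hypergeometric_enrichment(
    hits: set[str],
    db: PathwayDB,
    universe: set[str],
    method: str = "bonferroni",
    min_overlap: int = MIN_OVERLAP,
) -> pd.DataFrame:
    """One-sided over-representation of ``hits`` in each pathway set.

    p = P(X >= overlap) under hypergeometric(|universe|, |set ∩ universe|,
    |hits|). Sets are intersected with the universe before testing, sets
    with overlap below ``min_overlap`` are excluded before correction (so
    the correction factor m reflects the exclusion), and rows are sorted
    by p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits:
        raise ValueError("empty hit set")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M = len(universe)
    N = len(hits)
    rows = []
    for name, members in db.sets.items():
        in_universe = set(members) & universe
        overlap = len(in_universe & hits)
        if overlap < min_overlap:
            continue
        n = len(in_universe)
        p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": n,
                "hits_size": N,
                "universe_size": M,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "hits_size", "universe_size", "p"]
    )
    if len(out):
        from .diffmeta import adjust_pvalues

        out["q"] = adjust_pvalues(out["p"].to_numpy(), method)
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    out.attrs["correction"] = method
    out.attrs["min_overlap"] = min_overlap
    return out


def activation_zscore(
    observed: dict[str, int], expected: dict[str, int]
) -> float | None:
    """Sign-consistency activation z for one pathway.

    For each member annotated in both maps, s_i = observed_i * expected_i
    (+1 agreement, -1 disagreement); z = sum(s) / sqrt(N). Positive z means
    the pathway moves in its annotated activation direction, negative means
    inhibition. Returns None when no member carries both annotations.
    """
    shared = sorted(set(observed) & set(expected))
    if not shared:
        return None
    s = np.array([np.sign(observed[m]) * np.sign(expected[m]) for m in shared], dtype=float)
    if np.any(s == 0):
        raise ValueError("observed/expected signs must be nonzero")
    return float(s.sum() / np.sqrt(len(s)))


def pathway_trait_correlation(
    scores: dict[str, pd.Series],
    traits: TraitTable,
    trait_names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each pathway's per-sample score with each trait."""
    names = trait_names if trait_names is not None else traits.numeric_traits()
    rows = []
    for set_name, score in scores.items():
        shared = [s for s in score.index if s in set(traits.sample_ids)]
        if len(shared) < 10:
            raise ValueError(f"pathway {set_name!r}: need >= 10 overlapping samples")
        x = score.loc[shared].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"pathway {set_name!r} has a constant score")
        for trait in names:
            y = traits.data.loc[shared, trait].to_numpy(dtype=float)
            r, p = correlation_with_p(x, y)
            rows.append({"set": set_name, "trait": trait, "r": r, "p": p, "n": len(shared)})
    return pd.DataFrame(rows)


def score_pathways(
    X: ExpressionMatrix, db: PathwayDB, min_members: int = 2
) -> dict[str, pd.Series]:
    """Per-sample first-PC score for every pathway with enough members."""
    out: dict[str, pd.Series] = {}
    present = set(X.feature_ids)
    for name, members in db.sets.items():
        if len(set(members) & present) >= min_members:
            out[name] = pathway_sample_scores(X, list(members))
    return out
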