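"""Cis protein-quantitative-trait locus (pQTL) mapping.

Candidate variant-protein pairs are restricted to the cis window — variants
on the same chromosome within 1 Mb of the protein's coding-gene body edges,
boundary inclusive — and common variants (MAF > 0.05). Each pair is tested
by OLS of the standardized protein level on the additively coded genotype
(0/1/2 dosage) plus covariates, with BH q-values over exactly the tested
pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import ExpressionMatrix

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000
MAF_MIN = 0.05
SIGNIFICANT_Q = 0.05
SUGGESTIVE_P = 1e-3


@dataclass
class GenotypeMatrix:
    """Variants x samples additively coded dosages; NaN marks missing calls."""

    variant_ids: list[str]
    chrom: list[str]
    pos: np.ndarray  # 1-based
    sample_ids: list[str]
    dosages: np.ndarray  # variants x samples, values 0/1/2 or NaN

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.pos = np.asarray(self.pos, dtype=int)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, [0.0, 1.0, 2.0])
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    def row(self, variant_id: str) -> np.ndarray:
        return self.dosages[self.variant_ids.index(variant_id)]


@dataclass
class GeneCoordinateTable:
    """Feature -> gene body (chrom, start, end), 1-based inclusive."""

    table: pd.DataFrame  # index feature_id; columns chrom, start, end

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate feature ids in gene coordinates")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene start must be <= end (1-based inclusive)")


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """MAF = min(f, 1-f) of the coded allele over non-missing dosages."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        raise ValueError("all dosages missing")
    f = d.sum() / (2.0 * len(d))
    return float(min(f, 1.0 - f))


def signed_distance(pos: int, start: int, end: int) -> int:
    """Distance from a variant to the nearest gene edge: negative upstream
    of start, positive downstream of end, 0 inside the gene body."""
    if pos < start:
        return pos - start
    if pos > end:
        return pos - end
    return 0


def cis_candidate_pairs(
    genes: GeneCoordinateTable,
    variants: GenotypeMatrix,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """All (variant, feature) pairs with |distance| <= window on the same
    chromosome; the window is inclusive at its boundary."""
    gene_chroms = set(genes.table["chrom"])
    var_chroms = set(variants.chrom)
    # both tables must speak the same chromosome naming
    unknown = var_chroms - gene_chroms if not (var_chroms & gene_chroms) else set()
    if unknown:
        raise ValueError("no shared chromosomes; unknown: " + ", ".join(sorted(unknown)))
    rows = []
    gt = genes.table
    for vi, (vid, vchrom, vpos) in enumerate(
        zip(variants.variant_ids, variants.chrom, variants.pos)
    ):
        same = gt[gt["chrom"] == vchrom]
        for fid, g in same.iterrows():
            dist = signed_distance(int(vpos), int(g["start"]), int(g["end"]))
            if abs(dist) <= window:
                rows.append(
                    {"variant_id": vid, "feature_id": fid, "distance": dist}
                )
    return pd.DataFrame(rows, columns=["variant_id", "feature_id", "distance"])


def pqtl_scan(
    X: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    covariates: np.ndarray | None = None,
    maf_min: float = MAF_MIN,
    adjust: str = "BH",
    min_samples: int = 10,
) -> pd.DataFrame:
    """OLS of standardized protein level on dosage (+ covariates) per cis pair.

    Pairs with MAF <= ``maf_min`` are dropped (count logged); missing
    dosages are excluded per test; q-values are computed over exactly the
    emitted rows.
    """
    from .diffmeta import adjust_pvalues

    shared = [s for s in X.sample_ids if s in set(genotypes.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between expression and genotypes")
    xcol = {s: i for i, s in enumerate(X.sample_ids)}
    gcol = {s: i for i, s in enumerate(genotypes.sample_ids)}
    xi = [xcol[s] for s in shared]
    gi = [gcol[s] for s in shared]
    vrow = {v: i for i, v in enumerate(genotypes.variant_ids)}
    frow = {f: i for i, f in enumerate(X.feature_ids)}

    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(shared):
            pass
        elif cov.shape[1] == len(shared):
            cov = cov.T
        else:
            raise ValueError("covariate rows must match shared samples")

    n_maf_dropped = 0
    n_skipped = 0
    rows = []
    for _, pair in pairs.iterrows():
        vid, fid = pair["variant_id"], pair["feature_id"]
        g = genotypes.dosages[vrow[vid], gi]
        y = X.values[frow[fid], xi]
        keep = ~np.isnan(g)
        if keep.sum() < min_samples:
            n_skipped += 1
            logger.info("pair (%s, %s) skipped: %d usable samples", vid, fid, keep.sum())
            continue
        gk, yk = g[keep], y[keep]
        maf = minor_allele_frequency(gk)
        if maf <= maf_min:
            n_maf_dropped += 1
            continue
        ysd = yk.std(ddof=1)
        if ysd == 0:
            n_skipped += 1
            continue
        yk = (yk - yk.mean()) / ysd
        cols = [np.ones(keep.sum()), gk]
        if cov is not None:
            cols.extend(cov[keep].T)
        D = np.column_stack(cols)
        dof = D.shape[0] - D.shape[1]
        XtX_inv = np.linalg.pinv(D.T @ D)
        b = XtX_inv @ D.T @ yk
        resid = yk - D @ b
        sigma2 = (resid**2).sum() / dof
        se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
        beta = float(b[1])
        t = beta / se if se > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(t), df=dof))
        rows.append(
            {
                "variant_id": vid,
                "feature_id": fid,
                "distance": int(pair.get("distance", 0)),
                "maf": maf,
                "n": int(keep.sum()),
                "beta": beta,
                "se": se,
                "t": t,
                "p": max(p, np.finfo(float).tiny),
            }
        )
    if n_maf_dropped:
        logger.info("dropped %d pairs below MAF threshold %.3f", n_maf_dropped, maf_min)
    out = pd.DataFrame(
        rows,
        columns=["variant_id", "feature_id", "distance", "maf", "n", "beta", "se", "t", "p"],
    )
    if len(out):
        out["q"] = adjust_pvalues(out["p"].to_numpy(), adjust)
        out["tier"] = np.where(
            out["q"] < SIGNIFICANT_Q,
            "significant",
            np.where(out["p"] < SUGGESTIVE_P, "suggestive", "ns"),
        )
    else:
        out["q"] = pd.Series(dtype=float)
        out["tier"] = pd.Series(dtype=str)
    out.attrs["n_maf_dropped"] = n_maf_dropped
    out.attrs["n_skipped"] = n_skipped
    return out
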