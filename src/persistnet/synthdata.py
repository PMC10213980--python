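"""Multi-cohort synthetic data with planted ground truth.

Emulates the statistical structure of a multi-cohort serum-proteomics case/
control study: K cohorts share planted co-expression modules generated from
a single latent factor per module (feature i in module m is
``lambda_i * f_m + sqrt(1 - lambda_i^2) * eps``), a subset of features carry
additive case/control mean shifts whose sign is consistent across cohorts
except for a configurable inconsistent fraction, clinical severity scores
are driven by the module factors and mapped into the printed instrument
ranges (CAPS cases >= 40, controls < 20; PCL cases >= 38, controls < 22),
and a toy genome carries common variants with planted cis effects on a
subset of proteins.

The latent single-factor model is the simplest structure that correlation-
network module detection provably recovers, which makes parameter-recovery
tests well defined. Case effects are additive on the standardized scale so
Cohen's d is known by construction. Genotypes are independent across
variants (no LD): the cis-window logic, MAF filter and regression are the
mechanisms under test, not fine-mapping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .netbuild import ExpressionMatrix
from .modules import TraitTable
from .pqtl import GeneCoordinateTable, GenotypeMatrix, CIS_WINDOW
from .enrich import PathwayDB

logger = logging.getLogger(__name__)

# abundance scale: raw = sample_scale * (RAW_LOCATION + RAW_SCALE * z)
RAW_LOCATION = 1000.0
RAW_SCALE = 100.0

# printed instrument cutoffs: CAPS case >= 40, control < 20;
# PCL case >= 38, subthreshold 22-37, control < 22
CAPS_CASE_RANGE = (40.0, 100.0)
CAPS_CONTROL_RANGE = (0.0, 19.0)
PCL_CASE_RANGE = (38.0, 80.0)
PCL_CONTROL_RANGE = (0.0, 21.0)

GENE_SPACING = 3_000_000
GENE_LENGTH = 20_000


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the synthetic multi-cohort fixture.

    Defaults give 3 cohorts of 100 cases / 100 controls over 500 features
    with three planted modules of 100 features each.
    """

    n_cohorts: int = 3
    samples_per_cohort: tuple[tuple[int, int], ...] = ((100, 100), (100, 100), (100, 100))
    n_features: int = 500
    module_sizes: tuple[int, ...] = (100, 100, 100)
    loading_range: tuple[float, float] = (0.5, 0.9)
    case_effect_sd: float = 0.8
    n_affected_per_module: int = 30
    frac_inconsistent: float = 0.1
    trait_loadings: tuple[float, ...] = (1.0, -0.8, 0.0)
    trait_noise_sd: float = 1.0
    sample_scale_jitter: float = 0.02
    n_variants: int = 40
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_cis_effects: int = 5
    cis_beta: float = 1.0
    n_caps_cohorts: int = 2  # leading cohorts use the CAPS scale, the rest PCL
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValueError("samples_per_cohort must have n_cohorts entries")
        if any(nc <= 0 or nn <= 0 for nc, nn in self.samples_per_cohort):
            raise ValueError("sample counts must be positive")
        if sum(self.module_sizes) > self.n_features:
            raise ValueError("sum(module_sizes) exceeds n_features")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        lo, hi = self.loading_range
        if not (0 < lo <= hi < 1):
            raise ValueError("loading_range must lie inside (0, 1)")
        if not 0 <= self.frac_inconsistent <= 1:
            raise ValueError("frac_inconsistent must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        if self.n_cis_effects > self.n_variants:
            raise ValueError("n_cis_effects exceeds n_variants")
        if len(self.trait_loadings) != len(self.module_sizes):
            raise ValueError("trait_loadings must match module_sizes")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for scoring recovery downstream."""

    module_labels: dict[str, int] = field(default_factory=dict)
    affected_features: dict[str, dict] = field(default_factory=dict)
    trait_loadings: dict[int, float] = field(default_factory=dict)
    cis_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    enriched_sets: dict[str, dict[str, int]] = field(default_factory=dict)

    def consistent_affected(self) -> set[str]:
        return {
            f for f, info in self.affected_features.items() if info["consistent"]
        }

    def to_json(self) -> dict:
        return {
            "module_labels": self.module_labels,
            "affected_features": self.affected_features,
            "trait_loadings": {str(k): v for k, v in self.trait_loadings.items()},
            "cis_pairs": [list(p) for p in self.cis_pairs],
            "enriched_sets": self.enriched_sets,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SyntheticTruth":
        return cls(
            module_labels={k: int(v) for k, v in obj["module_labels"].items()},
            affected_features=obj["affected_features"],
            trait_loadings={int(k): float(v) for k, v in obj["trait_loadings"].items()},
            cis_pairs=[tuple(p) for p in obj["cis_pairs"]],
            enriched_sets={
                k: {m: int(s) for m, s in v.items()} for k, v in obj["enriched_sets"].items()
            },
        )


def _feature_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def _rescale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Affine map of values onto [lo, hi]; constant input maps to the midpoint."""
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.full_like(values, (lo + hi) / 2.0)
    return lo + (values - vmin) / (vmax - vmin) * (hi - lo)


def generate_cohorts(
    config: SynthConfig,
) -> tuple[list[ExpressionMatrix], list[TraitTable], SyntheticTruth]:
    """Generate per-cohort expression and trait tables with planted truth.

    Feature ids and order are identical across cohorts. Factor loadings are
    drawn once and shared across cohorts, so modules are reproducible in
    every cohort; module factors themselves are cohort-specific. Severity
    scores are built from the module factors plus noise and mapped, within
    each designed case/control group, into the printed instrument ranges.
    """
    rng = np.random.default_rng([config.seed, 1])
    features = _feature_ids(config.n_features)

    # feature -> module (0 background), loadings shared across cohorts
    labels = np.zeros(config.n_features, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[pos : pos + size] = m
        pos += size
    loadings = rng.uniform(*config.loading_range, size=config.n_features)

    truth = SyntheticTruth(
        module_labels={f: int(l) for f, l in zip(features, labels)},
        trait_loadings={
            m: float(c) for m, c in enumerate(config.trait_loadings, start=1)
        },
    )

    # affected features live in the trait-linked modules (loading != 0)
    affected_idx: list[int] = []
    for m, load in truth.trait_loadings.items():
        if load == 0:
            continue
        member_idx = np.where(labels == m)[0]
        k = min(config.n_affected_per_module, len(member_idx))
        affected_idx.extend(rng.choice(member_idx, size=k, replace=False).tolist())
    base_signs = rng.choice([-1, 1], size=len(affected_idx))
    n_flip = int(round(config.frac_inconsistent * len(affected_idx)))
    flipped = set(
        rng.choice(len(affected_idx), size=n_flip, replace=False).tolist()
    ) if n_flip else set()
    for j, (fi, s) in enumerate(zip(affected_idx, base_signs)):
        signs = [int(s)] * config.n_cohorts
        if j in flipped:
            signs[-1] = -int(s)  # flip the last cohort's direction
        truth.affected_features[features[fi]] = {
            "signs": signs,
            "magnitude": config.case_effect_sd,
            "consistent": j not in flipped,
        }

    n_modules = len(config.module_sizes)
    expressions: list[ExpressionMatrix] = []
    traits: list[TraitTable] = []
    for c in range(config.n_cohorts):
        cohort_id = f"cohort{c + 1}"
        n_case, n_control = config.samples_per_cohort[c]
        n = n_case + n_control
        sample_ids = [f"{cohort_id}_s{j:03d}" for j in range(n)]
        case = np.zeros(n)
        case[:n_case] = 1.0

        F = rng.standard_normal((n_modules, n))  # module factors, this cohort
        eps = rng.standard_normal((config.n_features, n))
        Z = eps.copy()
        for m in range(1, n_modules + 1):
            idx = labels == m
            lam = loadings[idx][:, None]
            Z[idx] = lam * F[m - 1] + np.sqrt(1.0 - lam**2) * eps[idx]
        for f, info in truth.affected_features.items():
            fi = features.index(f)
            Z[fi] += info["signs"][c] * info["magnitude"] * case

        # raw RFU-like abundances with a mild per-sample level jitter that
        # median normalization is expected to remove
        scale = 1.0 + rng.uniform(
            -config.sample_scale_jitter, config.sample_scale_jitter, size=n
        )
        raw = scale[None, :] * (RAW_LOCATION + RAW_SCALE * Z)
        expressions.append(
            ExpressionMatrix(list(features), sample_ids, raw, cohort=cohort_id)
        )

        # severity score from module factors, mapped into instrument ranges
        t_raw = (
            np.array(config.trait_loadings) @ F
            + config.trait_noise_sd * rng.standard_normal(n)
        )
        caps_like = c < config.n_caps_cohorts
        case_rng = CAPS_CASE_RANGE if caps_like else PCL_CASE_RANGE
        ctrl_rng = CAPS_CONTROL_RANGE if caps_like else PCL_CONTROL_RANGE
        score = np.empty(n)
        is_case = case == 1.0
        score[is_case] = _rescale(t_raw[is_case], *case_rng)
        score[~is_case] = _rescale(t_raw[~is_case], *ctrl_rng)
        score = np.round(score, 1)

        df = pd.DataFrame(
            {
                "cohort": cohort_id,
                "group": np.where(is_case, "case", "control"),
                ("CAPS_total" if caps_like else "PCL_total"): score,
                "age": np.round(rng.normal(35.0, 8.0, size=n), 1),
                "BMI": np.round(rng.normal(27.0, 4.0, size=n), 1),
                "batch": rng.choice(["A", "B"], size=n),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        traits.append(TraitTable(df))

    return expressions, traits, truth


def generate_genotypes(
    config: SynthConfig,
    expressions: list[ExpressionMatrix],
    truth: SyntheticTruth,
) -> tuple[GenotypeMatrix, GeneCoordinateTable, list[ExpressionMatrix]]:
    """Hardy-Weinberg genotypes on a toy linear genome with planted cis effects.

    Genes are placed 3 Mb apart on one chromosome (so 1 Mb cis windows never
    overlap); planted cis variants sit inside their gene's window, the
    remaining variants are split between null cis positions and positions
    beyond every window. Planted effects add ``cis_beta`` feature-SD per
    coded allele to the named protein's abundance. Returns updated
    expression matrices (inputs are not mutated).
    """
    rng = np.random.default_rng([config.seed, 2])
    features = expressions[0].feature_ids
    for x in expressions[1:]:
        if x.feature_ids != features:
            raise ValueError("expression matrices disagree on feature ids")

    coords = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [1 + i * GENE_SPACING for i in range(len(features))],
            "end": [1 + i * GENE_SPACING + GENE_LENGTH for i in range(len(features))],
        },
        index=pd.Index(features, name="feature_id"),
    )
    genes = GeneCoordinateTable(coords)

    all_samples = [s for x in expressions for s in x.sample_ids]
    n_total = len(all_samples)

    background = [f for f in features if truth.module_labels[f] == 0]
    pool = background if len(background) >= config.n_cis_effects else list(features)
    cis_features = rng.choice(pool, size=config.n_cis_effects, replace=False).tolist()

    variant_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    dosages = np.zeros((config.n_variants, n_total))
    freqs = rng.uniform(*config.maf_range, size=config.n_variants)

    new_values = [x.values.copy() for x in expressions]
    for v in range(config.n_variants):
        vid = f"rs{v:05d}"
        if v < config.n_cis_effects:
            fid = cis_features[v]
            g = coords.loc[fid]
            pos = int(g["start"] + rng.integers(-CIS_WINDOW // 2, CIS_WINDOW // 2))
            chrom = str(g["chrom"])
        elif v % 2 == 0:
            # null cis variant near a random gene
            fid = features[int(rng.integers(len(features)))]
            g = coords.loc[fid]
            pos = int(g["start"] + rng.integers(-CIS_WINDOW // 2, CIS_WINDOW // 2))
            chrom = str(g["chrom"])
        else:
            # outside every cis window: midway between genes
            i = int(rng.integers(len(features) - 1))
            pos = int(coords.iloc[i]["end"] + CIS_WINDOW + 400_000)
            chrom = "chr1"
        variant_ids.append(vid)
        chroms.append(chrom)
        positions.append(max(1, pos))
        dosages[v] = rng.binomial(2, freqs[v], size=n_total)

    # plant the cis effects on the raw abundance scale (1 feature SD = RAW_SCALE)
    offset = 0
    for x, vals in zip(expressions, new_values):
        n = x.n_samples
        for v, fid in enumerate(cis_features):
            fi = features.index(fid)
            vals[fi] += config.cis_beta * RAW_SCALE * dosages[v, offset : offset + n]
        offset += n
    updated = [
        ExpressionMatrix(list(x.feature_ids), list(x.sample_ids), vals, x.cohort)
        for x, vals in zip(expressions, new_values)
    ]

    for v, fid in enumerate(cis_features):
        truth.cis_pairs.append((variant_ids[v], fid, float(config.cis_beta)))

    genotypes = GenotypeMatrix(
        variant_ids=variant_ids,
        chrom=chroms,
        pos=np.array(positions),
        sample_ids=all_samples,
        dosages=dosages,
    )
    return genotypes, genes, updated


def generate_pathways(
    truth: SyntheticTruth,
    config: SynthConfig,
    enriched_affected: int = 15,
    enriched_background: int = 5,
    null_size: int = 20,
) -> PathwayDB:
    """GMT-serializable pathway sets keyed to the planted truth.

    One set is enriched for affected features with direction annotations
    matching the planted consensus signs; one null set is drawn uniformly
    from background features; two decoys are drawn from the whole universe.
    """
    rng = np.random.default_rng([config.seed, 3])
    features = _feature_ids(config.n_features)
    affected = sorted(truth.affected_features)
    background = [f for f in features if f not in truth.affected_features]
    for requested, pool, what in [
        (null_size, background, "background"),
        (enriched_background, background, "background"),
    ]:
        if requested > len(pool):
            raise ValueError(f"requested set size {requested} exceeds {what} pool")

    sets: dict[str, list[str]] = {}
    directions: dict[str, dict[str, int]] = {}

    if affected:
        k = min(enriched_affected, len(affected))
        members = rng.choice(affected, size=k, replace=False).tolist()
        members += rng.choice(background, size=enriched_background, replace=False).tolist()
        dirs = {}
        for f in members:
            if f in truth.affected_features:
                dirs[f] = int(truth.affected_features[f]["signs"][0])
            else:
                dirs[f] = int(rng.choice([-1, 1]))
        sets["planted_response"] = members
        directions["planted_response"] = dirs
        truth.enriched_sets["planted_response"] = dirs

    sets["null_background"] = rng.choice(background, size=null_size, replace=False).tolist()
    for i in range(2):
        sets[f"decoy_{i + 1}"] = rng.choice(
            features, size=null_size, replace=False
        ).tolist()
    return PathwayDB(sets=sets, directions=directions, source="synthetic")


# ---------------------------------------------------------------------------
# fixture serialization


def write_fixture(
    outdir: str | Path,
    config: SynthConfig,
    expressions: list[ExpressionMatrix],
    traits: list[TraitTable],
    truth: SyntheticTruth,
    genotypes: GenotypeMatrix | None = None,
    genes: GeneCoordinateTable | None = None,
    pathways: PathwayDB | None = None,
) -> dict:
    """Write all fixture artifacts as plain text and return the manifest."""
    outdir = Path(outdir)
    if not outdir.exists():
        logger.info("creating fixture directory %s", outdir)
        outdir.mkdir(parents=True)

    files: dict[str, str] = {}
    for x in expressions:
        name = f"expression_{x.cohort}.tsv"
        df = x.to_frame()
        df.index.name = "feature_id"
        df.to_csv(outdir / name, sep="\t", float_format="%.6f")
        files[f"expression:{x.cohort}"] = name
    for t, x in zip(traits, expressions):
        name = f"traits_{x.cohort}.csv"
        t.data.to_csv(outdir / name)
        files[f"traits:{x.cohort}"] = name
    if genotypes is not None:
        name = "genotypes.tsv"
        geno = pd.DataFrame(
            genotypes.dosages,
            index=pd.Index(genotypes.variant_ids, name="variant_id"),
            columns=genotypes.sample_ids,
        )
        geno.insert(0, "chrom", genotypes.chrom)
        geno.insert(1, "pos", genotypes.pos)
        geno.to_csv(outdir / name, sep="\t", na_rep="NA", float_format="%g")
        files["genotypes"] = name
    if genes is not None:
        name = "gene_coords.tsv"
        with open(outdir / name, "w") as fh:
            fh.write("# coordinates are 1-based inclusive\n")
            genes.table.to_csv(fh, sep="\t")
        files["gene_coords"] = name
    if pathways is not None:
        pathways.write_gmt(outdir / "pathways.gmt")
        files["pathways"] = "pathways.gmt"
        if pathways.directions:
            with open(outdir / "pathway_directions.tsv", "w") as fh:
                fh.write("set\tfeature_id\tdirection\n")
                for s, dirs in pathways.directions.items():
                    for f, d in dirs.items():
                        fh.write(f"{s}\t{f}\t{d:+d}\n")
            files["pathway_directions"] = "pathway_directions.tsv"
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    files["truth"] = "truth.json"

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def generate_all(
    config: SynthConfig,
) -> tuple[
    list[ExpressionMatrix],
    list[TraitTable],
    GenotypeMatrix,
    GeneCoordinateTable,
    PathwayDB,
    SyntheticTruth,
]:
    """Convenience wrapper: cohorts, genotypes (with cis effects), pathways."""
    expressions, traits, truth = generate_cohorts(config)
    genotypes, genes, expressions = generate_genotypes(config, expressions, truth)
    pathways = generate_pathways(truth, config)
    return expressions, traits, genotypes, genes, pathways, truth
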