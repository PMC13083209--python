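"""Seeded synthetic study generator.

Emulates a clonal forest-tree breeding trial sampled for its root
microbiome: a multi-generation pedigree whose final generation is a set of
full-sib families, a single-tree incomplete-block field layout, correlated
soil covariates, latent genetic values produced by Mendelian gene dropping,
and ASV count tables with configurable genetic, spatial, batch, and soil
structure. Every stage is deterministic under a master seed; the master
seed spawns independent child streams per stage.

Defaults reproduce the study conditions: 28 full-sib families of 3-6
genotypes (132 genotypes), 4 ramets each (528 trees), blocks of 36 trees,
two sequencing batches, and soil covariates with the reported means, SDs
and correlations (pH 4.63 +/- 0.18; moisture 43.9 +/- 6.0 %; total C
9.79 +/- 2.46 %; total N 0.45 +/- 0.10 %; r(pH,C) = -0.78, r(pH,N) = -0.70,
r(C,N) = 0.89).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelationshipMatrix, sort_and_validate

__all__ = [
    "GeneticArchitecture",
    "SimulatedPedigree",
    "TrialLayout",
    "GeneticValues",
    "AsvSimParams",
    "SimulationTruth",
    "SOIL_MEANS",
    "SOIL_SDS",
    "SOIL_CORRELATION",
    "generate_pedigree",
    "generate_layout",
    "gene_drop",
    "simulate_soil",
    "simulate_mixed_model_response",
    "simulate_asv_counts",
    "simulate_study",
    "nearest_positive_definite",
]

# ---------------------------------------------------------------------------
# soil defaults (study-calibrated)

SOIL_VARS = ["pH", "moisture", "total_C", "total_N"]
SOIL_MEANS = {"pH": 4.63, "moisture": 43.9, "total_C": 9.79, "total_N": 0.45}
SOIL_SDS = {"pH": 0.18, "moisture": 6.0, "total_C": 2.46, "total_N": 0.10}
# Reported: r(pH, C) = -0.78, r(pH, N) = -0.70, r(C, N) = 0.89.
# Moisture rows are not reported; -0.3 / +0.3 are free defaults chosen to
# keep the matrix positive definite (documented as arbitrary).
SOIL_CORRELATION = pd.DataFrame(
    [
        [1.00, -0.30, -0.78, -0.70],
        [-0.30, 1.00, 0.30, 0.30],
        [-0.78, 0.30, 1.00, 0.89],
        [-0.70, 0.30, 0.89, 1.00],
    ],
    index=SOIL_VARS,
    columns=SOIL_VARS,
)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# pedigree


@dataclass
class SimulatedPedigree:
    """A generated pedigree plus the family membership of the study genotypes."""

    pedigree: Pedigree
    genotypes: list[str]
    families: pd.DataFrame  # columns: genotype, family, sire, dam

    @property
    def family_of(self) -> dict[str, str]:
        return dict(zip(self.families["genotype"], self.families["family"]))


def generate_pedigree(
    n_founders: int = 24,
    n_families: int = 28,
    progeny_per_family_range: tuple[int, int] = (3, 6),
    generations: int = 3,
    seed=0,
    n_genotypes: int | None = 132,
) -> SimulatedPedigree:
    """Generate a pedigree whose last generation is full-sib study families.

    Generation 0 holds ``n_founders`` unrelated founders; intermediate
    generations are produced by random crosses among the previous
    generation (keeping the cohort size at ``n_founders``), so the final
    parents are related and families acquire half-sib and deeper links.
    The final generation consists of ``n_families`` full-sib families whose
    sizes are drawn from ``progeny_per_family_range``; when ``n_genotypes``
    is given, sizes are adjusted within the range to hit that total exactly.

    Raises
    ------
    ValueError
        If ``n_families`` exceeds the number of distinct parent pairs, or
        the requested total is infeasible for the range.
    """
    lo, hi = progeny_per_family_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid progeny_per_family_range")
    if n_genotypes is not None and not (n_families * lo <= n_genotypes <= n_families * hi):
        raise ValueError(
            f"n_genotypes={n_genotypes} infeasible for {n_families} families "
            f"of size {lo}..{hi}"
        )
    if generations < 1:
        raise ValueError("generations must be >= 1")

    rng = _rng(seed)
    records: list[tuple[str, str | None, str | None]] = []
    cohort = [f"F{k:03d}" for k in range(n_founders)]
    records += [(i, None, None) for i in cohort]

    # intermediate generations: random distinct-pair crosses
    for g in range(1, max(generations - 1, 1)):
        nxt = []
        for k in range(n_founders):
            s, d = rng.choice(len(cohort), size=2, replace=False)
            child = f"I{g}_{k:03d}"
            records.append((child, cohort[s], cohort[d]))
            nxt.append(child)
        cohort = nxt

    # parent pairs for the study families (distinct pairs, parents reusable)
    n_parents = len(cohort)
    max_pairs = n_parents * (n_parents - 1) // 2
    if n_families > max_pairs:
        raise ValueError(f"cannot form {n_families} distinct pairs from {n_parents} parents")
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < n_families:
        s, d = sorted(rng.choice(n_parents, size=2, replace=False))
        pairs.add((int(s), int(d)))
    pair_list = sorted(pairs)
    rng.shuffle(pair_list)

    sizes = rng.integers(lo, hi + 1, size=n_families)
    if n_genotypes is not None:
        # nudge sizes within bounds until the total matches
        while sizes.sum() != n_genotypes:
            k = int(rng.integers(n_families))
            if sizes.sum() < n_genotypes and sizes[k] < hi:
                sizes[k] += 1
            elif sizes.sum() > n_genotypes and sizes[k] > lo:
                sizes[k] -= 1

    genotypes, fam_rows = [], []
    g_idx = 0
    for f_idx, ((si, di), size) in enumerate(zip(pair_list, sizes)):
        fam = f"FAM{f_idx + 1:02d}"
        sire, dam = cohort[si], cohort[di]
        for _ in range(int(size)):
            gid = f"G{g_idx + 1:03d}"
            records.append((gid, sire, dam))
            genotypes.append(gid)
            fam_rows.append((gid, fam, sire, dam))
            g_idx += 1

    ped = sort_and_validate(Pedigree(tuple(records)))
    fam_df = pd.DataFrame(fam_rows, columns=["genotype", "family", "sire", "dam"])
    return SimulatedPedigree(ped, genotypes, fam_df)


# ---------------------------------------------------------------------------
# field layout


@dataclass
class TrialLayout:
    """Single-tree incomplete-block layout: one tree per grid position.

    ``trees`` columns: tree_id, genotype, ramet, block, x, y. Within any
    block a genotype appears at most once, so clonal ramets are spread
    across blocks.
    """

    trees: pd.DataFrame
    grid_shape: tuple[int, int]
    block_shape: tuple[int, int]

    def coordinates(self) -> pd.DataFrame:
        return self.trees.set_index("tree_id")[["x", "y"]]


def generate_layout(
    genotypes: Sequence[str],
    ramets_per_genotype: int = 4,
    block_capacity: int = 36,
    grid_shape: tuple[int, int] | None = None,
    seed=0,
) -> TrialLayout:
    """Place ``len(genotypes) * ramets_per_genotype`` trees on a grid.

    Blocks are contiguous square-ish tiles of the grid with
    ``block_capacity`` positions each; each genotype occurs at most once
    per block (single-tree incomplete block design). Assignment rotates
    each ramet round through consecutive blocks, then block labels,
    genotype order and within-block positions are shuffled, which keeps
    the design constraint while randomising placement.
    """
    genotypes = list(genotypes)
    n_trees = len(genotypes) * ramets_per_genotype
    if block_capacity < 1:
        raise ValueError("block_capacity must be >= 1")

    # block tile geometry
    bw = max(int(np.floor(np.sqrt(block_capacity))), 1)
    bh = int(np.ceil(block_capacity / bw))
    n_blocks = int(np.ceil(n_trees / block_capacity))
    if n_blocks < ramets_per_genotype:
        n_blocks = ramets_per_genotype  # need >= r blocks to separate ramets
    tiles_x = int(np.ceil(np.sqrt(n_blocks)))
    tiles_y = int(np.ceil(n_blocks / tiles_x))
    if grid_shape is None:
        grid_shape = (tiles_x * bw, tiles_y * bh)
    if grid_shape[0] * grid_shape[1] < n_trees:
        raise ValueError(
            f"grid {grid_shape} too small for {n_trees} trees"
        )

    rng = _rng(seed)
    g_order = rng.permutation(len(genotypes))
    block_label = rng.permutation(n_blocks)

    # strided deal: ramet j of (shuffled) genotype at rank i goes to block
    # (i*r + j) mod B; consecutive residues are distinct (B >= r), so the
    # incomplete-block rule holds and block loads stay within ceil(n/B)
    assign: dict[int, list[tuple[str, int]]] = {b: [] for b in range(n_blocks)}
    r = ramets_per_genotype
    for rank, gi in enumerate(g_order):
        for j in range(r):
            b = int(block_label[(rank * r + j) % n_blocks])
            assign[b].append((genotypes[gi], j + 1))
    for b, members in assign.items():
        if len(members) > block_capacity:
            raise ValueError(
                f"block capacity violated: block {b} holds {len(members)} trees"
            )

    # contiguous tile coordinates per block
    rows = []
    tree_counter = 0
    for b in range(n_blocks):
        tx, ty = b % tiles_x, b // tiles_x
        cells = [(tx * bw + i, ty * bh + j) for j in range(bh) for i in range(bw)]
        cells = [c for c in cells if c[0] < grid_shape[0] and c[1] < grid_shape[1]]
        cells = cells[:block_capacity]
        rng.shuffle(cells)
        members = assign[b]
        if len(members) > len(cells):
            raise ValueError(f"block {b}: {len(members)} trees but {len(cells)} cells")
        for (geno, ramet), (x, y) in zip(members, cells):
            tree_counter += 1
            rows.append((f"T{tree_counter:04d}", geno, ramet, f"B{b + 1:03d}", x, y))

    trees = pd.DataFrame(rows, columns=["tree_id", "genotype", "ramet", "block", "x", "y"])
    trees = trees.sort_values("tree_id", ignore_index=True)
    return TrialLayout(trees, grid_shape, (bw, bh))


# ---------------------------------------------------------------------------
# gene dropping


@dataclass
class GeneticArchitecture:
    """Generative genetic architecture for the latent abundance trait.

    ``n_loci`` independent biallelic loci at frequency ``allele_freq``;
    per-locus additive effects ~ N(0, additive_effect_scale^2), dominance
    deviations ~ N(0, dominance_effect_scale^2), and optional pairwise
    additive-by-additive epistatic effects ~ N(0, epistatic_effect_scale^2)
    over ``n_epistatic_pairs`` random locus pairs. All effect units are on
    the latent (transformed-abundance) scale.
    """

    n_loci: int = 100
    allele_freq: float = 0.5
    additive_effect_scale: float = 1.0
    dominance_effect_scale: float = 0.0
    epistatic_effect_scale: float = 0.0
    n_epistatic_pairs: int | None = None

    def __post_init__(self):
        if not (0.0 < self.allele_freq < 1.0):
            raise ValueError("allele_freq must be in (0, 1)")
        for name in ("additive_effect_scale", "dominance_effect_scale", "epistatic_effect_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


@dataclass
class GeneticValues:
    """Latent genetic values per individual, decomposed by effect type.

    ``dose`` (individuals x loci allele counts) and ``effects`` are kept
    only when ``gene_drop(..., keep_dose=True)``; they enable per-locus
    variance accounting.
    """

    ids: list[str]
    additive: np.ndarray
    dominance: np.ndarray
    epistatic: np.ndarray
    dose: np.ndarray | None = None
    effects: dict | None = None

    @property
    def total(self) -> np.ndarray:
        return self.additive + self.dominance + self.epistatic

    def subset(self, ids: Sequence[str]) -> "GeneticValues":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return GeneticValues(
            list(ids), self.additive[idx], self.dominance[idx], self.epistatic[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "additive": self.additive,
                "dominance": self.dominance,
                "epistatic": self.epistatic,
                "total": self.total,
            },
            index=self.ids,
        )


def gene_drop(
    pedigree: Pedigree,
    architecture: GeneticArchitecture,
    seed=0,
    keep_dose: bool = False,
) -> GeneticValues:
    """Drop founder alleles through the pedigree and score genetic values.

    Founders receive Hardy-Weinberg genotypes; each offspring receives one
    allele per parent by Mendelian sampling (a parent of dose ``g``
    transmits the reference allele with probability ``g/2``, exact for the
    independent-locus model). Per-locus contributions are centred at the
    founder-population expectation so unrelated non-inbred individuals have
    mean value 0:

    * additive: ``a * (dose - 2p)``
    * dominance: ``d * (het - 2p(1-p))``
    * epistatic (additive-by-additive): ``w * (dose_i - 2p)(dose_j - 2p)``
    """
    ped = pedigree  # must be sorted; generate_pedigree output already is
    rng = _rng(seed)
    p = architecture.allele_freq
    L = architecture.n_loci
    ids = ped.ids
    pos = {i: k for k, i in enumerate(ids)}
    dose = np.zeros((len(ids), L), dtype=np.int8)

    for k, (i, s, d) in enumerate(ped.records):
        if s is None and d is None:
            dose[k] = rng.binomial(2, p, size=L)
        else:
            # unknown single parent: draw that gamete from the base population
            ps = dose[pos[s]] / 2.0 if s is not None else np.full(L, p)
            pd_ = dose[pos[d]] / 2.0 if d is not None else np.full(L, p)
            dose[k] = (rng.random(L) < ps).astype(np.int8) + (rng.random(L) < pd_)

    a_eff = (
        rng.normal(0.0, architecture.additive_effect_scale, size=L)
        if architecture.additive_effect_scale > 0
        else np.zeros(L)
    )
    d_eff = (
        rng.normal(0.0, architecture.dominance_effect_scale, size=L)
        if architecture.dominance_effect_scale > 0
        else np.zeros(L)
    )

    centred = dose - 2.0 * p
    het = (dose == 1).astype(float) - 2.0 * p * (1.0 - p)
    additive = centred @ a_eff
    dominance = het @ d_eff

    epistatic = np.zeros(len(ids))
    if architecture.epistatic_effect_scale > 0:
        n_pairs = architecture.n_epistatic_pairs
        if n_pairs is None:
            n_pairs = L // 2
        if n_pairs > 0:
            perm = rng.permutation(L)
            i1 = perm[:n_pairs]
            i2 = perm[n_pairs: 2 * n_pairs]
            if len(i2) < n_pairs:  # more pairs than L/2: sample with replacement
                i1 = rng.integers(0, L, size=n_pairs)
                i2 = (i1 + 1 + rng.integers(0, L - 1, size=n_pairs)) % L
            w = rng.normal(0.0, architecture.epistatic_effect_scale, size=n_pairs)
            epistatic = (centred[:, i1] * centred[:, i2]) @ w

    gv = GeneticValues(ids, additive, dominance, epistatic)
    if keep_dose:
        gv.dose = dose
        gv.effects = {"additive": a_eff, "dominance": d_eff, "allele_freq": p}
    return gv


def dominance_partition_gene_drop(
    n_families: int = 200,
    progeny_per_family: int = 50,
    n_loci: int = 2000,
    allele_freq: float = 0.5,
    seed=0,
) -> dict[str, float]:
    """Partition pure-dominance genetic variance between and within families.

    Drops ``n_loci`` biallelic loci with zero additive effect and unit
    dominance deviations through ``n_families`` independent full-sib
    families (unrelated, non-inbred parents), then splits the variance of
    the dropped genetic values into between-family and within-family
    components. Classical full-sib covariance theory
    (Cov(FS) = VA/2 + VD/4, here VA = 0) puts 25% of dominance variance
    between families and 75% within.

    The components are estimated per locus with the balanced one-way
    ANOVA moment estimators and summed with the squared dominance effects
    as weights. Loci are independent, so the cross-locus covariance terms
    this drops have zero expectation; pooling over thousands of loci
    shrinks the Monte-Carlo error far below the per-family resolution of
    the aggregate estimator while estimating the same quantity.

    Returns a dict with ``between_family_pct`` and ``within_family_pct``.
    """
    records: list[tuple[str, str | None, str | None]] = []
    fam_of: list[int] = []
    for f in range(n_families):
        s, d = f"S{f}", f"D{f}"
        records += [(s, None, None), (d, None, None)]
        for j in range(progeny_per_family):
            records.append((f"P{f}_{j}", s, d))
            fam_of.append(f)
    ped = Pedigree(tuple(records))  # already parent-first ordered

    arch = GeneticArchitecture(
        n_loci=n_loci,
        allele_freq=allele_freq,
        additive_effect_scale=0.0,
        dominance_effect_scale=1.0,
    )
    gv = gene_drop(ped, arch, seed=seed, keep_dose=True)
    is_progeny = np.array([r[1] is not None for r in ped.records])
    d_eff = gv.effects["dominance"]

    # per-locus dominance contributions of the progeny, family-major order
    F, k = n_families, progeny_per_family
    het = (gv.dose[is_progeny] == 1).astype(float).reshape(F, k, n_loci)
    fam_mean = het.mean(axis=1)                      # (F, L)
    grand = fam_mean.mean(axis=0)
    msb = k * ((fam_mean - grand) ** 2).sum(axis=0) / (F - 1)
    msw = ((het - fam_mean[:, None, :]) ** 2).sum(axis=(0, 1)) / (F * (k - 1))
    vb_locus = (msb - msw) / k
    vw_locus = msw
    w2 = d_eff**2
    var_between = float(w2 @ vb_locus)
    var_within = float(w2 @ vw_locus)
    total = var_between + var_within
    return {
        "between_family_pct": 100.0 * var_between / total,
        "within_family_pct": 100.0 * var_within / total,
        "n_progeny": F * k,
    }


# ---------------------------------------------------------------------------
# soil covariates


def nearest_positive_definite(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Higham-style projection of a symmetric matrix to the PD cone."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    out = vecs @ np.diag(vals) @ vecs.T
    # restore unit diagonal for correlation matrices
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


def simulate_soil(
    n_samples: int,
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
    correlation_matrix: pd.DataFrame | np.ndarray | None = None,
    seed=0,
    n_missing: int = 0,
) -> pd.DataFrame:
    """Draw correlated soil covariates (pH, moisture %, total C %, total N %).

    Multivariate Gaussian, scaled to the requested means/SDs; defaults are
    the study-calibrated values. A non-PD correlation matrix is repaired to
    the nearest PD matrix with a warning. ``n_missing`` entries per column
    may be blanked (NaN) to exercise mean imputation downstream.
    """
    means = dict(SOIL_MEANS if means is None else means)
    sds = dict(SOIL_SDS if sds is None else sds)
    cols = list(means)
    corr = SOIL_CORRELATION if correlation_matrix is None else correlation_matrix
    corr = np.asarray(pd.DataFrame(corr).loc[cols, cols] if isinstance(corr, pd.DataFrame) else corr, dtype=float)
    if corr.shape != (len(cols), len(cols)):
        raise ValueError("correlation matrix shape mismatch")

    if np.linalg.eigvalsh((corr + corr.T) / 2).min() <= 0:
        warnings.warn("correlation matrix not positive definite; applying nearest-PD repair")
        corr = nearest_positive_definite(corr)
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("correlation matrix remains non-PD after repair")

    rng = _rng(seed)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_samples, len(cols))) @ chol.T
    sd_vec = np.array([sds[c] for c in cols])
    mean_vec = np.array([means[c] for c in cols])
    soil = pd.DataFrame(z * sd_vec + mean_vec, columns=cols)
    if n_missing > 0:
        for c in cols:
            idx = rng.choice(n_samples, size=min(n_missing, n_samples), replace=False)
            soil.loc[idx, c] = np.nan
    return soil


# ---------------------------------------------------------------------------
# direct mixed-model response (generative counterpart of the REML model)


def simulate_mixed_model_response(
    A: RelationshipMatrix,
    genotype_of_sample: Sequence[str],
    family_of_sample: Sequence[str],
    variances: dict[str, float],
    X: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    seed=0,
) -> np.ndarray:
    """Draw one response vector from y = Xb + Za ua + Zf uf + Zc uc + e.

    ``variances`` keys: ``additive`` (scales A), ``family``, ``clone``,
    ``residual``. Used for parameter-recovery and null simulations where
    exact Gaussian structure (rather than the count-level generator) is
    wanted.
    """
    rng = _rng(seed)
    genos = list(A.labels)
    gpos = {g: k for k, g in enumerate(genos)}
    fams = sorted(set(family_of_sample))
    fpos = {f: k for k, f in enumerate(fams)}
    gi = np.array([gpos[g] for g in genotype_of_sample])
    fi = np.array([fpos[f] for f in family_of_sample])
    n = len(gi)

    y = np.zeros(n)
    va = variances.get("additive", 0.0)
    if va > 0:
        # sample ua ~ N(0, va * A) via eigendecomposition (A may be singular)
        vals, vecs = np.linalg.eigh(A.values)
        vals = np.clip(vals, 0.0, None)
        ua = vecs @ (np.sqrt(vals * va) * rng.standard_normal(len(genos)))
        y += ua[gi]
    vf = variances.get("family", 0.0)
    if vf > 0:
        y += (np.sqrt(vf) * rng.standard_normal(len(fams)))[fi]
    vc = variances.get("clone", 0.0)
    if vc > 0:
        y += (np.sqrt(vc) * rng.standard_normal(len(genos)))[gi]
    ve = variances.get("residual", 0.0)
    if ve > 0:
        y += np.sqrt(ve) * rng.standard_normal(n)
    if X is not None and beta is not None:
        y += np.asarray(X) @ np.asarray(beta)
    return y


# ---------------------------------------------------------------------------
# ASV count simulation


@dataclass
class AsvSimParams:
    """Per-dataset parameters for the count generator.

    The latent per-sample log-abundance of ASV j is

        baseline_j + slope_j * g(genotype) + spatial_j(x, y)
        + batch_offset_j[batch] + soil_beta_j * soil_z + eps

    and counts are negative binomial around ``libsize * exp(latent)``
    (Poisson when ``overdispersion`` is 0). ``frac_core`` of ASVs get high
    baselines calibrated so they appear in >= 80% of samples at the default
    depth; the rest are sparser. ``frac_genetic`` of ASVs receive a nonzero
    genetic slope drawn with SD ``genetic_slope_sd``.
    """

    n_asvs: int = 120
    frac_core: float = 0.25
    baseline_core: tuple[float, float] = (3.0, 5.0)     # log-scale uniform range
    baseline_noncore: tuple[float, float] = (-2.0, 2.0)
    frac_genetic: float = 0.3
    genetic_slope_sd: float = 0.35
    spatial_sd: float = 0.5
    n_spatial_waves: int = 3
    batch_sd: float = 0.3
    n_batches: int = 2
    soil_beta_sd: float = 0.2
    latent_noise_sd: float = 0.5
    overdispersion: float = 0.5     # NB shape = 1/overdispersion; 0 => Poisson
    library_size_sigma: float = 0.3
    mean_depth: float = 10_000.0


@dataclass
class SimulationTruth:
    """Realised per-ASV variance shares of the latent signal components."""

    shares: pd.DataFrame          # index: asv ids; columns: component shares
    genetic_values: pd.DataFrame  # per genotype: additive/dominance/epistatic/total
    params: AsvSimParams

    def to_json_dict(self) -> dict:
        return {
            "shares": self.shares.round(6).to_dict(orient="index"),
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.params).items()},
        }


def _spatial_surface(x, y, n_waves, amplitude, rng):
    """Smooth low-frequency surface: sum of random sinusoidal plane waves.

    Frequencies span a quarter to three quarters of a cycle across the
    trial extent — the scale of soil/drainage gradients a field trial's
    spatial model is meant to remove, and smooth enough for a thin-plate
    spline to capture essentially completely.
    """
    xs = (x - x.mean()) / max(np.ptp(x), 1.0)
    ys = (y - y.mean()) / max(np.ptp(y), 1.0)
    surf = np.zeros_like(xs, dtype=float)
    for _ in range(n_waves):
        freq = rng.uniform(0.25, 0.75)
        theta = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        surf += np.sin(2 * np.pi * freq * (np.cos(theta) * xs + np.sin(theta) * ys) + phase)
    sd = surf.std()
    if sd > 0:
        surf = surf / sd * amplitude
    return surf


def assign_batches(layout: TrialLayout, n_batches: int = 2) -> pd.Series:
    """Assign sequencing batches by contiguous layout regions (x-splits)."""
    x = layout.trees["x"].to_numpy()
    qs = np.quantile(x, np.linspace(0, 1, n_batches + 1)[1:-1]) if n_batches > 1 else []
    batch = np.digitize(x, qs)
    return pd.Series(
        [f"batch{b + 1}" for b in batch], index=layout.trees["tree_id"], name="batch"
    )


def simulate_asv_counts(
    layout: TrialLayout,
    genetic_values: GeneticValues,
    soil: pd.DataFrame,
    params: AsvSimParams | None = None,
    seed=0,
    batches: pd.Series | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a samples x ASVs count table over the trial layout.

    One sample per tree. Returns the integer count table (rows = tree ids)
    and a :class:`SimulationTruth` recording each ASV's realised variance
    shares (additive / dominance / epistatic / spatial / batch / soil /
    residual) of its latent log-abundance.
    """
    params = params or AsvSimParams()
    rng = _rng(seed)
    trees = layout.trees
    n = len(trees)
    if len(soil) != n:
        raise ValueError("soil table must have one row per tree")

    gv = genetic_values.subset(sorted(set(trees["genotype"])))
    gpos = {g: k for k, g in enumerate(gv.ids)}
    gi = np.array([gpos[g] for g in trees["genotype"]])

    if batches is None:
        batches = assign_batches(layout, params.n_batches)
    bfac = pd.Categorical(batches.loc[trees["tree_id"]].to_numpy())
    bi = bfac.codes

    # standardised soil axis used as the environmental covariate
    soil_filled = soil.fillna(soil.mean())
    soil_z = (soil_filled - soil_filled.mean()) / soil_filled.std(ddof=0)
    soil_axis = soil_z.mean(axis=1).to_numpy()

    x = trees["x"].to_numpy(float)
    y = trees["y"].to_numpy(float)
    libsize = np.exp(rng.normal(0.0, params.library_size_sigma, size=n))

    n_core = int(round(params.frac_core * params.n_asvs))
    latent = np.zeros((n, params.n_asvs))
    share_rows = []
    asv_ids = [f"ASV{j + 1:04d}" for j in range(params.n_asvs)]

    # per-genotype standardised genetic components
    comp = {
        "additive": gv.additive,
        "dominance": gv.dominance,
        "epistatic": gv.epistatic,
    }
    tot = gv.total
    tot_sd = tot.std() if tot.std() > 0 else 1.0

    for j in range(params.n_asvs):
        core = j < n_core
        lo, hi = params.baseline_core if core else params.baseline_noncore
        baseline = rng.uniform(lo, hi)
        slope = (
            rng.normal(0.0, params.genetic_slope_sd)
            if rng.random() < params.frac_genetic
            else 0.0
        )
        genetic_term = slope * tot / tot_sd
        spatial_term = _spatial_surface(x, y, params.n_spatial_waves, params.spatial_sd, rng) \
            if params.spatial_sd > 0 else np.zeros(n)
        offsets = rng.normal(0.0, params.batch_sd, size=params.n_batches) \
            if params.batch_sd > 0 else np.zeros(params.n_batches)
        batch_term = offsets[bi]
        soil_term = rng.normal(0.0, params.soil_beta_sd) * soil_axis
        eps = rng.normal(0.0, params.latent_noise_sd, size=n)

        latent[:, j] = baseline + genetic_term[gi] + spatial_term + batch_term + soil_term + eps

        parts = {
            "spatial": spatial_term,
            "batch": batch_term,
            "soil": soil_term,
            "residual": eps,
        }
        g_scale = slope / tot_sd
        for name, vec in comp.items():
            parts[name] = g_scale * vec[gi]
        total_var = sum(v.var() for v in parts.values())
        share_rows.append(
            {k: (v.var() / total_var if total_var > 0 else 0.0) for k, v in parts.items()}
        )

    # counts: compositional draw around each sample's expected depth, so the
    # latent log-abundances act as relative weights and the library-size
    # factor perturbs total depth
    rel = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs = rel / rel.sum(axis=1, keepdims=True)
    mu = probs * (params.mean_depth * libsize)[:, None]
    if params.overdispersion > 0:
        shape = 1.0 / params.overdispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=trees["tree_id"].to_numpy(), columns=asv_ids)
    counts_df.index.name = "sample_id"
    shares = pd.DataFrame(share_rows, index=asv_ids)
    truth = SimulationTruth(shares, genetic_values.to_frame(), params)
    return counts_df, truth


# ---------------------------------------------------------------------------
# whole-study bundle


@dataclass
class SyntheticStudy:
    """Everything one run of the generator produces, ready for the pipeline."""

    pedigree: SimulatedPedigree
    layout: TrialLayout
    soil: pd.DataFrame
    genetic_values: GeneticValues
    counts: pd.DataFrame
    truth: SimulationTruth
    metadata: pd.DataFrame  # per sample: genotype, family, ramet, block, x, y, batch, soil

    @property
    def A(self) -> RelationshipMatrix:
        from .pedigree import additive_relationship

        return additive_relationship(self.pedigree.pedigree, validate=False)


def simulate_study(
    seed=0,
    architecture: GeneticArchitecture | None = None,
    asv_params: AsvSimParams | None = None,
    n_founders: int = 24,
    n_families: int = 28,
    n_genotypes: int | None = 132,
    progeny_per_family_range: tuple[int, int] = (3, 6),
    generations: int = 3,
    ramets_per_genotype: int = 4,
    block_capacity: int = 36,
    n_soil_missing: int = 0,
) -> SyntheticStudy:
    """Generate a full synthetic study under one master seed.

    The master seed spawns independent child seeds for pedigree, layout,
    gene dropping, soil, and counts, so stages can be regenerated
    independently and the whole bundle is bit-reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_ped, s_lay, s_gene, s_soil, s_counts = ss.spawn(5)

    sim_ped = generate_pedigree(
        n_founders=n_founders,
        n_families=n_families,
        progeny_per_family_range=progeny_per_family_range,
        generations=generations,
        seed=s_ped,
        n_genotypes=n_genotypes,
    )
    layout = generate_layout(
        sim_ped.genotypes,
        ramets_per_genotype=ramets_per_genotype,
        block_capacity=block_capacity,
        seed=s_lay,
    )
    architecture = architecture or GeneticArchitecture(
        n_loci=100, allele_freq=0.5,
        additive_effect_scale=0.3, dominance_effect_scale=0.3,
        epistatic_effect_scale=0.2,
    )
    gvals = gene_drop(sim_ped.pedigree, architecture, seed=s_gene)
    soil = simulate_soil(len(layout.trees), seed=s_soil, n_missing=n_soil_missing)
    asv_params = asv_params or AsvSimParams()
    batches = assign_batches(layout, asv_params.n_batches)
    counts, truth = simulate_asv_counts(
        layout, gvals, soil, asv_params, seed=s_counts, batches=batches
    )

    fam_of = sim_ped.family_of
    meta = layout.trees.copy()
    meta["family"] = meta["genotype"].map(fam_of)
    meta["batch"] = batches.loc[meta["tree_id"]].to_numpy()
    soil_idx = soil.copy()
    soil_idx.index = meta["tree_id"].to_numpy()
    meta = meta.set_index("tree_id").join(soil_idx)
    meta.index.name = "sample_id"
    return SyntheticStudy(sim_ped, layout, soil, gvals, counts, truth, meta)
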