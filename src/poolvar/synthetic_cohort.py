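"""Synthetic birth-cohort generator for the pooled-sequencing pipeline.

Everything downstream of wet-lab work is driven from per-site allele-count
tables, validation calls, dose-response assay tables, longitudinal phenotype
tables and per-individual polygenic scores.  This module generates all of
those from seeds, with the statistical structure the analysis stages assume:

* a registry of diploid individuals with sex, relatedness (twin/triplet/
  quadruplet groups), duplicated aliquots and missing-identifier flags;
* rare heterozygous carriers of receptor variants in four functional
  classes (cLoF, pLoF, WT-like, GoF) at configurable prevalences;
* random assignment of individuals to sequencing pools;
* per-pool, per-site strand-resolved read counts with Poisson depth,
  lognormal unequal-contribution weights, beta-binomial overdispersion and
  a base-error floor, plus error-only sites so false positives exist;
* per-individual capillary ("Sanger") validation as a truth oracle;
* piecewise-linear growth trajectories from a two-level random-effects
  model (the model family the growth-model stage fits);
* sigmoidal dose-response assay replicates;
* a Gaussian polygenic score optionally coupled to trajectory level.

Given a seed every generator output is bit-identical across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTIG = "chr18_toy"
CONTIG_LEN = 1500
CLASSES = ("cLoF", "pLoF", "WT-like", "GoF")

#: carrier counts of the reference cohort, per functional class
DEFAULT_PREVALENCES = {
    "pLoF": 13 / 5724,
    "cLoF": 4 / 5724,
    "WT-like": 21 / 5724,
    "GoF": 2 / 5724,
}


@dataclass
class SimulationConfig:
    """Knobs of the sequencing-side simulation.

    Defaults emulate the reference study design: 5993 samples pooled 50 at
    a time (120 pools) at ~43,654x mean depth, with lognormal per-sample
    DNA-contribution weights (CV 0.4), slight beta-binomial overdispersion
    and a 0.1% base-error floor.  Registry defects (duplicated aliquots,
    missing identifiers, twin/triplet sets inside the sequenced set) are
    given as exact counts so the exclusion ledger is deterministic.
    """

    n_individuals: int = 5993
    pool_size: int = 50
    mean_depth: float = 43654.0
    base_error_rate: float = 0.001
    contribution_cv: float = 0.4
    overdispersion: float = 1e-4
    amplification_bias: float = 1.08
    n_missing_id: int = 5
    n_duplicates: int = 214
    n_twin_pairs: int = 48
    n_triplet_sets: int = 1
    n_quadruplet_sets: int = 0
    n_fp_sites: int = 17
    fp_error_multiplier: float = 5.5
    fp_error_log_sd: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if not (0.0 <= self.base_error_rate < 0.01):
            raise ValueError("base_error_rate must lie in [0, 0.01)")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ValueError("overdispersion rho must lie in [0, 1)")
        if self.contribution_cv < 0:
            raise ValueError("contribution_cv must be non-negative")
        if self.amplification_bias <= 0:
            raise ValueError("amplification_bias must be positive")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")


@dataclass
class VariantDef:
    variant_id: str
    pos: int
    ref: str
    alt: str
    functional_class: str
    carrier_count: int


@dataclass
class ValidationRecord:
    individual_id: str
    variant_id: str
    carrier: bool
    zygosity: str | None


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``individuals`` columns: individual_id, sex (M/F), relatedness_group_id
    (-1 for singletons), multiplet_size, duplicate_flag, missing_id_flag,
    sequenced, prs_score.  ``variants`` columns mirror :class:`VariantDef`.
    ``genotypes`` is long-format (individual_id, variant_id, copies).
    """

    individuals: pd.DataFrame
    variants: pd.DataFrame
    genotypes: pd.DataFrame

    def carriers_of(self, variant_id: str) -> list[str]:
        g = self.genotypes
        return sorted(g.loc[(g.variant_id == variant_id) & (g.copies > 0), "individual_id"])

    def copies(self, individual_id: str, variant_id: str) -> int:
        g = self.genotypes
        m = (g.individual_id == individual_id) & (g.variant_id == variant_id)
        return int(g.loc[m, "copies"].sum())

    def class_of_variant(self, variant_id: str) -> str:
        v = self.variants.set_index("variant_id")
        return str(v.loc[variant_id, "functional_class"])

    def carrier_ids(self, classes: tuple[str, ...] = ("pLoF", "cLoF")) -> list[str]:
        """Individuals carrying >=1 variant of the given classes."""
        keep = set(self.variants.loc[self.variants.functional_class.isin(classes), "variant_id"])
        g = self.genotypes
        return sorted(set(g.loc[g.variant_id.isin(keep) & (g.copies > 0), "individual_id"]))

    def write_tsv(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.individuals.to_csv(os.path.join(outdir, "individuals.tsv"), sep="\t", index=False)
        self.variants.to_csv(os.path.join(outdir, "variants.tsv"), sep="\t", index=False)
        self.genotypes.to_csv(os.path.join(outdir, "genotypes.tsv"), sep="\t", index=False)


DEFAULT_CARRIERS_PER_VARIANT = {1: 0.65, 2: 0.20, 3: 0.10, 4: 0.05}


def simulate_cohort(
    config: SimulationConfig,
    class_prevalences: dict[str, float] | None = None,
    carriers_per_variant: dict[int, float] | None = None,
    class_counts: dict[str, int] | None = None,
) -> CohortTruth:
    """Draw a cohort registry, rare-variant carriers and variant definitions.

    Carrier counts per functional class are binomial draws at the configured
    prevalence among individuals that survive the exclusion ledger (the
    reference study found no carrier among its exclusions); ``class_counts``
    fixes them exactly instead.  Carriers are heterozygous.  Carriers of a
    class are partitioned into distinct variants according to
    ``carriers_per_variant``, a distribution over the number of carriers
    sharing one variant.
    """
    config.validate()
    if class_prevalences is None:
        class_prevalences = dict(DEFAULT_PREVALENCES)
    unknown = set(class_prevalences) - set(CLASSES)
    if class_counts:
        unknown |= set(class_counts) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown functional classes: {sorted(unknown)}")
    total_prev = sum(class_prevalences.values())
    if total_prev > 1.0:
        raise ValueError(f"class prevalences sum to {total_prev:.4f} > 1")
    if carriers_per_variant is None:
        carriers_per_variant = dict(DEFAULT_CARRIERS_PER_VARIANT)

    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    n_dup = config.n_duplicates
    n_unique = n - n_dup
    if n_unique <= 0:
        raise ValueError("n_duplicates must be smaller than n_individuals")

    ids = np.array([f"I{i:05d}" for i in range(n_unique)])
    sex = rng.choice(["M", "F"], size=n_unique)
    rel_group = np.full(n_unique, -1, dtype=int)
    multiplet = np.ones(n_unique, dtype=int)

    # multiplet sets fully inside the sequenced set, assigned to the head of
    # the id range so carrier assignment (drawn from unflagged singletons)
    # never collides with them
    cursor = 0
    group = 0
    for size, n_sets in ((4, config.n_quadruplet_sets), (3, config.n_triplet_sets), (2, config.n_twin_pairs)):
        for _ in range(n_sets):
            rel_group[cursor : cursor + size] = group
            multiplet[cursor : cursor + size] = size
            group += 1
            cursor += size
    if cursor > n_unique:
        raise ValueError("multiplet sets exceed cohort size")

    missing = np.zeros(n_unique, dtype=bool)
    if config.n_missing_id:
        missing[cursor : cursor + config.n_missing_id] = True
    flagged_until = cursor + config.n_missing_id

    individuals = pd.DataFrame(
        {
            "individual_id": ids,
            "sex": sex,
            "relatedness_group_id": rel_group,
            "multiplet_size": multiplet,
            "duplicate_flag": False,
            "missing_id_flag": missing,
            "sequenced": True,
            "prs_score": np.nan,
        }
    )
    if n_dup:
        src = rng.choice(np.arange(flagged_until, n_unique), size=n_dup, replace=False)
        dup = individuals.iloc[src].copy()
        dup["individual_id"] = [f"{i}-b" for i in dup["individual_id"]]
        dup["duplicate_flag"] = True
        individuals = pd.concat([individuals, dup], ignore_index=True)

    # individuals eligible to carry a rare variant: those surviving every
    # exclusion step (of each in-set multiplet only the lowest id survives)
    surv = individuals[~individuals.duplicate_flag & ~individuals.missing_id_flag].copy()
    in_group = surv[surv.relatedness_group_id >= 0].sort_values("individual_id")
    keep_of_group = in_group.groupby("relatedness_group_id")["individual_id"].first()
    survivors = set(surv.loc[surv.relatedness_group_id < 0, "individual_id"]) | set(keep_of_group)
    n_analysis = len(survivors)
    eligible = np.array(sorted(survivors))

    # draw carrier counts and assign carriers without replacement
    if class_counts is not None:
        counts = dict(class_counts)
    else:
        counts = {c: int(rng.binomial(n_analysis, p)) for c, p in class_prevalences.items()}
    total_carriers = sum(counts.values())
    chosen = rng.choice(eligible, size=total_carriers, replace=False) if total_carriers else np.array([], dtype=object)

    sizes_pop = np.array(sorted(carriers_per_variant))
    sizes_p = np.array([carriers_per_variant[s] for s in sizes_pop], dtype=float)
    sizes_p = sizes_p / sizes_p.sum()

    positions = rng.choice(np.arange(1, CONTIG_LEN + 1), size=CONTIG_LEN, replace=False)
    bases = np.array(list("ACGT"))
    variants: list[VariantDef] = []
    geno_rows: list[tuple[str, str, int]] = []
    offset = 0
    pos_i = 0
    for cls in CLASSES:
        k = counts.get(cls, 0)
        carriers = list(chosen[offset : offset + k])
        offset += k
        while carriers:
            m = int(rng.choice(sizes_pop, p=sizes_p))
            m = min(m, len(carriers))
            vid = f"v{len(variants):03d}_{cls}"
            ref = str(rng.choice(bases))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(VariantDef(vid, int(positions[pos_i]), ref, alt, cls, m))
            pos_i += 1
            for ind in carriers[:m]:
                geno_rows.append((ind, vid, 1))
            carriers = carriers[m:]

    variants_df = pd.DataFrame(
        [(v.variant_id, CONTIG, v.pos, v.ref, v.alt, v.functional_class, v.carrier_count) for v in variants],
        columns=["variant_id", "contig", "pos", "ref", "alt", "functional_class", "carrier_count"],
    ).sort_values("pos", ignore_index=True)
    genotypes = pd.DataFrame(geno_rows, columns=["individual_id", "variant_id", "copies"])
    return CohortTruth(individuals, variants_df, genotypes)


def assign_pools(cohort: CohortTruth, pool_size: int, seed: int) -> pd.DataFrame:
    """Randomly combine every sequenced sample into pools of ``pool_size``.

    Returns a long DataFrame (pool_id, individual_id).  All pools have
    exactly ``pool_size`` members except possibly the last.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    seq = cohort.individuals.loc[cohort.individuals.sequenced, "individual_id"].to_numpy()
    if len(seq) == 0:
        raise ValueError("cohort has no sequenced individuals")
    rng = np.random.default_rng(seed)
    order = rng.permutation(seq)
    n_pools = int(np.ceil(len(order) / pool_size))
    rows = []
    for p in range(n_pools):
        for ind in order[p * pool_size : (p + 1) * pool_size]:
            rows.append((f"P{p:03d}", ind))
    return pd.DataFrame(rows, columns=["pool_id", "individual_id"])


@dataclass
class PoolPileups:
    """Per-pool, per-site strand-resolved allele counts plus site truth.

    ``frame`` columns: pool_id, contig, pos, ref, alt, ref_fwd, ref_rev,
    alt_fwd, alt_rev.  ``sites`` maps pos to the generating variant_id
    (empty string for injected error-only sites).
    """

    frame: pd.DataFrame
    sites: pd.DataFrame

    def write_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


PILEUP_COLUMNS = ["pool_id", "contig", "pos", "ref", "alt", "ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]


def read_pileups_tsv(path: str) -> pd.DataFrame:
    """Read a pileup table, reporting malformed rows with line numbers."""
    df = pd.read_csv(path, sep="\t", dtype={"pool_id": str, "contig": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ["pos", "ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any() or (bad < 0).any():
            lines = (np.nonzero(bad.isna() | (bad < 0))[0] + 2).tolist()
            raise ValueError(f"{path}: malformed {col} at line(s) {lines[:10]}")
        df[col] = bad.astype(int)
    return df


def _betabinom_draw(rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial counts with intra-site correlation rho (binomial at 0)."""
    out = np.zeros_like(n)
    pos = (p > 0) & (n > 0)
    if rho <= 0:
        out[pos] = rng.binomial(n[pos], p[pos])
        return out
    conc = 1.0 / rho - 1.0
    a = np.clip(p * conc, 1e-12, None)
    b = np.clip((1.0 - p) * conc, 1e-12, None)
    q = rng.beta(a[pos], b[pos])
    out[pos] = rng.binomial(n[pos], q)
    return out


def simulate_pool_pileups(
    design: pd.DataFrame,
    cohort: CohortTruth,
    config: SimulationConfig,
    seed: int | None = None,
) -> PoolPileups:
    """Simulate strand-resolved read counts for every pool x site.

    Per pool x site: depth ~ Poisson(mean_depth); the true alternate
    fraction is the contribution-weighted carrier allele fraction with
    lognormal per-sample weights (CV ``contribution_cv``); amplification
    bias and sequencing error move it to
    ``p = bias*p0 + eps*(1 - 2*p0)``; read counts are beta-binomial
    with correlation ``overdispersion``; each allele's reads split between
    strands as Binomial(0.5).  ``n_fp_sites`` error-only sites are
    injected, each manifesting as an elevated error rate (lognormal around
    ``fp_error_multiplier * base_error_rate``) in one randomly chosen pool
    — a localised library artifact — so the downstream ROC stage sees both
    classes.  Zero-depth sites are emitted with zero counts.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    eps = config.base_error_rate

    sites = cohort.variants[["variant_id", "contig", "pos", "ref", "alt"]].copy()
    used = set(sites.pos)
    free = [p for p in range(1, CONTIG_LEN + 1) if p not in used]
    fp_pos = rng.choice(free, size=config.n_fp_sites, replace=False) if config.n_fp_sites else []
    bases = "ACGT"
    fp_rows = []
    for p in fp_pos:
        ref = bases[rng.integers(4)]
        alt = rng.choice([b for b in bases if b != ref])
        fp_rows.append(("", CONTIG, int(p), ref, alt))
    if fp_rows:
        sites = pd.concat([sites, pd.DataFrame(fp_rows, columns=sites.columns)], ignore_index=True)
    sites = sites.sort_values("pos", ignore_index=True)
    is_fp = (sites.variant_id == "").to_numpy()
    pool_ids = sorted(design.pool_id.unique())
    fp_pool = np.array([rng.choice(pool_ids) if f else "" for f in is_fp], dtype=object)
    fp_eps = np.full(len(sites), eps)
    if is_fp.any() and eps > 0:
        fp_eps[is_fp] = np.exp(
            rng.normal(np.log(config.fp_error_multiplier * eps), config.fp_error_log_sd, int(is_fp.sum()))
        )
    sites = sites.assign(fp_pool=fp_pool)

    # carriers per variant, and the row index of each variant site
    carriers_by_variant: dict[str, list[tuple[str, int]]] = {}
    for r in cohort.genotypes.itertuples():
        carriers_by_variant.setdefault(r.variant_id, []).append((r.individual_id, r.copies))
    site_row = {v: j for j, v in enumerate(sites.variant_id) if v}

    pools = design.groupby("pool_id")["individual_id"].apply(list)
    records = []
    for pool_id, members in pools.items():
        k = len(members)
        if config.contribution_cv > 0:
            sigma2 = np.log1p(config.contribution_cv**2)
            w = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), k)
        else:
            w = np.ones(k)
        wsum = w.sum()
        member_idx = {ind: m for m, ind in enumerate(members)}
        p0 = np.zeros(len(sites))
        for vid, carriers in carriers_by_variant.items():
            acc = 0.0
            for ind, copies in carriers:
                m = member_idx.get(ind)
                if m is not None:
                    acc += w[m] * (copies / 2.0)
            if acc:
                p0[site_row[vid]] = acc / wsum
        site_eps = np.where(fp_pool == pool_id, fp_eps, eps)
        p = np.clip(config.amplification_bias * p0 + site_eps * (1.0 - 2.0 * p0), 0.0, 1.0)
        depth = rng.poisson(config.mean_depth, len(sites))
        alt = _betabinom_draw(rng, depth, p, config.overdispersion)
        ref = depth - alt
        alt_fwd = rng.binomial(alt, 0.5)
        ref_fwd = rng.binomial(ref, 0.5)
        for j, row in enumerate(sites.itertuples()):
            records.append(
                (
                    pool_id,
                    row.contig,
                    row.pos,
                    row.ref,
                    row.alt,
                    int(ref_fwd[j]),
                    int(ref[j] - ref_fwd[j]),
                    int(alt_fwd[j]),
                    int(alt[j] - alt_fwd[j]),
                )
            )
    frame = pd.DataFrame(records, columns=PILEUP_COLUMNS)
    return PoolPileups(frame=frame, sites=sites)


def simulate_sanger(
    cohort: CohortTruth,
    variant_id: str,
    individual_id: str,
    miss_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ValidationRecord:
    """Capillary re-sequencing oracle: returns the true genotype.

    Perfect by default; ``miss_rate`` is the probability a true carrier is
    reported as a non-carrier (useful for robustness experiments only).
    """
    if individual_id not in set(cohort.individuals.individual_id):
        raise KeyError(f"unknown individual {individual_id!r}")
    if variant_id not in set(cohort.variants.variant_id):
        raise KeyError(f"unknown variant {variant_id!r}")
    c = cohort.copies(individual_id, variant_id)
    if c > 0 and miss_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        if rng.random() < miss_rate:
            c = 0
    if c == 0:
        return ValidationRecord(individual_id, variant_id, False, None)
    return ValidationRecord(individual_id, variant_id, True, "het" if c == 1 else "hom")


# ---------------------------------------------------------------------------
# growth trajectories


@dataclass
class TraitSpec:
    """Generating model of one trait's piecewise-linear growth trajectory.

    The mean curve is intercept + per-interval slopes on a linear-spline
    basis anchored at ``start_age`` with the given knot ages.  ``sex_effects``
    and ``carrier_effects`` are additive offsets on (intercept, slope_1, ...,
    slope_K+1) for males and for loss-of-function carriers respectively.
    Individual heterogeneity is a random intercept (and optionally a random
    linear age slope) plus iid residual noise; ``schedule`` lists the
    measurement occasions as (age, probability the measure is present), so
    missingness is at random and typically increases with age.
    ``prs_beta`` shifts the whole curve by that many trait units per SD of
    the standardized polygenic score.
    """

    name: str
    start_age: float
    end_age: float
    knots: tuple[float, ...]
    intercept: float
    slopes: tuple[float, ...]
    sex_effects: tuple[float, ...]
    carrier_effects: tuple[float, ...]
    random_sd: tuple[float, ...]
    resid_sd: float
    schedule: tuple[tuple[float, float], ...]
    random_corr: float = 0.0
    prs_beta: float = 0.0

    def validate(self) -> None:
        ks = list(self.knots)
        if ks != sorted(ks) or len(set(ks)) != len(ks):
            raise ValueError("knots must be strictly increasing")
        if ks and (ks[0] <= self.start_age or ks[-1] >= self.end_age):
            raise ValueError("knots must lie strictly inside (start_age, end_age)")
        n_terms = len(ks) + 1
        for nm, eff in (("slopes", self.slopes), ):
            if len(eff) != n_terms:
                raise ValueError(f"{nm} must have {n_terms} entries")
        for nm, eff in (("sex_effects", self.sex_effects), ("carrier_effects", self.carrier_effects)):
            if len(eff) != n_terms + 1:
                raise ValueError(f"{nm} must have {n_terms + 1} entries (intercept + slopes)")
        if len(self.random_sd) not in (1, 2):
            raise ValueError("random_sd must be (intercept_sd,) or (intercept_sd, age_slope_sd)")
        if not (-1.0 < self.random_corr < 1.0):
            raise ValueError("random_corr must lie in (-1, 1)")
        cov = self.random_cov()
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("random-effects covariance not positive semi-definite")
        for age, p_obs in self.schedule:
            if not (self.start_age <= age <= self.end_age):
                raise ValueError(f"schedule age {age} outside [{self.start_age}, {self.end_age}]")
            if not (0.0 <= p_obs <= 1.0):
                raise ValueError("schedule probabilities must lie in [0,1]")

    def random_cov(self) -> np.ndarray:
        sd = np.asarray(self.random_sd, dtype=float)
        if len(sd) == 1:
            return np.array([[sd[0] ** 2]])
        r = self.random_corr
        return np.array(
            [[sd[0] ** 2, r * sd[0] * sd[1]], [r * sd[0] * sd[1], sd[1] ** 2]]
        )

    def gap_at(self, age: float) -> float:
        """Generating carrier-vs-reference mean difference at an age."""
        from .growth_models import spline_basis

        b = np.concatenate([[1.0], spline_basis(np.array([age]), self.knots, self.start_age)[0]])
        return float(b @ np.asarray(self.carrier_effects))


def default_bmi_spec() -> TraitSpec:
    """BMI (kg/m^2) from 18 months to 18 years; knots 3.5, 5, 8, 15 y.

    Anchored at a mean of 16.84 kg/m^2 at 18 months; carrier slope offsets
    accrue to a 4.84 kg/m^2 carrier-vs-reference gap at 18 years.
    """
    d = 4.84 / 16.5
    return TraitSpec(
        name="BMI",
        start_age=1.5,
        end_age=18.0,
        knots=(3.5, 5.0, 8.0, 15.0),
        intercept=16.84,
        slopes=(-0.32, -0.27, 0.17, 0.46, 0.90),
        sex_effects=(0.10, 0.0, 0.0, 0.0, -0.04, -0.10),
        carrier_effects=(0.0, d, d, d, d, d),
        random_sd=(1.1, 0.15),
        random_corr=0.25,
        resid_sd=0.8,
        schedule=((1.5, 0.9), (3.5, 0.85), (5.0, 0.8), (7.0, 0.85), (9.0, 0.8),
                  (11.0, 0.75), (13.0, 0.7), (15.0, 0.65), (18.0, 0.6)),
    )


def default_weight_spec() -> TraitSpec:
    """Weight (kg) from birth to 18 years; knots 1, 8, 15 y.

    Birth weight anchored at 3.44 kg; carrier slope offsets of 0.84 kg/y
    (1-8 y) and 1.33 kg/y (8-15 y) with flanking offsets chosen so the
    18-year carrier gap is 17.76 kg.
    """
    return TraitSpec(
        name="weight",
        start_age=0.0,
        end_age=18.0,
        knots=(1.0, 8.0, 15.0),
        intercept=3.44,
        slopes=(6.6, 2.2, 4.2, 3.3),
        sex_effects=(0.12, 0.3, 0.05, 0.25, 0.8),
        carrier_effects=(0.0, 0.5, 0.84, 1.33, 0.69),
        random_sd=(0.45, 0.6),
        random_corr=0.3,
        resid_sd=1.5,
        schedule=((0.0, 0.95), (1.0, 0.9), (3.5, 0.85), (5.0, 0.8), (7.0, 0.85),
                  (9.0, 0.8), (11.0, 0.75), (13.0, 0.7), (15.0, 0.65), (18.0, 0.6)),
    )


def default_height_spec() -> TraitSpec:
    """Height (cm) from 18 months to 18 years; knots 5 and 15 y."""
    return TraitSpec(
        name="height",
        start_age=1.5,
        end_age=18.0,
        knots=(5.0, 15.0),
        intercept=81.90,
        slopes=(8.0, 5.5, 2.3),
        sex_effects=(0.8, 0.1, 0.2, 2.5),
        carrier_effects=(0.0, 0.45, 0.45, -0.5),
        random_sd=(3.0, 0.35),
        random_corr=0.2,
        resid_sd=1.2,
        schedule=((1.5, 0.9), (3.5, 0.85), (5.0, 0.8), (7.0, 0.85), (9.0, 0.8),
                  (11.0, 0.75), (13.0, 0.7), (15.0, 0.65), (18.0, 0.6)),
    )


def simulate_trajectories(
    cohort: CohortTruth,
    spec: TraitSpec,
    seed: int,
    carrier_ids: set[str] | None = None,
    individual_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format trait measurements under the two-level spline model.

    Returns columns (individual_id, trait, age_years, value, sex, carrier).
    ``carrier_ids`` defaults to the cohort's pLoF+cLoF carriers.
    """
    from .growth_models import spline_basis

    spec.validate()
    rng = np.random.default_rng(seed)
    if individual_ids is None:
        inds = cohort.individuals[~cohort.individuals.duplicate_flag]
    else:
        inds = cohort.individuals[cohort.individuals.individual_id.isin(individual_ids)]
    ids = inds.individual_id.to_numpy()
    male = (inds.sex == "M").to_numpy(dtype=float)
    if carrier_ids is None:
        carrier_ids = set(cohort.carrier_ids(("pLoF", "cLoF")))
    carrier = np.array([i in carrier_ids for i in ids], dtype=float)
    prs = inds.prs_score.to_numpy(dtype=float)
    if spec.prs_beta != 0.0 and np.isnan(prs).all():
        raise ValueError("prs_beta set but cohort has no polygenic scores")
    prs_z = np.zeros(len(ids))
    if spec.prs_beta != 0.0:
        prs_z = (prs - np.nanmean(prs)) / np.nanstd(prs)
        prs_z = np.nan_to_num(prs_z)

    ages = np.array([a for a, _ in spec.schedule])
    p_obs = np.array([p for _, p in spec.schedule])
    basis = spline_basis(ages, spec.knots, spec.start_age)  # (n_ages, n_terms)
    full = np.column_stack([np.ones(len(ages)), basis])      # intercept + slopes

    mean_pop = full @ np.concatenate([[spec.intercept], spec.slopes])
    mean_sex = full @ np.asarray(spec.sex_effects)
    mean_car = full @ np.asarray(spec.carrier_effects)

    cov = spec.random_cov()
    q = cov.shape[0]
    if np.trace(cov) == 0.0:
        b = np.zeros((len(ids), q))
    else:
        chol = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) / q * np.eye(q))
        b = rng.standard_normal((len(ids), q)) @ chol.T
    z_age = np.column_stack([np.ones(len(ages)), ages - spec.start_age])[:, :q]

    values = (
        mean_pop[None, :]
        + male[:, None] * mean_sex[None, :]
        + carrier[:, None] * mean_car[None, :]
        + b @ z_age.T
        + spec.prs_beta * prs_z[:, None]
        + rng.normal(0.0, spec.resid_sd, (len(ids), len(ages)))
    )
    present = rng.random((len(ids), len(ages))) < p_obs[None, :]

    ii, jj = np.nonzero(present)
    out = pd.DataFrame(
        {
            "individual_id": ids[ii],
            "trait": spec.name,
            "age_years": ages[jj],
            "value": values[ii, jj],
            "sex": np.where(male[ii] > 0, "M", "F"),
            "carrier": carrier[ii].astype(int),
        }
    )
    return out


# ---------------------------------------------------------------------------
# assays and polygenic scores


@dataclass
class AssayProfile:
    """True dose-response characteristics of one receptor variant."""

    emax: float           # % of wild-type maximal response
    logec50: float        # log10 molar
    basal: float = 0.0
    hill: float = 1.0
    clof: bool = False    # no ligand response at all


WT_PROFILE = AssayProfile(emax=100.0, logec50=-9.0)

DEFAULT_DOSES = tuple(10.0 ** np.arange(-12, -5))  # 1e-12 .. 1e-6 M


def four_pl(log_dose: np.ndarray, basal: float, emax: float, logec50: float, hill: float) -> np.ndarray:
    expo = np.clip((logec50 - log_dose) * hill, -300.0, 300.0)
    return basal + (emax - basal) / (1.0 + 10.0**expo)


def simulate_assay(
    profile: AssayProfile,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    variant_id: str = "variant",
    assay: str = "cAMP",
) -> pd.DataFrame:
    """Replicate dose-response measurements around a logistic mean curve.

    cLoF profiles respond flat at baseline.  Returns long format columns
    (variant, assay, replicate, dose, response).
    """
    doses_arr = np.asarray(doses, dtype=float)
    if np.any(doses_arr <= 0):
        raise ValueError("doses must be positive (molar)")
    if len(doses_arr) < 4:
        raise ValueError("need >= 4 dose levels for identifiable fits")
    rng = np.random.default_rng(seed)
    x = np.log10(doses_arr)
    mean = np.full_like(x, profile.basal) if profile.clof else four_pl(
        x, profile.basal, profile.emax, profile.logec50, profile.hill
    )
    rows = []
    for rep in range(replicates):
        y = mean + rng.normal(0.0, noise_sd, len(x))
        for d, v in zip(doses_arr, y):
            rows.append((variant_id, assay, rep, d, v))
    return pd.DataFrame(rows, columns=["variant", "assay", "replicate", "dose", "response"])


def trait_variance_at(spec: TraitSpec, age: float) -> float:
    """Total phenotypic variance of the generating model at one age
    (random effects plus residual; excludes PRS and fixed contrasts)."""
    t = age - spec.start_age
    cov = spec.random_cov()
    z = np.array([1.0, t])[: cov.shape[0]]
    return float(z @ cov @ z + spec.resid_sd**2)


def prs_beta_for_r2(spec: TraitSpec, r2: float, age: float = 18.0) -> float:
    """Score loading (trait units per SD) giving the target variance
    explained at an age: solves r2 = beta^2 / (var(age) + beta^2)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must lie in [0, 1)")
    return float(np.sqrt(r2 * trait_variance_at(spec, age) / (1.0 - r2)))


def simulate_prs(cohort: CohortTruth, mean: float = 0.0, sd: float = 1.0, seed: int = 0) -> pd.Series:
    """Draw a Gaussian polygenic score per individual (stored on the cohort).

    Coupling with trajectories is configured on :class:`TraitSpec` via
    ``prs_beta`` (trait units per SD of score), which is how a target
    variance-explained is dialled in.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    scores = mean + sd * rng.standard_normal(len(cohort.individuals))
    cohort.individuals["prs_score"] = scores
    return pd.Series(scores, index=cohort.individuals.individual_id, name="prs_score")


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
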