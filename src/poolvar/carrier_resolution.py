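"""Carrier resolution, cohort exclusions, prevalence and allele frequency.

After validation, each confirmed pooled call is resolved to the specific
individuals carrying the variant.  The cohort registry is then reduced to
the analysis set through an ordered, fully-audited exclusion ledger
(missing identifiers, duplicated aliquots, relatedness), and per-class
carrier prevalence and per-variant minor allele frequencies are estimated
with exact binomial confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: most-severe-first ordering used when one individual carries two variants
SEVERITY = ("cLoF", "pLoF", "GoF", "WT-like")

LOF_CLASSES = ("pLoF", "cLoF")


def resolve_carriers(
    confirmed_calls: pd.DataFrame,
    pool_design: pd.DataFrame,
    validations: pd.DataFrame,
    variant_classes: dict[str, str] | None = None,
    site_to_variant: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Map confirmed pooled calls to individual carriers with zygosity.

    ``validations`` is long format (pool_id, pos, individual_id, carrier,
    zygosity).  Each confirmed (pool, site) call is assigned the validated
    carriers among that pool's members.  A confirmed call with no validated
    carrier in its pool is an inconsistency and raises.  Returns a
    CarrierTable frame (individual_id, variant_id, zygosity,
    functional_class) with one record per (individual, variant).
    """
    members = pool_design.groupby("pool_id")["individual_id"].apply(set)
    rows = []
    for call in confirmed_calls.itertuples():
        vs = validations[
            (validations.pool_id == call.pool_id)
            & (validations.pos == call.pos)
            & validations.carrier
        ]
        if vs.empty:
            raise ValueError(
                f"confirmed call at {call.contig}:{call.pos} in {call.pool_id} has no validated carrier"
            )
        vid = site_to_variant.get(call.pos, str(call.pos)) if site_to_variant else str(call.pos)
        for v in vs.itertuples():
            if v.individual_id not in members.get(call.pool_id, set()):
                raise ValueError(f"validated carrier {v.individual_id} not a member of {call.pool_id}")
            cls = variant_classes.get(vid, "") if variant_classes else ""
            rows.append((v.individual_id, vid, v.zygosity, cls))
    out = pd.DataFrame(rows, columns=["individual_id", "variant_id", "zygosity", "functional_class"])
    return out.drop_duplicates(["individual_id", "variant_id"], ignore_index=True)


@dataclass
class ExclusionLedger:
    """Ordered record of registry exclusions; conserves individuals."""

    steps: pd.DataFrame  # columns: reason, n_removed, remaining

    @property
    def final_n(self) -> int:
        return int(self.steps.remaining.iloc[-1])

    def validate(self, n_start: int) -> None:
        removed = int(self.steps.n_removed.sum())
        if n_start != self.final_n + removed:
            raise AssertionError("ledger does not conserve individuals")


def apply_exclusions(registry: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Reduce a registry to the analysis set with an audited ledger.

    Order of operations is fixed: (1) drop missing-identifier rows; (2)
    drop duplicated aliquots; (3) for relatedness groups spanning the
    sequenced/unsequenced boundary, drop the unsequenced members; (4) of
    each multiplet lying fully inside the sequenced set keep exactly one
    member (deterministically the lowest id).  The registry needs columns
    individual_id, duplicate_flag, missing_id_flag, relatedness_group_id
    (negative for singletons) and, optionally, sequenced.
    """
    df = registry.copy()
    if "sequenced" not in df.columns:
        df["sequenced"] = True
    steps = []
    n0 = len(df)

    m = df.missing_id_flag.astype(bool)
    df = df[~m]
    steps.append(("missing identifier", int(m.sum()), len(df)))

    d = df.duplicate_flag.astype(bool)
    df = df[~d]
    steps.append(("duplicated aliquot", int(d.sum()), len(df)))

    grouped = df[df.relatedness_group_id >= 0]
    mixed = 0
    drop_ids: list[str] = []
    for gid, grp in grouped.groupby("relatedness_group_id"):
        if grp.sequenced.all() or not grp.sequenced.any():
            continue
        unseq = grp.loc[~grp.sequenced, "individual_id"]
        drop_ids.extend(unseq)
        mixed += len(unseq)
    df = df[~df.individual_id.isin(drop_ids)]
    steps.append(("unsequenced member of mixed sibling set", mixed, len(df)))

    grouped = df[(df.relatedness_group_id >= 0) & df.sequenced]
    keep = grouped.sort_values("individual_id").groupby("relatedness_group_id").head(1)
    drop = grouped[~grouped.individual_id.isin(keep.individual_id)]
    df = df[~df.individual_id.isin(drop.individual_id)]
    steps.append(("sibling within sequenced set (kept lowest id)", len(drop), len(df)))

    ledger = ExclusionLedger(pd.DataFrame(steps, columns=["reason", "n_removed", "remaining"]))
    ledger.validate(n0)
    return df.reset_index(drop=True), ledger


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class PrevalenceTable:
    """Per-class carrier counts with exact 95% CIs, plus LoF aggregates."""

    frame: pd.DataFrame   # class, count, percent, ci_low_percent, ci_high_percent
    n_total: int
    lof_count: int
    lof_percent: float
    one_in_k: int | None
    lof_ci_percent: tuple[float, float]


def estimate_prevalence(carriers: pd.DataFrame, n_total: int, conf: float = 0.95) -> PrevalenceTable:
    """Per-class prevalence among ``n_total`` analysed individuals.

    An individual carrying several variants counts once, in the most
    severe class (cLoF > pLoF > GoF > WT-like).  Loss of function
    aggregates pLoF + cLoF; its headline "1 in k" uses k = round(N/count).
    Percentages are rounded to two decimals as in a printed prevalence
    table; CIs are exact (Clopper-Pearson).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    best: dict[str, str] = {}
    rank = {c: i for i, c in enumerate(SEVERITY)}
    for row in carriers.itertuples():
        cls = row.functional_class
        if cls not in rank:
            raise ValueError(f"unknown functional class {cls!r}")
        cur = best.get(row.individual_id)
        if cur is None or rank[cls] < rank[cur]:
            best[row.individual_id] = cls
    counts = {c: 0 for c in SEVERITY}
    for cls in best.values():
        counts[cls] += 1
    n_carriers = sum(counts.values())
    if n_carriers > n_total:
        raise ValueError("more carriers than individuals in the analysis set")

    rows = []
    order = ("GoF", "WT-like", "pLoF", "cLoF")
    rows.append(("non-carrier", n_total - n_carriers, *_pct_ci(n_total - n_carriers, n_total, conf)))
    for cls in order:
        rows.append((cls, counts[cls], *_pct_ci(counts[cls], n_total, conf)))
    frame = pd.DataFrame(rows, columns=["class", "count", "percent", "ci_low_percent", "ci_high_percent"])

    lof = counts["pLoF"] + counts["cLoF"]
    lof_pct, lof_lo, lof_hi = _pct_ci(lof, n_total, conf)
    one_in_k = int(round(n_total / lof)) if lof else None
    return PrevalenceTable(frame, n_total, lof, lof_pct, one_in_k, (lof_lo, lof_hi))


def _pct_ci(k: int, n: int, conf: float) -> tuple[float, float, float]:
    lo, hi = clopper_pearson(k, n, conf)
    return round(100.0 * k / n, 2), round(100.0 * lo, 2), round(100.0 * hi, 2)


def compute_maf(carrier_count: int, n_total: int, zygosity: str = "het") -> float:
    """Minor allele frequency in percent, rounded to four decimals.

    Heterozygous carriers contribute one allele copy each (homozygous two)
    among 2N chromosomes.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if zygosity not in ("het", "hom"):
        raise ValueError("zygosity must be 'het' or 'hom'")
    copies = carrier_count * (1 if zygosity == "het" else 2)
    if copies > 2 * n_total:
        raise ValueError("allele copies exceed 2N")
    return round(100.0 * copies / (2.0 * n_total), 4)


def variant_table(carriers: pd.DataFrame, n_total: int) -> pd.DataFrame:
    """Per-variant summary (variant, class, carriers, MAF%) from a CarrierTable."""
    rows = []
    for vid, grp in carriers.groupby("variant_id"):
        het = int((grp.zygosity == "het").sum())
        hom = int((grp.zygosity == "hom").sum())
        maf = round(100.0 * (het + 2 * hom) / (2.0 * n_total), 4)
        cls = grp.functional_class.iloc[0]
        rows.append((vid, cls, len(grp), maf))
    return pd.DataFrame(rows, columns=["variant_id", "functional_class", "carriers", "maf_percent"])


def crosstab_obesity(
    carrier_ids: set[str],
    bmi: pd.Series,
    cutpoints: tuple[float, float] = (25.0, 30.0),
) -> dict:
    """Cross-tabulate adiposity categories against carrier status.

    ``bmi`` is indexed by individual_id (one measurement age, e.g. 18
    years).  Returns overweight-or-obese percentages within carriers and
    non-carriers, the overall obesity percentage, and the percentage of
    LoF carriers among obese vs non-obese individuals.  Empty strata are
    reported as NaN, never as 0.
    """
    overweight_cut, obese_cut = cutpoints
    bmi = bmi.dropna()
    is_carrier = bmi.index.isin(list(carrier_ids))
    n = len(bmi)
    if n == 0:
        raise ValueError("no BMI measurements supplied")
    obese = bmi >= obese_cut
    over = bmi >= overweight_cut

    def pct(mask: np.ndarray, of: np.ndarray) -> float:
        denom = int(np.sum(of))
        return round(100.0 * float(np.sum(mask & of)) / denom, 2) if denom else float("nan")

    return {
        "n": n,
        "n_obese": int(obese.sum()),
        "pct_obese_overall": round(100.0 * float(obese.mean()), 2),
        "pct_overweight_or_obese_carriers": pct(over.to_numpy(), is_carrier),
        "pct_overweight_or_obese_noncarriers": pct(over.to_numpy(), ~is_carrier),
        "pct_carriers_among_obese": pct(is_carrier, obese.to_numpy()),
        "pct_carriers_among_nonobese": pct(is_carrier, ~obese.to_numpy()),
    }


def write_prevalence_tsv(table: PrevalenceTable, path: str) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_carriers_vcf(
    carriers: pd.DataFrame,
    variants: pd.DataFrame,
    path: str,
    contig_length: int = 10000,
) -> None:
    """Write confirmed variants as a VCF with per-sample genotype columns."""
    import pysam

    header = pysam.VariantHeader()
    for c in variants.contig.unique():
        header.contigs.add(str(c), length=contig_length)
    header.info.add("CLASS", 1, "String", "Functional class of the variant")
    header.formats.add("GT", 1, "String", "Genotype")
    samples = sorted(set(carriers.individual_id))
    for s in samples:
        header.add_sample(s)
    vmap = variants.set_index("variant_id")
    with pysam.VariantFile(path, "w", header=header) as vf:
        for vid, grp in carriers.groupby("variant_id"):
            if vid not in vmap.index:
                continue
            v = vmap.loc[vid]
            rec = vf.new_record(
                contig=str(v.contig), start=int(v.pos) - 1, stop=int(v.pos),
                alleles=(str(v.ref), str(v.alt)), id=str(vid),
            )
            rec.info["CLASS"] = str(v.functional_class)
            zyg = dict(zip(grp.individual_id, grp.zygosity))
            for s in samples:
                z = zyg.get(s)
                if z == "het":
                    rec.samples[s]["GT"] = (0, 1)
                elif z == "hom":
                    rec.samples[s]["GT"] = (1, 1)
                else:
                    rec.samples[s]["GT"] = (0, 0)
            vf.write(rec)
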