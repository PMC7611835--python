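"""Rare-variant candidate calling from pooled per-site allele counts.

A heterozygous carrier in a pool of P diploid samples contributes an
expected alternate-allele fraction of 1/(2P) — 1% for pools of 50 — so
candidate calling is a matter of separating low-VAF signal from the base
error floor.  A site passes when its VAF and coverage clear configurable
thresholds, a one-sided exact binomial test rejects the null error rate,
and (optionally) alternate reads are adequately represented on both
strands.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CallConfig:
    """Screening criteria for pooled candidate calls.

    The significance test is a one-sided exact binomial tail
    P(X >= alt | depth, error_rate_null).  The strand filter requires at
    least ``strand_min_reads_each`` alternate reads on each strand and a
    minor-strand alternate fraction of at least ``strand_min_fraction``
    (a 90/10-style rule).  ``vaf_min`` defaults to the 0.5% initial
    screening cut-off used ahead of validation-driven recalibration.
    """

    vaf_min: float = 0.005
    coverage_min: int = 100
    alpha: float = 0.05
    error_rate_null: float = 0.001
    strand_filter_on: bool = True
    strand_min_fraction: float = 0.1
    strand_min_reads_each: int = 1

    def validate(self) -> None:
        if not (0.0 < self.vaf_min < 1.0):
            raise ValueError("vaf_min must lie in (0,1)")
        if self.coverage_min < 1:
            raise ValueError("coverage_min must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0,1)")
        if not (0.0 < self.error_rate_null < 1.0):
            raise ValueError("error_rate_null must lie in (0,1)")


@dataclass
class CandidateCall:
    pool_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    vaf: float
    p_value: float
    strand_pass: bool
    passed: bool
    depth_zero: bool = False
    estimated_carriers: int | None = None


def expected_pool_vaf(n_het: int, pool_size: int) -> float:
    """Theoretical VAF of ``n_het`` heterozygous carriers in an equimolar pool.

    One heterozygote contributes one alternate allele among 2*pool_size
    allele copies, so the expectation is ``n_het / (2 * pool_size)``.
    """
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    if not (0 <= n_het <= pool_size):
        raise ValueError("n_het must lie in [0, pool_size]")
    return n_het / (2.0 * pool_size)


def binomial_tail_pvalue(alt_reads: int, depth: int, error_rate: float) -> float:
    """One-sided exact tail P(X >= alt_reads) for X ~ Binomial(depth, error_rate)."""
    if alt_reads <= 0:
        return 1.0
    return float(stats.binom.sf(alt_reads - 1, depth, error_rate))


def call_site(
    ref_fwd: int,
    ref_rev: int,
    alt_fwd: int,
    alt_rev: int,
    config: CallConfig,
    pool_id: str = "",
    contig: str = "",
    pos: int = 0,
    ref: str = "N",
    alt: str = "N",
    pool_size: int | None = None,
) -> CandidateCall:
    """Evaluate the screening criteria on one pool x site count quartet.

    The VAF denominator is ref+alt reads.  A zero-depth site yields a
    not-passed call with VAF reported as 0 and ``depth_zero`` set.
    """
    for v in (ref_fwd, ref_rev, alt_fwd, alt_rev):
        if v < 0:
            raise ValueError("read counts must be non-negative")
    config.validate()
    alt_reads = alt_fwd + alt_rev
    depth = ref_fwd + ref_rev + alt_reads
    if depth == 0:
        return CandidateCall(pool_id, contig, pos, ref, alt, 0, 0, 0.0, 1.0, False, False, depth_zero=True)
    vaf = alt_reads / depth
    p_value = binomial_tail_pvalue(alt_reads, depth, config.error_rate_null)
    if config.strand_filter_on:
        lo = min(alt_fwd, alt_rev)
        strand_pass = (
            lo >= config.strand_min_reads_each
            and alt_reads > 0
            and lo / alt_reads >= config.strand_min_fraction
        )
    else:
        strand_pass = True
    passed = (
        vaf >= config.vaf_min
        and depth >= config.coverage_min
        and p_value < config.alpha
        and strand_pass
    )
    est = int(round(vaf * 2 * pool_size)) if pool_size is not None else None
    return CandidateCall(pool_id, contig, pos, ref, alt, depth, alt_reads, vaf, p_value, strand_pass, passed,
                         estimated_carriers=est)


def call_pools(
    pileups: pd.DataFrame,
    config: CallConfig,
    pool_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Run the site caller across a pileup table.

    Emits one record per pool x site with at least one alternate read (plus
    zero-depth sites, flagged), ordered by (contig, pos, pool_id).
    Estimated carriage per call is ``round(VAF * 2 * pool_size)`` when pool
    sizes are supplied.
    """
    config.validate()
    out_columns = [
        "pool_id", "contig", "pos", "ref", "alt", "depth", "alt_reads", "vaf",
        "p_value", "strand_pass", "passed", "depth_zero", "estimated_carriers",
    ]
    if len(pileups) == 0:
        return pd.DataFrame(columns=out_columns)
    alt = (pileups.alt_fwd + pileups.alt_rev).to_numpy()
    depth = (alt + pileups.ref_fwd.to_numpy() + pileups.ref_rev.to_numpy())
    keep = (alt > 0) | (depth == 0)
    df = pileups.loc[keep].reset_index(drop=True)
    alt, depth = alt[keep], depth[keep]

    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    p_value = np.ones(len(df))
    nz = alt > 0
    p_value[nz] = stats.binom.sf(alt[nz] - 1, depth[nz], config.error_rate_null)
    if config.strand_filter_on:
        lo = np.minimum(df.alt_fwd.to_numpy(), df.alt_rev.to_numpy())
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(alt > 0, lo / np.maximum(alt, 1), 0.0)
        strand_pass = (lo >= config.strand_min_reads_each) & (alt > 0) & (frac >= config.strand_min_fraction)
    else:
        strand_pass = np.ones(len(df), dtype=bool)
    passed = (
        (vaf >= config.vaf_min)
        & (depth >= config.coverage_min)
        & (p_value < config.alpha)
        & strand_pass
    )
    est = np.full(len(df), np.nan)
    if pool_sizes:
        sizes = df.pool_id.map(pool_sizes).to_numpy(dtype=float)
        est = np.round(vaf * 2 * sizes)
    out = pd.DataFrame(
        {
            "pool_id": df.pool_id,
            "contig": df.contig,
            "pos": df.pos,
            "ref": df.ref,
            "alt": df.alt,
            "depth": depth,
            "alt_reads": alt,
            "vaf": vaf,
            "p_value": p_value,
            "strand_pass": strand_pass,
            "passed": passed,
            "depth_zero": depth == 0,
            "estimated_carriers": est,
        }
    )
    return out.sort_values(["contig", "pos", "pool_id"], ignore_index=True)


def write_calls_tsv(calls: pd.DataFrame, path: str) -> None:
    calls.to_csv(path, sep="\t", index=False)


def write_calls_vcf(calls: pd.DataFrame, path: str, contig_length: int = 10000) -> None:
    """Write one VCF record per passing site, aggregating pools in INFO.

    INFO keys: VAF (mean across passing pools), DP (mean depth), PP (min
    binomial tail p-value), POOLS (comma-joined pool ids).
    """
    import pysam

    header = pysam.VariantHeader()
    contigs = calls.contig.unique() if len(calls) else []
    for c in contigs:
        header.contigs.add(str(c), length=contig_length)
    header.info.add("VAF", 1, "Float", "Mean variant allele fraction across passing pools")
    header.info.add("DP", 1, "Integer", "Mean read depth across passing pools")
    header.info.add("PP", 1, "Float", "Minimum binomial tail p-value across passing pools")
    header.info.add("POOLS", 1, "String", "Pools in which the site passed")
    with pysam.VariantFile(path, "w", header=header) as vf:
        passing = calls[calls.passed]
        for (contig, pos, ref, alt), grp in passing.groupby(["contig", "pos", "ref", "alt"], sort=True):
            rec = vf.new_record(
                contig=str(contig), start=int(pos) - 1, stop=int(pos),
                alleles=(str(ref), str(alt)),
            )
            rec.info["VAF"] = float(grp.vaf.mean())
            rec.info["DP"] = int(round(grp.depth.mean()))
            rec.info["PP"] = float(grp.p_value.min())
            rec.info["POOLS"] = ",".join(sorted(grp.pool_id))
            vf.write(rec)


def read_calls_tsv(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t")
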