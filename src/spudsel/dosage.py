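"""Five-class tetraploid dosage calling and variant-level filtering.

A tetraploid genotype is one of AAAA, AAAB, AABB, ABBB, BBBB (A = reference
allele) and is coded as the reference-allele frequency {1, 0.75, 0.5, 0.25, 0}.
Calling is nearest-class assignment of the observed reference-read fraction
with class boundaries at {0.125, 0.375, 0.625, 0.875} — the maximum-likelihood
rule under symmetric binomial read sampling.  Fractions landing exactly on a
boundary are assigned to the upper class (np.digitize convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .matrices import CLASS_CODES, DosageMatrix, ReadCountMatrix

_BIN_EDGES = np.array([0.125, 0.375, 0.625, 0.875])

#: First-failing-reason attribution order for the filter report.
FILTER_REASONS = ["depth_fail", "alt_support_fail", "fraction_fail", "missing_fail", "maf_fail"]


def call_dosages(
    counts: ReadCountMatrix, min_depth: int = 5, min_het_alt: int = 2
) -> DosageMatrix:
    """Call five-class dosages from ref/alt read counts.

    Cells with total depth < ``min_depth`` are missing.  A cell whose
    alternate support is positive but below ``min_het_alt`` reads cannot be
    called heterozygous: if nearest-class assignment would give AAAB/AABB/ABBB
    it is set to homozygous reference instead (the "minimum two alternate
    bases to call a heterozygote" rule).
    """
    if min_depth < 1 or min_het_alt < 1:
        raise ValueError("min_depth and min_het_alt must be >= 1")
    depth = counts.total_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_frac = np.where(depth > 0, counts.ref_depth / np.maximum(depth, 1), np.nan)
    codes = CLASS_CODES[np.digitize(ref_frac, _BIN_EDGES)]
    weak_alt = (counts.alt_depth >= 1) & (counts.alt_depth < min_het_alt)
    het = (codes > 0) & (codes < 1)
    codes = np.where(weak_alt & het, 1.0, codes)
    codes = np.where(depth < min_depth, np.nan, codes)
    return DosageMatrix(
        samples=list(counts.samples), loci=counts.loci.copy(), codes=codes
    )


@dataclass
class FilterReport:
    """Per-locus filter outcome with exclusive first-failing-reason labels.

    ``table`` has one boolean column per reason in :data:`FILTER_REASONS`, a
    ``reason`` column holding the first failing reason ("" if retained) and a
    ``retained`` column.  ``counts`` gives the survivor count after each
    cumulative stage; a locus is counted against exactly one reason, so
    n_retained = n_input - sum(per-reason exclusive failures).
    """

    table: pd.DataFrame
    counts: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.table)

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())

    def reason_counts(self) -> dict[str, int]:
        return {
            r: int((self.table["reason"] == r).sum()) for r in FILTER_REASONS
        }


def filter_variants(
    dosages: DosageMatrix,
    counts: ReadCountMatrix | None = None,
    min_alt_reads_any: int = 5,
    min_alt_fraction_any: float = 0.4,
    max_missing: float = 0.5,
    min_maf: float = 0.05,
) -> tuple[DosageMatrix, FilterReport]:
    """Apply the variant-retention cascade; return survivors and a report.

    A locus survives iff all hold:

    * not every genotype is missing (``depth_fail`` otherwise);
    * at least one sample shows >= ``min_alt_reads_any`` alternate reads
      (``alt_support_fail``) and among such samples at least one has an
      alternate-read fraction >= ``min_alt_fraction_any`` (``fraction_fail``);
      both are skipped when no read counts are supplied;
    * the missing fraction is strictly below ``max_missing`` — loci with "50%
      or more" missing genotypes are removed (``missing_fail``);
    * MAF strictly exceeds ``min_maf`` — "5% or less" is removed — where
      MAF = min(p, 1-p) with p the mean dosage code over non-missing samples
      (``maf_fail``).
    """
    if dosages.n_loci == 0 or dosages.n_samples == 0:
        raise ValueError("cannot filter an empty dosage matrix")
    if not (0 < max_missing <= 1 and 0 <= min_maf < 0.5):
        raise ValueError("thresholds out of range")
    codes = dosages.codes
    missing = np.isnan(codes)
    n_obs = (~missing).sum(axis=0)

    depth_fail = n_obs == 0
    if counts is not None:
        alt = counts.alt_depth
        total = counts.total_depth
        strong = alt >= min_alt_reads_any
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
        alt_support_fail = ~strong.any(axis=0)
        fraction_fail = ~(strong & (frac >= min_alt_fraction_any)).any(axis=0)
        fraction_fail &= ~alt_support_fail
    else:
        alt_support_fail = np.zeros(dosages.n_loci, dtype=bool)
        fraction_fail = np.zeros(dosages.n_loci, dtype=bool)

    missing_fail = missing.mean(axis=0) >= max_missing
    with np.errstate(invalid="ignore"):
        p_bar = np.nanmean(np.where(depth_fail, np.nan, codes), axis=0)
    maf = np.minimum(p_bar, 1.0 - p_bar)
    maf_fail = np.where(np.isnan(maf), True, maf <= min_maf)

    flags = {
        "depth_fail": depth_fail,
        "alt_support_fail": alt_support_fail,
        "fraction_fail": fraction_fail,
        "missing_fail": missing_fail,
        "maf_fail": maf_fail,
    }
    reason = np.full(dosages.n_loci, "", dtype=object)
    assigned = np.zeros(dosages.n_loci, dtype=bool)
    survivors = np.ones(dosages.n_loci, dtype=bool)
    counts_out: dict[str, int] = {"input": dosages.n_loci}
    for name in FILTER_REASONS:
        fail = flags[name]
        newly = fail & ~assigned
        reason[newly] = name
        assigned |= newly
        survivors &= ~fail
        counts_out[f"after_{name}"] = int(survivors.sum())
    table = pd.concat(
        [
            dosages.loci.reset_index(drop=True),
            pd.DataFrame({n: flags[n] for n in FILTER_REASONS}),
        ],
        axis=1,
    )
    table["reason"] = reason
    table["retained"] = ~assigned
    report = FilterReport(table=table, counts=counts_out)
    return dosages.subset_loci(~assigned), report


def density_bins(
    loci: pd.DataFrame, layout: GenomeLayout, bin_bp: int = 100_000
) -> pd.DataFrame:
    """SNP counts in half-open bins [start, start+bin_bp) tiling each chromosome.

    Bins start at position 1, so bin i covers [1+(i-1)*bin_bp, 1+i*bin_bp);
    position ``bin_bp`` itself falls in the first bin.  All bins of every
    chromosome in the layout are emitted, including empty ones, and the counts
    sum to the total number of loci.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    lengths = layout.chromosome_lengths
    for _, row in loci.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in lengths:
            raise ValueError(f"locus {chrom}:{pos} on unknown chromosome")
        if not 1 <= pos <= lengths[chrom]:
            raise ValueError(
                f"locus {chrom}:{pos} beyond chromosome length {lengths[chrom]}"
            )
    rows = []
    for chrom, length in layout.chromosomes:
        n_bins = int(np.ceil(length / bin_bp))
        counts = np.zeros(n_bins, dtype=np.int64)
        on_chrom = loci.loc[loci["chrom"] == chrom, "pos"].to_numpy()
        if on_chrom.size:
            idx = (on_chrom - 1) // bin_bp
            np.add.at(counts, idx, 1)
        for i in range(n_bins):
            rows.append(
                (chrom, 1 + i * bin_bp, min(1 + (i + 1) * bin_bp - 1, length), counts[i])
            )
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "n_snps"])
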