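"""Synthetic tetraploid cohorts with known truth.

The generator emulates a commercial autotetraploid cultivar collection
genotyped by transcriptome sequencing: biallelic markers placed inside gene
intervals on the 12 potato chromosomes, LD structured by a per-block founder
haplotype pool, Poisson sequencing depth with binomial allele sampling and a
symmetric base-error rate, additive polygenic phenotypes at a target
heritability, and missing-completely-at-random genotype dropout.

LD model: loci are grouped into physical blocks of ``ld_block_bp``; each block
carries a small founder haplotype pool (default 4) and every sample draws its
four homologous chromosomes i.i.d. from that pool, so loci in one block share
founder identity and are correlated while blocks are independent.  The
effective allele-frequency granularity is 1/n_founders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout, default_layout
from .matrices import DosageMatrix, PhenotypeTable, ReadCountMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort: complete dosages, effects, h2."""

    true_dosage: DosageMatrix
    true_effects: np.ndarray
    h2_target: float
    seed: int

    def __post_init__(self) -> None:
        if np.isnan(self.true_dosage.codes).any():
            raise ValueError("true dosages must be complete (no missing cells)")
        if len(self.true_effects) != self.true_dosage.n_loci:
            raise ValueError("one effect per locus required")
        if not 0 < self.h2_target <= 1:
            raise ValueError("h2_target must lie in (0, 1]")


def simulate_cohort(
    n_samples: int,
    n_loci: int,
    layout: GenomeLayout | None = None,
    ld_block_bp: int = 1_000_000,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    n_founders: int = 4,
    h2_target: float = 0.8,
) -> SimTruth:
    """Simulate true tetraploid dosages for a cultivar cohort.

    Markers are placed uniformly within gene intervals (duplicated positions
    resampled), per-locus target alternate-allele frequencies are drawn
    uniformly from ``maf_range`` and realised by assigning the alternate
    allele to the nearest achievable number of founder haplotypes (at least
    one, at most n_founders-1, so every locus is polymorphic in the pool).
    Dense standard-normal additive effects are attached for phenotype
    simulation.
    """
    if n_samples < 2 or n_loci < 2:
        raise ValueError("n_samples and n_loci must both be >= 2")
    low, high = maf_range
    if not 0 < low <= high <= 0.5:
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n_founders < 2:
        raise ValueError("need at least 2 founder haplotypes")
    if ld_block_bp <= 0:
        raise ValueError("ld_block_bp must be positive")
    rng = np.random.default_rng(seed)
    if layout is None:
        layout = default_layout(genes_scale=0.02, seed=seed)
    if not layout.gene_intervals:
        raise ValueError("layout has no gene intervals to place markers in")

    loci = _place_loci(rng, layout, n_loci)
    block_ids = _block_ids(loci, ld_block_bp)

    alt_count = np.zeros((n_samples, n_loci), dtype=np.int64)
    for block in np.unique(block_ids):
        idx = np.flatnonzero(block_ids == block)
        founders = np.zeros((n_founders, idx.size), dtype=np.int8)
        target = rng.uniform(low, high, idx.size)
        n_alt = np.floor(target * n_founders).astype(int)
        n_alt += (rng.random(idx.size) < target * n_founders - n_alt).astype(int)
        n_alt = np.clip(n_alt, 1, n_founders - 1)
        for j in range(idx.size):
            carriers = rng.permutation(n_founders)[: n_alt[j]]
            founders[carriers, j] = 1
        draws = rng.integers(0, n_founders, size=(n_samples, 4))
        alt_count[:, idx] = founders[draws].sum(axis=1)

    codes = 1.0 - alt_count / 4.0
    dosage = DosageMatrix(
        samples=[f"cv{i + 1:04d}" for i in range(n_samples)], loci=loci, codes=codes
    )
    effects = rng.normal(0.0, 1.0, n_loci)
    return SimTruth(
        true_dosage=dosage, true_effects=effects, h2_target=h2_target, seed=seed
    )


def _place_loci(
    rng: np.random.Generator, layout: GenomeLayout, n_loci: int
) -> pd.DataFrame:
    intervals = layout.gene_intervals
    sizes = np.array([e - s + 1 for _, s, e in intervals], dtype=float)
    prob = sizes / sizes.sum()
    seen: set[tuple[str, int]] = set()
    rows: list[tuple[str, int]] = []
    # rejection-sample distinct positions; gene space must be large enough
    for _ in range(200):
        need = n_loci - len(rows)
        if need == 0:
            break
        picks = rng.choice(len(intervals), size=need, p=prob)
        offsets = rng.random(need)
        for k, off in zip(picks, offsets):
            chrom, start, end = intervals[k]
            pos = start + int(off * (end - start + 1))
            if (chrom, pos) not in seen:
                seen.add((chrom, pos))
                rows.append((chrom, pos))
    if len(rows) < n_loci:
        raise ValueError("gene space too small to place the requested loci")
    rows.sort()
    ref_idx = rng.integers(0, 4, len(rows))
    alt_idx = (ref_idx + rng.integers(1, 4, len(rows))) % 4
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in rows],
            "pos": [p for _, p in rows],
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


def _block_ids(loci: pd.DataFrame, ld_block_bp: int) -> np.ndarray:
    keys = loci["chrom"].astype(str) + ":" + (loci["pos"] // ld_block_bp).astype(str)
    return keys.to_numpy()


def simulate_reads(
    truth: SimTruth, mean_depth: float, error_rate: float = 0.0, seed: int = 0
) -> ReadCountMatrix:
    """Simulate ref/alt read counts from true dosages.

    Total depth per cell is Poisson(mean_depth); alternate reads are
    Binomial(depth, f) with f = (1-code)*(1-e) + code*e, i.e. the true
    alternate-allele fraction perturbed by a symmetric error rate e.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    codes = truth.true_dosage.codes
    depth = rng.poisson(mean_depth, size=codes.shape)
    alt_frac = (1.0 - codes) * (1.0 - error_rate) + codes * error_rate
    alt = rng.binomial(depth, alt_frac)
    return ReadCountMatrix(
        samples=list(truth.true_dosage.samples),
        loci=truth.true_dosage.loci.copy(),
        ref_depth=depth - alt,
        alt_depth=alt,
    )


def simulate_phenotypes(
    truth: SimTruth,
    architecture: str = "dense",
    n_qtl: int | None = None,
    seed: int = 0,
    trait_name: str = "trait",
    mu: float = 0.0,
    h2: float | None = None,
) -> PhenotypeTable:
    """Simulate an additive polygenic trait y = mu + Z v + e at a target h2.

    ``architecture`` is "dense" (every locus contributes the truth's effect)
    or "sparse" (``n_qtl`` randomly chosen loci carry unit-magnitude,
    random-sign effects and every other effect is zero — equal-variance QTL,
    so each simulated QTL genuinely contributes trait signal).  The
    environmental variance is set from the realised genetic variance so that
    var(Zv)/var(y) targets h2.  The effects actually used are stored on the
    returned table under ``trait_effects[trait_name]``.
    """
    h2 = truth.h2_target if h2 is None else h2
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    effects = truth.true_effects.copy()
    if architecture == "sparse":
        if n_qtl is None or not 1 <= n_qtl <= len(effects):
            raise ValueError("sparse architecture needs 1 <= n_qtl <= n_loci")
        keep = rng.choice(len(effects), size=n_qtl, replace=False)
        effects = np.zeros(len(effects))
        effects[keep] = rng.choice([-1.0, 1.0], size=n_qtl)
    elif architecture != "dense":
        raise ValueError("architecture must be 'dense' or 'sparse'")

    Z = truth.true_dosage.codes
    g = Z @ effects
    var_g = float(np.var(g, ddof=1))
    if var_g == 0:
        raise ValueError("genetic variance is zero; heritability undefined")
    if h2 == 1.0:
        e = np.zeros_like(g)
    else:
        var_e = var_g * (1.0 - h2) / h2
        e = rng.normal(0.0, np.sqrt(var_e), size=g.shape)
    y = mu + g + e
    data = pd.DataFrame({trait_name: y}, index=pd.Index(truth.true_dosage.samples))
    data.index.name = "sample_id"
    return PhenotypeTable(
        data=data, h2={trait_name: h2}, trait_effects={trait_name: effects}
    )


def apply_missingness(
    dosages: DosageMatrix, rate: float, seed: int = 0
) -> DosageMatrix:
    """Mask cells missing-completely-at-random at the given expected rate.

    Rates arbitrarily close to (but below) 1 are accepted; whether the
    resulting matrix survives downstream missingness filters is the filter's
    concern, not the generator's.
    """
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must lie in [0, 1)")
    out = dosages.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        out.codes[rng.random(out.codes.shape) < rate] = np.nan
    return out


def realized_heritability(truth: SimTruth, pheno: PhenotypeTable, trait: str) -> float:
    """var(Zv)/var(y) realised in one simulated trait draw."""
    effects = pheno.trait_effects[trait]
    g = truth.true_dosage.codes @ effects
    y = pheno.values_for(trait, truth.true_dosage.samples)
    return float(np.var(g, ddof=1) / np.var(y, ddof=1))
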