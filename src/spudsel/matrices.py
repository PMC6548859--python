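"""In-memory containers for read counts, dosage genotypes and phenotypes.

Dosage convention, fixed once and used everywhere: a genotype code is the
REFERENCE allele frequency of the tetraploid genotype, so
AAAA=1.0, AAAB=0.75, AABB=0.5, ABBB=0.25, BBBB=0.0 (A = reference allele).
The expected alternate-read fraction of a cell is therefore ``1 - code``.
Missing genotypes are NaN.  Imputed matrices may hold continuous codes in
[0, 1]; called (unimputed) matrices hold only the five legal classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five legal tetraploid dosage codes (reference-allele frequency).
CLASS_CODES = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]


def _check_loci(loci: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing:
        raise ValueError(f"locus table missing columns {missing}")
    return loci.reset_index(drop=True)


@dataclass
class ReadCountMatrix:
    """Per-sample, per-locus reference/alternate read depths.

    ``ref_depth`` and ``alt_depth`` are (n_samples, n_loci) non-negative
    integer arrays; ``loci`` has columns chrom, pos (1-based), ref, alt.
    """

    samples: list[str]
    loci: pd.DataFrame
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        self.loci = _check_loci(self.loci)
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        shape = (len(self.samples), len(self.loci))
        if self.ref_depth.shape != shape or self.alt_depth.shape != shape:
            raise ValueError(
                f"depth arrays must have shape {shape}, got "
                f"{self.ref_depth.shape} / {self.alt_depth.shape}"
            )
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("read depths must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def subset_loci(self, mask: np.ndarray) -> "ReadCountMatrix":
        mask = np.asarray(mask)
        return ReadCountMatrix(
            samples=list(self.samples),
            loci=self.loci.loc[mask].reset_index(drop=True),
            ref_depth=self.ref_depth[:, mask],
            alt_depth=self.alt_depth[:, mask],
        )


@dataclass
class DosageMatrix:
    """Per-sample, per-locus dosage codes (reference-allele frequency).

    ``codes`` is a float (n_samples, n_loci) array with NaN for missing.
    Set ``continuous=True`` for imputed matrices whose codes may be any value
    in [0, 1]; otherwise codes must come from the five legal classes.
    """

    samples: list[str]
    loci: pd.DataFrame
    codes: np.ndarray
    continuous: bool = False

    def __post_init__(self) -> None:
        self.loci = _check_loci(self.loci)
        self.codes = np.asarray(self.codes, dtype=np.float64)
        shape = (len(self.samples), len(self.loci))
        if self.codes.shape != shape:
            raise ValueError(f"codes must have shape {shape}, got {self.codes.shape}")
        obs = self.codes[~np.isnan(self.codes)]
        if self.continuous:
            if obs.size and ((obs < 0) | (obs > 1)).any():
                raise ValueError("continuous dosage codes must lie in [0, 1]")
        else:
            if obs.size and not np.isin(obs, CLASS_CODES).all():
                bad = obs[~np.isin(obs, CLASS_CODES)]
                raise ValueError(
                    f"illegal dosage codes (expected one of {CLASS_CODES.tolist()}): "
                    f"{np.unique(bad)[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.codes)

    def missing_fraction(self) -> float:
        return float(np.isnan(self.codes).mean()) if self.codes.size else 0.0

    def subset_loci(self, mask: np.ndarray) -> "DosageMatrix":
        mask = np.asarray(mask)
        return DosageMatrix(
            samples=list(self.samples),
            loci=self.loci.loc[mask].reset_index(drop=True),
            codes=self.codes[:, mask],
            continuous=self.continuous,
        )

    def copy(self) -> "DosageMatrix":
        return DosageMatrix(
            samples=list(self.samples),
            loci=self.loci.copy(),
            codes=self.codes.copy(),
            continuous=self.continuous,
        )


@dataclass
class PhenotypeTable:
    """Cultivar x trait numeric phenotypes with per-trait heritability.

    ``data`` is indexed by sample id with one numeric column per trait; NaN
    marks unphenotyped cultivars.  ``h2`` holds the heritability used for
    prior scaling.  ``trait_effects`` (optional, in-memory only) records the
    per-locus additive effects a simulated trait was generated from.
    """

    data: pd.DataFrame
    h2: dict[str, float] = field(default_factory=dict)
    trait_effects: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, trait: str, samples: list[str]) -> np.ndarray:
        return self.data.loc[samples, trait].to_numpy(dtype=float)
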