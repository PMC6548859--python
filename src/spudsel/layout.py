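"""Genome layout: chromosome sizes and gene intervals used to place markers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import potato


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths plus the gene intervals markers may fall in.

    ``chromosomes`` maps name -> length in bp; ``gene_intervals`` is a list of
    (chromosome, start, end), 1-based inclusive.  Intervals must lie inside
    their chromosome; overlapping intervals are merged at construction.
    """

    chromosomes: tuple[tuple[str, int], ...]
    gene_intervals: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if not lengths:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        for chrom, start, end in self.gene_intervals:
            if chrom not in lengths:
                raise ValueError(f"gene interval on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= lengths[chrom]):
                raise ValueError(
                    f"gene interval {chrom}:{start}-{end} outside chromosome bounds"
                )
        object.__setattr__(self, "gene_intervals", _merge(self.gene_intervals))

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def total_gene_bp(self) -> int:
        return sum(e - s + 1 for _, s, e in self.gene_intervals)


def _merge(
    intervals: tuple[tuple[str, int, int], ...]
) -> tuple[tuple[str, int, int], ...]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2] + 1:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], end)))
        else:
            out.append((chrom, start, end))
    return tuple(out)


def default_layout(
    genes_scale: float = 1.0,
    gene_length: int = 2_500,
    telomeric_bias: bool = True,
    seed: int = 0,
) -> GenomeLayout:
    """The 12-chromosome potato layout with randomly placed gene intervals.

    Gene counts per chromosome follow the reference annotation scaled by
    ``genes_scale`` (use small values for tests).  When ``telomeric_bias`` is
    on, interval midpoints are drawn from a uniform/reflected-Beta mixture so
    gene density rises toward chromosome ends, echoing the distal gene-rich,
    pericentromeric gene-poor organisation of the potato genome; this is
    cosmetic and can be switched off.
    """
    if genes_scale <= 0:
        raise ValueError("genes_scale must be positive")
    rng = np.random.default_rng(seed)
    summary = potato.chromosome_summary()
    chroms = tuple((str(c), int(summary.loc[c, "length_bp"])) for c in summary.index)
    intervals: list[tuple[str, int, int]] = []
    for chrom, length in chroms:
        n_genes = max(1, int(round(summary.loc[chrom, "n_genes"] * genes_scale)))
        if telomeric_bias:
            n_beta = n_genes // 2
            u = rng.random(n_genes - n_beta)
            b = rng.beta(0.5, 0.5, n_beta)  # U-shaped: mass at both ends
            mids = np.concatenate([u, b]) * length
        else:
            mids = rng.random(n_genes) * length
        half = gene_length // 2
        for m in np.sort(mids):
            start = int(np.clip(m - half, 1, length))
            end = int(np.clip(m + half, 1, length))
            intervals.append((chrom, start, max(start, end)))
    return GenomeLayout(chromosomes=chroms, gene_intervals=tuple(intervals))
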