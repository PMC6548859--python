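"""Reference constants for the tetraploid potato (Solanum tuberosum) genome.

Chromosome lengths follow the DM 1-3 516 R44 (Group Phureja) v4.03
pseudomolecule assembly.  Gene counts per chromosome are from the PGSC v4.03
annotation (unanchored contigs excluded).  SNP counts summarise the published
GBS-t (transcriptome genotyping-by-sequencing) high-confidence marker resource
for a 181-cultivar commercial collection; they are used as display/check
constants and as a realistic default marker budget, never as computed output.
"""

from __future__ import annotations

import pandas as pd

# chromosome -> (length_bp, genes, high-confidence SNPs)
_CHROMOSOME_SUMMARY = [
    ("chr01", 88_663_952, 4_692, 13_446),
    ("chr02", 48_614_681, 3_214, 12_771),
    ("chr03", 62_290_286, 3_601, 10_468),
    ("chr04", 72_208_621, 3_441, 13_921),
    ("chr05", 52_070_158, 2_642, 13_437),
    ("chr06", 59_532_096, 3_295, 14_444),
    ("chr07", 56_760_843, 2_711, 15_455),
    ("chr08", 56_938_457, 2_698, 14_963),
    ("chr09", 61_540_751, 3_012, 15_236),
    ("chr10", 59_756_223, 2_847, 18_552),
    ("chr11", 45_475_667, 2_423, 17_689),
    ("chr12", 61_165_649, 2_906, 23_466),
]

#: Trait narrow-sense heritabilities used for prior scaling in the potato GS
#: literature.  Traits with uncertain h2 carry the alternative estimate too.
TRAIT_H2: dict[str, tuple[float, ...]] = {
    "flesh_color": (0.8,),
    "color_when_boiled": (0.69,),
    "skin_texture": (0.5, 0.75),
    "dry_matter": (0.5, 0.74),
    "eye_depth": (0.5, 0.75),
    "crisp_score": (0.59, 0.75),
    "maturity": (0.83,),
}


def chromosome_summary() -> pd.DataFrame:
    """Per-chromosome genome summary with derived marker-density arithmetic.

    Returns a DataFrame indexed by chromosome with columns ``length_bp``,
    ``n_genes``, ``n_snps`` and the derived ``snps_per_gene`` (1 decimal, the
    convention used when this resource is reported).
    """
    df = pd.DataFrame(
        _CHROMOSOME_SUMMARY, columns=["chromosome", "length_bp", "n_genes", "n_snps"]
    ).set_index("chromosome")
    df["snps_per_gene"] = (df["n_snps"] / df["n_genes"]).round(1)
    return df


def genome_totals() -> dict[str, int]:
    """Genome-wide totals of annotated genes and high-confidence SNPs."""
    df = chromosome_summary()
    return {"n_genes": int(df["n_genes"].sum()), "n_snps": int(df["n_snps"].sum())}
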