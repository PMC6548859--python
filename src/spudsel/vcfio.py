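"""VCF and phenotype-table adapters.

VCF convention: ploidy-4 unphased GT with alleles in sorted order (0/0/1/1),
missing as ./././.; AD carries ref,alt read depths when available; DS carries
the (possibly continuous) dosage code as reference-allele frequency; IM flags
imputed cells.  Coordinates are 1-based in VCF and kept 1-based in the locus
tables throughout the package.  Only biallelic SNP records are modelled;
multi-allelic records are skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .layout import GenomeLayout
from .matrices import DosageMatrix, PhenotypeTable, ReadCountMatrix


@dataclass
class VcfData:
    """What a VCF yielded: dosages (from GT), counts (from AD), contigs."""

    dosages: DosageMatrix | None
    counts: ReadCountMatrix | None
    contigs: dict[str, int]


def read_vcf(path: str | Path) -> VcfData:
    """Read a ploidy-4 VCF into dosage and/or read-count matrices.

    GT 0/0/1/1 -> code 0.5 (count of reference alleles / 4); ./././. ->
    missing.  If a DS field is present it overrides the GT-derived code
    (continuous, e.g. imputed).  Records must be biallelic; mixed ploidy is
    an error; a file with neither GT nor AD is an error.
    """
    rows, gt_codes, ad_ref, ad_alt, ds_vals = [], [], [], [], []
    have_ds = False
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        contigs = {c: vf.header.contigs[c].length or 0 for c in vf.header.contigs}
        has_gt = "GT" in vf.header.formats
        has_ad = "AD" in vf.header.formats
        has_ds = "DS" in vf.header.formats
        if not has_gt and not has_ad:
            raise ValueError(f"{path}: neither GT nor AD present")
        n_skipped = 0
        for rec in vf:
            if len(rec.alleles) != 2:
                n_skipped += 1
                continue
            rows.append((rec.contig, rec.pos, rec.ref, rec.alts[0]))
            if has_gt:
                row = []
                for s in samples:
                    alleles = rec.samples[s].get("GT")
                    if alleles is None or all(a is None for a in alleles):
                        row.append(np.nan)
                    else:
                        if len(alleles) != 4 or any(a is None for a in alleles):
                            raise ValueError(
                                f"{rec.contig}:{rec.pos} sample {s}: "
                                f"expected ploidy-4 GT, got {alleles}"
                            )
                        row.append(alleles.count(0) / 4.0)
                gt_codes.append(row)
            if has_ad:
                rrow, arow = [], []
                for s in samples:
                    ad = rec.samples[s].get("AD")
                    if ad is None or ad[0] is None:
                        rrow.append(0)
                        arow.append(0)
                    else:
                        rrow.append(int(ad[0]))
                        arow.append(int(ad[1]))
                ad_ref.append(rrow)
                ad_alt.append(arow)
            if has_ds:
                drow = []
                for s in samples:
                    d = rec.samples[s].get("DS")
                    drow.append(np.nan if d is None else float(d))
                ds_vals.append(drow)
                have_ds = True
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-biallelic record(s)", stacklevel=2)
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = None
    if gt_codes:
        codes = np.array(gt_codes, dtype=float).T
        continuous = False
        if have_ds:
            ds = np.array(ds_vals, dtype=float).T
            codes = np.where(np.isnan(ds), codes, ds)
            continuous = True
        dosages = DosageMatrix(
            samples=samples, loci=loci.copy(), codes=codes, continuous=continuous
        )
    counts = None
    if ad_ref:
        counts = ReadCountMatrix(
            samples=samples,
            loci=loci.copy(),
            ref_depth=np.array(ad_ref, dtype=np.int64).T,
            alt_depth=np.array(ad_alt, dtype=np.int64).T,
        )
    return VcfData(dosages=dosages, counts=counts, contigs=contigs)


def write_vcf(
    path: str | Path,
    dosages: DosageMatrix,
    counts: ReadCountMatrix | None = None,
    layout: GenomeLayout | None = None,
    imputed_mask: np.ndarray | None = None,
    filter_reasons: pd.Series | None = None,
) -> None:
    """Write a ploidy-4 VCF with GT (+AD, +DS/IM for imputed cells).

    GT is the sorted-allele representation of the dosage class nearest to the
    code; continuous codes additionally carry DS.  ``filter_reasons`` (an
    optional per-locus string series, "" = pass) populates FILTER for
    annotated unfiltered output.
    """
    header = pysam.VariantHeader()
    if layout is not None:
        lengths = layout.chromosome_lengths
    else:
        lengths = (
            dosages.loci.groupby("chrom", sort=True)["pos"].max().astype(int).to_dict()
        )
    for chrom in sorted(lengths):
        header.contigs.add(str(chrom), length=int(lengths[chrom]))
    header.formats.add("GT", 1, "String", "Genotype (ploidy 4, sorted alleles)")
    header.formats.add("AD", "R", "Integer", "Ref,alt read depths")
    header.formats.add("DS", 1, "Float", "Dosage code (reference allele frequency)")
    header.formats.add("IM", 1, "Integer", "1 if the cell was imputed")
    if filter_reasons is not None:
        for reason in sorted(set(filter_reasons) - {""}):
            header.filters.add(reason, None, None, f"Failed {reason} filter")
    for s in dosages.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, row in dosages.loci.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            if filter_reasons is not None:
                rec.filter.add(filter_reasons.iloc[j] or "PASS")
            for i, s in enumerate(dosages.samples):
                code = dosages.codes[i, j]
                fmt = rec.samples[s]
                if np.isnan(code):
                    fmt["GT"] = (None, None, None, None)
                else:
                    n_ref = int(round(code * 4))
                    fmt["GT"] = (0,) * n_ref + (1,) * (4 - n_ref)
                    if dosages.continuous:
                        fmt["DS"] = float(code)
                if counts is not None:
                    fmt["AD"] = (
                        int(counts.ref_depth[i, j]),
                        int(counts.alt_depth[i, j]),
                    )
                if imputed_mask is not None and imputed_mask[i, j]:
                    fmt["IM"] = 1
            vf.write(rec)


def read_phenotypes(
    path: str | Path,
    h2: dict[str, float] | None = None,
    min_phenotyped: float = 0.5,
) -> PhenotypeTable:
    """Read a cultivar x trait CSV (sample_id column + numeric trait columns).

    Blank cells are missing.  Traits phenotyped in at most ``min_phenotyped``
    of samples are dropped with a warning (only traits where more than half
    the cultivars have records are usable for prediction).  Duplicate sample
    ids and non-numeric cells are errors.
    """
    raw = pd.read_csv(path, dtype=str)
    if "sample_id" not in raw.columns:
        raise ValueError(f"{path}: no sample_id column")
    if raw["sample_id"].duplicated().any():
        dupes = raw.loc[raw["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    data = raw.set_index("sample_id")
    numeric = pd.DataFrame(index=data.index)
    for col in data.columns:
        vals = pd.to_numeric(data[col], errors="coerce")
        bad = vals.isna() & data[col].notna() & (data[col].str.strip() != "")
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric value {data.at[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        numeric[col] = vals
    keep = []
    for col in numeric.columns:
        frac = float(numeric[col].notna().mean())
        if frac > min_phenotyped:
            keep.append(col)
        else:
            warnings.warn(
                f"trait {col!r} phenotyped in {frac:.0%} of samples; dropped",
                stacklevel=2,
            )
    numeric = numeric[keep]
    return PhenotypeTable(data=numeric, h2=dict(h2 or {}))


def write_phenotypes(path: str | Path, table: PhenotypeTable) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
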