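"""End-to-end pipeline: simulate -> call -> filter -> impute -> GS -> diversity."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diversity, dosage, evaluate, gs, impute, simulate, vcfio
from .gs import GSConfig
from .impute import ImputationConfig
from .layout import default_layout

log = logging.getLogger("spudsel")


@dataclass
class PipelineConfig:
    """All stage parameters plus paths; validated before anything runs."""

    # synthetic cohort (used when no input VCF is given)
    simulate: bool = True
    n_samples: int = 120
    n_loci: int = 300
    mean_depth: float = 60.0
    error_rate: float = 0.005
    missing_rate: float = 0.1
    ld_block_bp: int = 1_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_founders: int = 4
    h2: float = 0.8
    genes_scale: float = 0.02
    # dosage calling / filtering
    min_depth: int = 5
    min_het_alt: int = 2
    min_alt_reads_any: int = 5
    min_alt_fraction_any: float = 0.4
    max_missing: float = 0.5
    min_maf: float = 0.05
    bin_bp: int = 100_000
    # imputation
    k_neighbors: int = 11
    n_loci_ld: int = 17
    # genomic selection
    model: str = "BayesA"
    prob_in: float = 0.01
    n_iter: int = 12_000
    burn_in: int = 1_000
    cv_folds: int = 5
    # general
    seed: int = 0
    vcf_in: str | None = None
    pheno_in: str | None = None

    def validate(self) -> None:
        GSConfig(  # raises on bad GS settings
            model=self.model,
            prob_in=self.prob_in,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            h2_prior=self.h2,
            seed=self.seed,
        )
        ImputationConfig(k_neighbors=self.k_neighbors, n_loci_ld=self.n_loci_ld)
        if self.simulate and (self.n_samples < 2 or self.n_loci < 2):
            raise ValueError("simulated cohort needs n_samples, n_loci >= 2")
        if not self.simulate and not self.vcf_in:
            raise ValueError("either simulate=True or vcf_in is required")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        if "maf_range" in payload:
            payload["maf_range"] = tuple(payload["maf_range"])
        return cls(**payload)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write all declared outputs under ``out_dir``.

    Outputs: config echo, run log, truth sidecar + raw VCF + phenotype CSV
    (simulated runs), filter report, imputed VCF, CV result JSON, per-sample
    GEBV CSV, marker-effect TSV, SNP density TSV, distance TSV and Newick
    tree.  Reruns with the same config and seeds are byte-identical.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except Exception as err:
        log.error("pipeline halted: %s", err)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    log.info("spudsel %s | python %s", __version__, sys.version.split()[0])
    log.info("parameters: %s", json.dumps(dataclasses.asdict(config), sort_keys=True))
    config.to_json(out / "config.json")
    rng = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(6)]

    if config.simulate:
        log.info("stage simulate: n=%d m=%d seed=%d", config.n_samples, config.n_loci, seeds[0])
        layout = default_layout(genes_scale=config.genes_scale, seed=seeds[0])
        truth = simulate.simulate_cohort(
            config.n_samples,
            config.n_loci,
            layout=layout,
            ld_block_bp=config.ld_block_bp,
            maf_range=config.maf_range,
            seed=seeds[0],
            n_founders=config.n_founders,
            h2_target=config.h2,
        )
        counts = simulate.simulate_reads(
            truth, config.mean_depth, config.error_rate, seed=seeds[1]
        )
        pheno = simulate.simulate_phenotypes(truth, seed=seeds[2])
        called = dosage.call_dosages(counts, config.min_depth, config.min_het_alt)
        vcfio.write_vcf(out / "raw.vcf", called, counts=counts, layout=layout)
        vcfio.write_phenotypes(out / "phenotypes.csv", pheno)
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "h2": truth.h2_target,
                    "effects": truth.true_effects.tolist(),
                },
                indent=2,
            )
        )
    else:
        log.info("stage load: %s", config.vcf_in)
        data = vcfio.read_vcf(config.vcf_in)
        layout = None
        if data.counts is not None:
            counts = data.counts
            called = dosage.call_dosages(counts, config.min_depth, config.min_het_alt)
        elif data.dosages is not None:
            counts = None
            called = data.dosages
        else:
            raise ValueError("input VCF yielded neither counts nor dosages")
        if not config.pheno_in:
            raise ValueError("pheno_in is required for real-data runs")
        pheno = vcfio.read_phenotypes(config.pheno_in)

    log.info("stage filter: %d loci in", called.n_loci)
    filtered, report = dosage.filter_variants(
        called,
        counts=counts,
        min_alt_reads_any=config.min_alt_reads_any,
        min_alt_fraction_any=config.min_alt_fraction_any,
        max_missing=config.max_missing,
        min_maf=config.min_maf,
    )
    report.table.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    (out / "filter_counts.json").write_text(json.dumps(report.counts, indent=2) + "\n")
    log.info("stage filter: %d loci retained", filtered.n_loci)
    if filtered.n_loci == 0:
        raise RuntimeError("filter stage removed every locus")

    if layout is not None:
        dens = dosage.density_bins(filtered.loci, layout, config.bin_bp)
        dens.to_csv(out / "snp_density.tsv", sep="\t", index=False)

    log.info("stage impute: k=%d loci=%d", config.k_neighbors, config.n_loci_ld)
    imp_cfg = ImputationConfig(config.k_neighbors, config.n_loci_ld)
    imputed = impute.impute(filtered, imp_cfg)
    vcfio.write_vcf(
        out / "imputed.vcf",
        imputed,
        layout=layout,
        imputed_mask=filtered.missing_mask,
    )

    gs_cfg = GSConfig(
        model=config.model,
        prob_in=config.prob_in,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        h2_prior=config.h2,
        seed=seeds[3],
    )
    Z = imputed.codes
    trait = pheno.traits[0]
    y = pheno.values_for(trait, imputed.samples)
    ok = ~np.isnan(y)
    log.info("stage gs-cv: model=%s trait=%s n=%d", config.model, trait, int(ok.sum()))
    cv = evaluate.kfold_cv(Z[ok], y[ok], gs_cfg, k=config.cv_folds, seed=seeds[4])
    (out / "cv_result.json").write_text(
        json.dumps({"trait": trait, "model": config.model, **cv.to_dict()}, indent=2)
        + "\n"
    )
    pd.DataFrame(
        {
            "sample_id": np.array(imputed.samples)[ok],
            "fold": cv.fold_assignments,
            "gebv": cv.pooled_gebvs,
        }
    ).to_csv(out / "gebvs.csv", index=False)

    log.info("stage effects: full-data fit")
    fit_full = gs.fit(Z[ok], y[ok], gs.with_seed(gs_cfg, seeds[5]), loci=imputed.loci)
    gs.manhattan_table(fit_full).to_csv(out / "marker_effects.tsv", sep="\t", index=False)

    log.info("stage diversity")
    dm = diversity.nei_distance(imputed)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out / "nei_distances.tsv", sep="\t"
    )
    tree = diversity.neighbor_joining(dm)
    (out / "nj_tree.nwk").write_text(str(tree))
    log.info("pipeline complete: %s", out)
    return out
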