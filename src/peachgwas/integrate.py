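"""Cross-result integration and end-to-end orchestration.

Joins GWAS candidate regions with selective-sweep regions (half-open
interval intersection), evaluates pipeline output against a simulation
truth set, and runs the whole analysis chain — simulate/load -> QC ->
structure -> association -> sweep scan -> LD -> overlap — writing all
artifacts plus a JSON run manifest that records parameters, seeds and
per-stage counts so every reported number is replayable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, genoqc, io, ldscan, popstruct, simdata, sweepscan
from .core import GenotypeMatrix, Region
from .simdata import SimConfig, TruthSet

logger = logging.getLogger(__name__)


@dataclass
class OverlapRecord:
    trait: str
    lead_chrom: str
    lead_pos: int
    candidate: Region
    sweep: Region
    stage: str
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp <= 0:
            raise ValueError("overlap record requires a positive intersection")


def overlap_regions(
    assoc_regions: list[tuple[str, Region]], sweep_regions: list[tuple[Region, str]]
) -> list[OverlapRecord]:
    """All (candidate, sweep) pairs with positive intersection.

    ``assoc_regions`` are (trait, region) pairs; ``sweep_regions`` are
    (region, stage) pairs.  Intervals are 0-based half-open, so bookended
    regions do not overlap.
    """
    records = []
    for trait, cand in assoc_regions:
        for sweep, stage in sweep_regions:
            bp = cand.overlap_bp(sweep)
            if bp > 0:
                records.append(OverlapRecord(
                    trait=trait, lead_chrom=cand.chrom,
                    lead_pos=(cand.start + cand.end) // 2,
                    candidate=cand, sweep=sweep, stage=stage, overlap_bp=bp,
                ))
    return records


@dataclass
class RecoveryReport:
    """Truth-based evaluation of leads and sweep calls."""

    loci: list[dict]  # {trait, chrom, pos, detected, distance_bp}
    sweeps: list[dict]  # {chrom, start, end, stage, recovered_fraction}
    false_positive_regions: int

    def detected_fraction(self) -> float:
        if not self.loci:
            return float("nan")
        return sum(1 for x in self.loci if x["detected"]) / len(self.loci)


def evaluate_against_truth(
    leads: list[assoc.LeadSignal],
    sweep_calls: list[tuple[Region, str]],
    truth: TruthSet,
    hit_radius: int = 25_000,
) -> RecoveryReport:
    """Score leads and sweep calls against the planted truth.

    A planted locus counts as detected when some lead for its trait lies
    within ``hit_radius`` bp on the same chromosome; sweep recovery is the
    planted-bp fraction covered by same-stage calls; called regions with no
    truth overlap at all count as false positives.
    """
    truth_chroms = {x["chrom"] for x in truth.causal_loci}
    truth_chroms |= {s["chrom"] for s in truth.sweep_regions}
    call_chroms = {r.chrom for r, _ in sweep_calls} | {l.chrom for l in leads}
    if call_chroms and truth_chroms and not (call_chroms & truth_chroms):
        raise ValueError(
            f"chromosome names disagree between calls {sorted(call_chroms)} "
            f"and truth {sorted(truth_chroms)}"
        )
    loci = []
    for locus in truth.causal_loci:
        dists = [
            abs(l.pos - locus["pos"])
            for l in leads
            if l.chrom == locus["chrom"] and (not l.trait or l.trait == locus["trait"])
        ]
        best = min(dists) if dists else None
        loci.append({
            "trait": locus["trait"], "chrom": locus["chrom"], "pos": locus["pos"],
            "detected": best is not None and best <= hit_radius,
            "distance_bp": best,
        })
    sweeps = []
    for s in truth.sweep_regions:
        planted = Region(s["chrom"], s["start"], s["end"])
        same_stage = [r for r, stage in sweep_calls if stage == s["stage"]]
        covered = sum(r.overlap_bp(planted) for r in
                      __merge_for_coverage(same_stage, planted.chrom))
        sweeps.append({
            "chrom": s["chrom"], "start": s["start"], "end": s["end"], "stage": s["stage"],
            "recovered_fraction": covered / planted.length,
        })
    planted_regions = [Region(s["chrom"], s["start"], s["end"]) for s in truth.sweep_regions]
    fp = sum(
        1 for r, _ in sweep_calls
        if all(r.overlap_bp(p) == 0 for p in planted_regions)
    )
    return RecoveryReport(loci=loci, sweeps=sweeps, false_positive_regions=fp)


def __merge_for_coverage(regions: list[Region], chrom: str) -> list[Region]:
    from .core import merge_intervals

    sub = [r for r in regions if r.chrom == chrom]
    return merge_intervals(sub) if sub else []


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    vcf_path: str | None = None
    phenotype_path: str | None = None
    groups_path: str | None = None
    gq_threshold: int = 3
    max_missing: float = 0.20
    min_freq: float = 0.05
    n_pcs: int = 2
    cutoff: float = 1e-8
    suggestive_cutoff: float = 1e-6
    min_gap: int = 50_000
    flank: int = 25_000
    window: int = 50_000
    step: int = 5_000
    top_fraction: float = 0.05
    ld_block: int = 50_000
    ld_max_pairs: int = 300
    min_snps: int = 10
    coding_qualitative: str = "genotypic"
    coding_quantitative: str = "additive"


def run_full(config: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the full chain and write all artifacts; returns the manifest.

    Stage order: input (simulate or load) -> QC -> structure -> association
    (GLM, GLM-PCA, MLM for binary traits; MLM for continuous) -> sweep scan
    -> windowed LD -> sweep x GWAS overlap -> truth evaluation (simulated
    inputs only).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.sim.seed = seed
    manifest: dict = {"stages": [], "seed": config.sim.seed,
                      "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                                     if k != "sim"}}
    manifest["parameters"]["sim"] = dataclasses.asdict(config.sim)

    # --- input ---------------------------------------------------------
    truth = None
    chrom_lengths = None
    if config.simulate:
        sim = simdata.simulate(config.sim)
        G, pheno, truth = sim.genotypes, sim.phenotypes, sim.truth
        chrom_lengths = {c: config.sim.chrom_length for c in config.sim.chrom_names()}
        io.write_vcf(G, out / "genotypes.vcf", chrom_lengths)
        io.write_phenotypes(pheno, out / "phenotypes.tsv")
        io.write_groups(G.samples, G.subpop, out / "groups.tsv")
        io.write_truth(truth, out / "truth.json")
    else:
        for name in ("vcf_path", "phenotype_path", "groups_path"):
            if getattr(config, name) is None:
                raise ValueError(f"simulate=false requires config field {name!r}")
        groups = io.read_groups(config.groups_path)
        G = io.read_vcf(config.vcf_path, subpop=groups)
        pheno = io.read_phenotypes(config.phenotype_path)
        pheno = pheno.reindex([str(s) for s in G.samples])
    manifest["stages"].append({"stage": "input", "n_samples": int(G.n_samples),
                               "n_variants": int(G.n_variants)})

    # --- QC ------------------------------------------------------------
    rng = np.random.default_rng([config.sim.seed, 101])
    Gq, report = genoqc.run_qc_chain(
        G, gq_threshold=config.gq_threshold, max_missing=config.max_missing,
        min_freq=config.min_freq, rng=rng,
    )
    (out / "qc_report.json").write_text(report.to_json())
    manifest["stages"].append({"stage": "qc", "n_variants": int(Gq.n_variants)})

    # --- structure -----------------------------------------------------
    pca = popstruct.pca_individuals(Gq, k=config.n_pcs)
    K = popstruct.compute_kinship(Gq)
    D = popstruct.allele_sharing_distance(Gq)
    newick = popstruct.neighbor_joining(D, Gq.samples)
    io.write_matrix_tsv(K, Gq.samples, out / "kinship.tsv")
    pd.DataFrame(pca.scores, index=Gq.samples,
                 columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
                 ).to_csv(out / "pca_scores.tsv", sep="\t")
    (out / "tree.nwk").write_text(newick + "\n")
    manifest["stages"].append({"stage": "structure", "n_pcs": config.n_pcs,
                               "top_eigenvalues": [float(v) for v in pca.eigenvalues[:5]]})

    # --- association ---------------------------------------------------
    all_leads: list[assoc.LeadSignal] = []
    assoc_tables = []
    vc_by_trait = {}
    for trait in pheno.columns:
        y = pheno[trait].to_numpy(dtype=float)
        binary = set(np.unique(y[~np.isnan(y)])) <= {0.0, 1.0}
        coding = config.coding_qualitative if binary else config.coding_quantitative
        ok = ~np.isnan(y)
        X = np.column_stack([np.ones(int(ok.sum())), pca.scores[ok]])
        vc = assoc.reml_null(y[ok], X, K[np.ix_(ok, ok)])
        vc_by_trait[trait] = {"sigma_g2": vc.sigma_g2, "sigma_e2": vc.sigma_e2,
                              "loglik": vc.loglik, "boundary": vc.boundary}
        res_mlm = assoc.mlm_scan(Gq, y, pca.scores, K, vc, coding=coding)
        res_mlm["trait"] = trait
        assoc_tables.append(res_mlm)
        if binary:
            res_glm = assoc.glm_scan(Gq, y, coding=coding)
            res_glm["trait"] = trait
            res_pca = assoc.glm_scan(Gq, y, covariates=pca.scores, coding=coding,
                                     model_tag="glm_pca")
            res_pca["trait"] = trait
            assoc_tables.extend([res_glm, res_pca])
            lead_source = res_pca
        else:
            lead_source = res_mlm
        cutoff = config.cutoff if binary else config.suggestive_cutoff
        leads = assoc.find_lead_snps(lead_source, cutoff=cutoff,
                                     min_gap=config.min_gap, flank=config.flank,
                                     trait=trait)
        for lead in leads:
            j = int(np.flatnonzero((Gq.chrom == lead.chrom) & (Gq.pos == lead.pos))[0])
            lead.explained_variation = assoc.marker_r2(
                y, Gq.genotypes[:, j], covariates=pca.scores, coding=coding)
        all_leads.extend(leads)
    assoc_df = pd.concat(assoc_tables, ignore_index=True)
    assoc_df.to_csv(out / "association.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"trait": l.trait, "chrom": l.chrom, "pos": l.pos, "p": l.p,
         "mlog10p": l.mlog10p, "explained_variation_pct": l.explained_variation,
         "region_start": l.region.start, "region_end": l.region.end}
        for l in all_leads
    ]).to_csv(out / "leads.tsv", sep="\t", index=False)
    io.write_bed([l.region for l in all_leads], out / "candidate_regions.bed")
    manifest["stages"].append({"stage": "association", "n_leads": len(all_leads),
                               "variance_components": vc_by_trait})

    # --- sweep scan ----------------------------------------------------
    sweep_calls: list[tuple[Region, str]] = []
    sweep_summaries = {}
    for stage in ("domestication", "improvement"):
        regions, ratios, summary = sweepscan.scan_stage(
            Gq, stage, window=config.window, step=config.step,
            top_fraction=config.top_fraction, min_snps=config.min_snps,
            chrom_lengths=chrom_lengths,
        )
        ratios.to_csv(out / f"pi_ratio_{stage}.tsv", sep="\t", index=False)
        io.write_bed(regions, out / f"sweeps_{stage}.bed")
        sweep_calls.extend((r, stage) for r in regions)
        sweep_summaries[stage] = summary
    manifest["stages"].append({"stage": "sweep_scan", **sweep_summaries})

    # --- LD ------------------------------------------------------------
    ld_rng = np.random.default_rng([config.sim.seed, 202])
    ld = ldscan.windowed_ld(Gq, block=config.ld_block, max_pairs=config.ld_max_pairs,
                            rng=ld_rng)
    ld_flagged = ldscan.dprime_r2_blocks(ld)
    ld_flagged.to_csv(out / "ld_windows.tsv", sep="\t", index=False)
    manifest["stages"].append({"stage": "ld", "n_blocks": int(len(ld)),
                               "n_flagged": int(ld_flagged["flagged"].sum())})

    # --- overlap -------------------------------------------------------
    cand = [(l.trait, l.region) for l in all_leads]
    overlaps = overlap_regions(cand, sweep_calls)
    pd.DataFrame([
        {"trait": o.trait, "chrom": o.candidate.chrom,
         "candidate_start": o.candidate.start, "candidate_end": o.candidate.end,
         "sweep_start": o.sweep.start, "sweep_end": o.sweep.end,
         "stage": o.stage, "overlap_bp": o.overlap_bp}
        for o in overlaps
    ]).to_csv(out / "overlaps.tsv", sep="\t", index=False)
    manifest["stages"].append({"stage": "overlap", "n_overlaps": len(overlaps)})

    # --- truth evaluation ---------------------------------------------
    if truth is not None:
        recovery = evaluate_against_truth(all_leads, sweep_calls, truth)
        manifest["stages"].append({
            "stage": "evaluation",
            "loci": recovery.loci,
            "sweeps": recovery.sweeps,
            "false_positive_regions": recovery.false_positive_regions,
            "detected_fraction": recovery.detected_fraction(),
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
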