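"""End-to-end demonstration pipeline.

Runs the whole chain on synthetic data at toy scale: forge a reference,
build the r/R1/R2 alleles (deriving R2 by unequal crossing over and
checking it against the direct specification), simulate mate-pair pools,
call and refine structural variants, score junction microhomology,
genotype a cohort by in-silico junction PCR, annotate breakpoints against
toy gene models, run the heterozygosity scan and two-point linkage, and
iterate the breeding equilibrium.  Everything is deterministic for a fixed
seed; each stage writes plain-text artifacts so it can be re-run alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allele_model, annotation, genotyping, popgen, sv_caller, synthetic_data
from .architecture import RoseCombArchitecture

logger = logging.getLogger("invseek")

__all__ = ["RunConfig", "run_demo", "junction_support"]


@dataclass(frozen=True)
class RunConfig:
    """One config for the whole demo run (YAML-serialisable)."""

    seed: int = 1
    scale_factor: float = 0.01
    ref_length: int = 300_000
    gc: float = 0.41
    pool: dict = field(default_factory=lambda: {"R1": 4, "R2": 9, "r": 3})
    insert_mean: float = 3900.0
    insert_sd: float = 300.0
    read_len: int = 50
    pool_coverage: float = 1.0
    homozygous_coverage: float = 10.0
    window: int = 1500
    min_frac: float = 0.25
    cluster_radius: int = 1000
    min_pairs: int = 4
    sd_mult: float = 10.0
    n_snp_loci: int = 1500
    n_case_birds: int = 40
    n_control_birds: int = 60
    het_window: int = 5000
    outdir: str = "demo_out"

    def __post_init__(self) -> None:
        if self.pool_coverage <= 0 or self.homozygous_coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 < self.scale_factor <= 1:
            raise ValueError("scale_factor must be in (0, 1]")
        if not self.pool or sum(self.pool.values()) <= 0:
            raise ValueError("pool must have positive total weight")
        # fail fast on nested component configs
        synthetic_data.InsertSizeModel(self.insert_mean, self.insert_sd, self.read_len)
        if self.min_frac <= 0 or self.min_frac > 1:
            raise ValueError("min_frac must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def junction_support(
    records: pd.DataFrame,
    model: synthetic_data.InsertSizeModel,
    arch: RoseCombArchitecture,
    sd_mult: float = 10.0,
) -> dict[str, int]:
    """Discordant-pair support per junction context, counted geometrically.

    Pairs are binned by which breakpoint rectangle their (left, right)
    placements fall into: the shared proximal junction links reads just
    left of the proximal breakpoint to the distal region, the R1-specific
    distal junction links reads just right of the proximal breakpoint to
    reads beyond the distal breakpoint, and the R2-specific junction links
    the proximal region to the duplicated-segment origin.
    """
    labels = sv_caller.classify_pairs(records, model, sd_mult=sd_mult)
    disc = records[
        labels.isin([sv_caller.ORIENTATION_ANOMALY, sv_caller.DISTANCE_ANOMALY])
        & records["mapped1"]
        & records["mapped2"]
    ]
    left = np.minimum(disc["pos1"], disc["pos2"]).to_numpy()
    right = np.maximum(disc["pos1"], disc["pos2"]).to_numpy()
    reach = model.mean + 10 * model.sd
    b1, b2, c = arch.proximal, arch.distal, arch.dup_start

    def count(l_lo, l_hi, r_lo, r_hi) -> int:
        return int(
            ((left >= l_lo) & (left < l_hi) & (right >= r_lo) & (right < r_hi)).sum()
        )

    return {
        "proximal": count(b1 - reach, b1, b2 - reach, b2),
        "r1_distal": count(b1, b1 + reach, b2, b2 + reach),
        "r2_duplication": count(arch.flank_start - reach, b1, c, c + reach),
    }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                logger.exception("stage %s: failed", name)
                raise RuntimeError(f"pipeline stage {name!r} failed") from None
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_demo(config: RunConfig) -> dict:
    """Run the full pipeline; returns a JSON-serialisable report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arch = RoseCombArchitecture.toy(
        factor=config.scale_factor, ref_length=config.ref_length
    )
    report: dict = {"config": dataclasses.asdict(config)}
    seed = config.seed

    # ---- reference and alleles
    @_stage("alleles")
    def stage_alleles():
        ref = synthetic_data.forge_reference(
            config.ref_length, gc=config.gc, seed=seed, name="chr7T"
        )
        ref.to_fasta(outdir / "reference.fa")
        alleles = arch.alleles()
        r2x = arch.r2_by_crossover()
        match = r2x.segments == alleles["R2"].segments
        for name, allele in alleles.items():
            allele.to_bed(outdir / f"allele_{name}.bed", ref.name)
            allele.to_yaml(outdir / f"allele_{name}.yaml")
        info = {
            name: {
                "length": len(a),
                "n_junctions": len(allele_model.extract_junctions(a)),
            }
            for name, a in alleles.items()
        }
        info["crossover_reproduces_R2"] = bool(match)
        return ref, alleles, info

    ref, alleles, report["alleles"] = stage_alleles()

    # ---- microhomology at the novel junctions
    @_stage("microhomology")
    def stage_microhomology():
        out = {}
        for name in ("R1", "R2"):
            for i, j in enumerate(allele_model.extract_junctions(alleles[name], ref)):
                rep = allele_model.junction_microhomology(
                    ref, alleles[name], j, max_mismatch=1
                )
                out[f"{name}_junction{i}"] = {
                    "allele_position": j.allele_position,
                    "overlap_len": rep.overlap_len,
                    "mismatches": rep.mismatches,
                }
        return out

    report["microhomology"] = stage_microhomology()

    # ---- mate pairs + SV calling
    model = synthetic_data.InsertSizeModel(
        config.insert_mean, config.insert_sd, config.read_len
    )

    @_stage("sv_calling")
    def stage_sv():
        hom = synthetic_data.simulate_matepairs(
            {"R1": 2}, alleles, config.ref_length, model, config.homozygous_coverage,
            seed=seed + 1,
        )
        est = sv_caller.estimate_insert_model(hom, read_len=config.read_len)
        calls, stats = sv_caller.call_sv_windows(
            hom, est, window=config.window, min_frac=config.min_frac,
            cluster_radius=config.cluster_radius, min_pairs=config.min_pairs,
            sd_mult=config.sd_mult,
        )
        refined = [
            sv_caller.refine_breakpoints(c, hom, est) if c.support >= 3 else c
            for c in calls
        ]
        sv_caller.calls_to_bedpe(refined, ref.name).to_csv(
            outdir / "r1_pool_calls.bedpe.tsv", sep="\t", index=False
        )
        stats.to_csv(outdir / "r1_pool_windows.bed.tsv", sep="\t", index=False)

        lemans = synthetic_data.simulate_matepairs(
            dict(config.pool), alleles, config.ref_length, model,
            config.pool_coverage, seed=seed + 2,
        )
        synthetic_data.write_sam(lemans, ref, alleles, model, outdir / "lemans_pool.sam")
        support = junction_support(lemans, model, arch, sd_mult=config.sd_mult)
        return {
            "insert_model": {"mean": est.mean, "sd": est.sd},
            "r1_pool_calls": [
                {
                    "type": c.svtype,
                    "breakpoint_a": list(c.breakpoint_a),
                    "breakpoint_b": list(c.breakpoint_b),
                    "size": c.size,
                    "support": c.support,
                    "refined": c.refined,
                }
                for c in refined
            ],
            "true_inversion_span": arch.inversion_span,
            "lemans_junction_support": support,
        }

    report["sv"] = stage_sv()

    # ---- junction-PCR genotyping of a cohort
    @_stage("genotyping")
    def stage_genotyping():
        assay = genotyping.build_assay(arch, alleles)
        assay.to_yaml(outdir / "assay.yaml")
        rng = np.random.default_rng(seed + 3)
        allele_names = ["r", "R1", "R2"]
        birds = pd.DataFrame(
            {
                "sample": [f"bird{i}" for i in range(120)],
                "allele1": rng.choice(allele_names, size=120, p=[0.5, 0.3, 0.2]),
                "allele2": rng.choice(allele_names, size=120, p=[0.5, 0.3, 0.2]),
            }
        )
        called = genotyping.genotype_cohort(birds, assay)
        called["phenotype"] = np.where(called["true_genotype"] == "rr", "Single", "Rose")
        called.to_csv(outdir / "cohort_genotypes.tsv", sep="\t", index=False)
        table, concordance, excluded = genotyping.cohort_summary(called)
        return {
            "n_birds": len(called),
            "genotype_concordance": float(
                (called["genotype"] == called["true_genotype"]).mean()
            ),
            "phenotype_concordance": concordance,
            "excluded": excluded,
            "diagnostic_sizes": dict(assay.diagnostics),
        }

    report["genotyping"] = stage_genotyping()

    # ---- breakpoint annotation
    @_stage("annotation")
    def stage_annotation():
        models = annotation.toy_gene_models(arch)
        annotation.write_gff3(models, outdir / "genes.gff3", ref.name)
        prox = annotation.annotate_breakpoint(arch.proximal, models)
        dist = annotation.annotate_breakpoint(arch.distal, models)
        effects = {
            name: [dataclasses.asdict(e) for e in annotation.predict_gene_effects(a, models)]
            for name, a in alleles.items()
        }
        pd.DataFrame(
            [e for lst in effects.values() for e in lst]
        ).to_csv(outdir / "gene_effects.tsv", sep="\t", index=False)
        return {
            "proximal": {"feature": prox.feature, "gene": prox.gene,
                         "distances": prox.distances},
            "distal": {"feature": dist.feature, "gene": dist.gene},
            "effects": effects,
            "fusions_R1": annotation.candidate_fusions(alleles["R1"], models),
        }

    report["annotation"] = stage_annotation()

    # ---- heterozygosity scan
    @_stage("hetscan")
    def stage_hetscan():
        panel = synthetic_data.simulate_snp_panel(
            {"R1R1": config.n_case_birds, "rr": config.n_control_birds},
            m_loci=config.n_snp_loci,
            ref_length=config.ref_length,
            sweep=arch.sweep,
            seed=seed + 4,
        )
        panel.to_tsv(outdir / "snp_panel.tsv")
        cases = panel.genotypes.loc[:, panel.groups == "R1R1"]
        controls = panel.genotypes.loc[:, panel.groups == "rr"]
        prof_case = popgen.het_scan(
            cases, panel.positions, window=config.het_window, span=config.ref_length
        )
        prof_ctrl = popgen.het_scan(
            controls, panel.positions, window=config.het_window, span=config.ref_length
        )
        runs = popgen.detect_sweep(prof_case, prof_ctrl)
        prof_case.windows.to_csv(outdir / "het_windows_cases.tsv", sep="\t", index=False)
        return {"sweep_intervals": [list(r) for r in runs], "expected": list(arch.sweep)}

    report["hetscan"] = stage_hetscan()

    # ---- linkage
    @_stage("linkage")
    def stage_linkage():
        markers = tuple(
            (f"M{i}", pos)
            for i, pos in enumerate(
                np.linspace(0.3, 0.95, 11) * config.ref_length
            )
        )
        markers = tuple((n, int(p)) for n, p in markers)
        design = synthetic_data.PedigreeDesign(
            markers=markers,
            trait_pos=arch.proximal,
            suppressed=(arch.sweep[0], arch.sweep[1]),
            missing_rate=0.013,
        )
        loci = design.loci
        theta = [
            min(0.4, abs(p1 - p0) / config.ref_length * 0.5)
            for (_, p0), (_, p1) in zip(loci, loci[1:])
        ]
        ped = synthetic_data.simulate_pedigree(design, theta, seed=seed + 5)
        ped.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
        table = popgen.linkage_table(ped, [m for m, _ in markers])
        table.to_csv(outdir / "linkage_table.tsv", sep="\t", index=False)
        return {
            "rose_fraction": float((ped["phenotype"] == "Rose").mean()),
            "table": table.to_dict(orient="records"),
        }

    report["linkage"] = stage_linkage()

    # ---- equilibrium
    @_stage("equilibrium")
    def stage_equilibrium():
        params = popgen.BreedingParams(seed=seed + 6)
        eq = popgen.rose_comb_equilibrium(params)
        mc = popgen.monte_carlo_flock(params, generations=200)
        eq.trajectory.to_json(outdir / "equilibrium_trajectory.json", orient="records")
        return {
            "q_star": eq.q_star,
            "rr_fraction": eq.rr_fraction,
            "converged": eq.converged,
            "mc_mean_rr_last50": float(mc["f_rr"].tail(50).mean()),
        }

    report["equilibrium"] = stage_equilibrium()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
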