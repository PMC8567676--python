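"""End-to-end orchestration: simulate-or-load, deconvolve, gate, test, filter.

A ``RunConfig`` collects every input path, threshold, seed and method
switch; ``run_all`` executes the stage sequence

    simulate/load -> deconvolve -> gate -> ewas (full + paired)
    -> stringent filter -> bump-hunting DMRs -> enrichment

writing each stage's outputs to the run directory as it completes (a
failure in a later stage preserves earlier outputs) and returning a
machine-readable report with the counts, thresholds and seeds of every
stage.  All randomness flows from one master seed, fanned out to one child
seed per stage through numpy's SeedSequence so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .bumphunt import find_dmrs
from .deconvolution import estimate_fractions, fraction_summary
from .dmp import exclude_probes, paired_stage, run_ewas
from .enrichment import GeneSet, map_probes_to_genes, test_enrichment
from .gating import apply_ic_thresholds, mds_embedding
from .methcore import genomic_inflation
from .spatial import cluster_dmps, nearest_significant_distance, stringent_filter
from .synthetic import (
    CohortDesign,
    ProbeEffect,
    RegionEffect,
    auto_effects,
    generate_reference,
    simulate_cohort,
)

__all__ = ["RunConfig", "run_all", "stage_seeds", "random_gene_sets"]

_STAGES = ("simulate", "deconvolve", "gate", "ewas", "filter", "dmr", "enrich")


def stage_seeds(master_seed: int) -> dict:
    """One independent 31-bit child seed per stage, derived from the master."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``simulate`` is true (cohort generated from the design fields)
    or the four input paths must point at existing files.  Thresholds carry
    the pipeline defaults: gating at IC <= 0.35 / >= 0.40, stage-1 q < 0.05,
    stringent filter at 2 kb / |effect| > 0.1 / paired alpha 0.05, bump
    hunting at cutoff 0.02 with B permutations.
    """

    # inputs (ignored when simulate=True)
    simulate: bool = True
    betas_path: str | None = None
    sheet_path: str | None = None
    manifest_path: str | None = None
    reference_path: str | None = None
    blacklist_paths: dict = field(default_factory=dict)
    gmt_path: str | None = None
    # simulation design
    n_subjects: int = 48
    n_probes: int = 20_000
    paired_fraction: float = 1.0
    noise_sd: float = 0.03
    batch_sd: float = 0.1
    n_smoking_probes: int = 200
    effects: list = field(default_factory=list)  # dicts, see _parse_effects
    # when effects is empty, plant this many DMPs/DMRs automatically at
    # feasible probes (0 disables planting -> a null cohort)
    n_planted_dmps: int = 50
    n_planted_dmrs: int = 2
    planted_delta_beta: float = -0.2
    # thresholds & switches
    uninflamed_max: float = 0.35
    inflamed_min: float = 0.40
    q_threshold: float = 0.05
    min_effect: float = 0.1
    paired_alpha: float = 0.05
    max_gap: int = 2000
    dmr_cutoff: float = 0.02
    dmr_cluster_gap: int = 500
    dmr_permutations: int = 1000
    deconv_method: str = "rpc"
    ic_reference: str = "zero"
    ewas_engine: str = "fixed"
    seed: int = 7

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name, lo, hi in (
            ("uninflamed_max", 0, 1), ("inflamed_min", 0, 1),
            ("q_threshold", 0, 1), ("paired_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.dmr_cutoff <= 0:
            raise ValueError("dmr_cutoff must be positive")
        if not self.simulate:
            for name in ("betas_path", "sheet_path", "manifest_path", "reference_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or does not exist: {p}")


def _parse_effects(effects: list) -> list:
    parsed = []
    for e in effects:
        e = dict(e)
        if "span_bp" in e:
            parsed.append(RegionEffect(**e))
        else:
            parsed.append(ProbeEffect(**e))
    return parsed


def random_gene_sets(
    manifest: pd.DataFrame, n_sets: int = 30, seed: int = 0
) -> list[GeneSet]:
    """Random gene sets over the manifest's gene universe (for simulated runs)."""
    genes = sorted(
        {g for field_ in manifest["gene"] for g in str(field_).split(";") if g}
    )
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(8, min(50, max(9, len(genes)))))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets.append(
            GeneSet(f"SET{i + 1:03d}", f"random set {i + 1}", "BP",
                    frozenset(members))
        )
    return sets


def _log(msg: str) -> None:
    print(f"[ctewas] {msg}", file=sys.stderr)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved on disk."""

    def __init__(self, stage: str, err: Exception, hint: str = ""):
        self.stage = stage
        suffix = f" — {hint}" if hint else ""
        super().__init__(f"stage {stage!r} failed: {err}{suffix}")


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns the run report (also on disk)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict = {
        "seeds": seeds,
        "config": {
            k: v for k, v in asdict(config).items()
            if not isinstance(v, (list, dict)) or k in ("blacklist_paths",)
        },
        "stages": {},
    }

    # -- stage 1: simulate or load -------------------------------------
    try:
        if config.simulate:
            design = CohortDesign(
                n_subjects=config.n_subjects,
                paired_fraction=config.paired_fraction,
                noise_sd=config.noise_sd,
                batch_sd=config.batch_sd,
                n_smoking_probes=config.n_smoking_probes,
                seed=seeds["simulate"],
            )
            reference = generate_reference(config.n_probes, seed=seeds["simulate"])
            if config.effects:
                spec = _parse_effects(config.effects)
            elif config.n_planted_dmps or config.n_planted_dmrs:
                spec = auto_effects(
                    reference,
                    n_dmps=config.n_planted_dmps,
                    n_dmrs=config.n_planted_dmrs,
                    dmp_delta=config.planted_delta_beta,
                    seed=seeds["simulate"],
                )
            else:
                spec = []
            cohort = simulate_cohort(design, reference=reference, effect_spec=spec)
            betas, sheet = cohort.betas, cohort.sheet
            manifest = cohort.reference.manifest
            reference = cohort.reference
            blacklists = {"smoking": list(cohort.truth.smoking_probes)}
            pio.write_beta_matrix(betas, outdir / "betas.tsv")
            pio.write_sample_sheet(sheet, outdir / "sample_sheet.csv")
            pio.write_manifest(manifest, outdir / "manifest.tsv")
            pio.write_reference(reference, outdir / "reference.tsv")
            pio.write_blacklist(blacklists["smoking"], outdir / "smoking_probes.txt")
            pio.write_table(cohort.fractions, outdir / "true_fractions.tsv")
            pio.write_table(cohort.truth.effects, outdir / "true_effects.tsv")
        else:
            betas = pio.read_beta_matrix(config.betas_path)
            sheet = pio.read_sample_sheet(config.sheet_path)
            manifest = pio.read_manifest(config.manifest_path)
            reference = pio.read_reference(config.reference_path, manifest)
            blacklists = {
                name: pio.read_blacklist(path)
                for name, path in config.blacklist_paths.items()
            }
            cohort = None
        report["stages"]["simulate"] = {
            "n_samples": betas.shape[1], "n_probes": betas.shape[0],
            "simulated": bool(config.simulate),
        }
        _log(f"cohort ready: {betas.shape[0]} probes x {betas.shape[1]} samples")
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", err, "check input paths / design values") from err

    # -- stage 2: deconvolution ----------------------------------------
    try:
        fractions = estimate_fractions(betas, reference, method=config.deconv_method)
        pio.write_table(fractions, outdir / "fractions.tsv")
        summary = fraction_summary(fractions, sheet)
        report["stages"]["deconvolve"] = {
            "method": config.deconv_method,
            "epi_ic_pearson_r": summary["epi_ic_pearson_r"],
            "wilcoxon_p": summary["wilcoxon_p"],
        }
        _log(f"deconvolution done (epi-ic r = {summary['epi_ic_pearson_r']:.3f})")
    except Exception as err:
        raise StageError("deconvolve", err, "check reference/matrix probe overlap") from err

    # -- stage 3: gating + MDS -----------------------------------------
    try:
        gating = apply_ic_thresholds(
            fractions, sheet,
            uninflamed_max=config.uninflamed_max, inflamed_min=config.inflamed_min,
        )
        pio.write_table(gating.included, outdir / "gating_included.tsv")
        pio.write_table(gating.excluded, outdir / "gating_excluded.tsv")
        mds = mds_embedding(betas)
        pio.write_table(mds, outdir / "mds_coordinates.tsv")
        report["stages"]["gate"] = gating.counts()
        _log(f"gating: {gating.counts()}")
    except Exception as err:
        raise StageError("gate", err, "check fraction/sheet sample ids") from err

    gated_ids = gating.included_ids
    gbetas = betas[gated_ids]
    gsheet = sheet.loc[gated_ids]
    gic = fractions.loc[gated_ids, "ic"]

    # -- stage 4: EWAS (full + paired) ---------------------------------
    try:
        retained, excl_counts = exclude_probes(manifest, blacklists)
        dmps = run_ewas(
            gbetas, gsheet, gic, manifest=manifest, retained=retained,
            engine=config.ewas_engine, ic_reference=config.ic_reference,
        )
        lam = genomic_inflation(dmps["p_full"].to_numpy())
        stage2 = paired_stage(
            dmps, gbetas, gsheet, gic, q_threshold=config.q_threshold,
            engine=config.ewas_engine,
        )
        dmps = dmps.join(stage2)
        pio.write_table(dmps, outdir / "dmp_table.tsv")
        n_sig = int((dmps["q_full"] < config.q_threshold).sum())
        report["stages"]["ewas"] = {
            "probe_exclusion": excl_counts,
            "lambda": lam,
            "n_significant_full": n_sig,
            "n_paired_tested": int(len(stage2)),
            "n_paired_significant": int((stage2["p_adj_paired"] < config.paired_alpha).sum()),
        }
        _log(f"ewas: {n_sig} DMPs at q<{config.q_threshold}, lambda={lam:.2f}")
    except Exception as err:
        raise StageError("ewas", err, "check status/batch design") from err

    # -- stage 5: stringent filter -------------------------------------
    try:
        sig = dmps[dmps["q_full"] < config.q_threshold]
        if len(sig):
            clusters = cluster_dmps(sig, max_gap=config.max_gap)
            retained_dmps, filt = stringent_filter(
                sig, clusters, min_effect=config.min_effect,
                paired_alpha=config.paired_alpha,
            )
            retained_dmps = retained_dmps.assign(
                nearest_sig_bp=nearest_significant_distance(sig).loc[retained_dmps.index]
            )
            pio.write_table(retained_dmps, outdir / "stringent_dmps.tsv")
            report["stages"]["filter"] = {
                "n_clusters_pre": filt.n_clusters_pre,
                "n_clusters_kept": filt.n_clusters_kept,
                "n_dmps_retained": filt.n_dmps_retained,
            }
        else:
            report["stages"]["filter"] = {"n_clusters_pre": 0, "n_clusters_kept": 0,
                                          "n_dmps_retained": 0}
        _log(f"filter: {report['stages']['filter']}")
    except Exception as err:
        raise StageError("filter", err) from err

    # -- stage 6: DMRs --------------------------------------------------
    try:
        if config.dmr_permutations > 0:
            dmrs = find_dmrs(
                gbetas.loc[retained], gsheet, gic, manifest.loc[retained],
                cutoff=config.dmr_cutoff, cluster_gap=config.dmr_cluster_gap,
                B=config.dmr_permutations, seed=seeds["dmr"],
            )
            pio.write_table(dmrs, outdir / "dmr_table.tsv")
            if len(dmrs):
                pio.write_bed(dmrs, outdir / "dmr_regions.bed")
            report["stages"]["dmr"] = {
                "n_candidates": int(len(dmrs)),
                "n_fwer_significant": int((dmrs["fwer"] < 0.05).sum()) if len(dmrs) else 0,
                "B": config.dmr_permutations,
            }
        else:
            report["stages"]["dmr"] = {"skipped": "dmr_permutations = 0"}
        _log(f"dmr: {report['stages']['dmr']}")
    except Exception as err:
        raise StageError("dmr", err) from err

    # -- stage 7: enrichment -------------------------------------------
    try:
        if config.gmt_path:
            sets = pio.read_gmt(config.gmt_path)
        else:
            sets = random_gene_sets(manifest.loc[retained], seed=seeds["enrich"])
        sig_paired = dmps.index[
            (dmps["q_full"] < config.q_threshold)
            & (dmps["p_adj_paired"] < config.paired_alpha)
        ]
        if len(sig_paired):
            gene_stats, pools = map_probes_to_genes(sig_paired, manifest.loc[retained])
            enr = test_enrichment(gene_stats, sets)
            pio.write_table(enr, outdir / "enrichment.tsv")
            report["stages"]["enrich"] = {
                "n_sets_tested": int(len(enr)),
                "n_significant_sets": int((enr["q"] < 0.05).sum()),
                "intergenic_pool": pools,
            }
        else:
            report["stages"]["enrich"] = {"skipped": "no paired-significant DMPs"}
        _log(f"enrich: {report['stages']['enrich']}")
    except Exception as err:
        raise StageError("enrich", err) from err

    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
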