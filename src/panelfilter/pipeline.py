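"""Replicate orchestration: simulate -> call -> annotate -> label ->
train -> filter -> evaluate -> flanking analysis.

One master seed is expanded into per-stage, per-replicate, per-sample
substreams (``numpy.random.SeedSequence`` spawning), so a run is a pure
function of (config, seed) and replicates are independent.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pfio
from .caller import call_batches
from .flanks import fv_flank_table
from .labeling import LabeledCall, calls_to_frame, label_calls
from .model import HardFilterModel, HardFilterResults
from .panel import Amplicon, random_panel
from .simulate import (
    TruthCatalog,
    assign_genotypes,
    build_catalog,
    make_diploid_sequences,
    simulate_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: "pfio.RunConfig"
    panel: list[Amplicon]
    catalog: TruthCatalog
    truths: list[TruthCatalog]  # one per replicate
    labeled: pd.DataFrame
    results: HardFilterResults
    retained: pd.DataFrame
    removed: pd.DataFrame
    flank_table: pd.DataFrame
    manifest: dict


def _spawned_rngs(config) -> tuple:
    root = np.random.SeedSequence(config.seed)
    panel_ss, catalog_ss, *rep_ss = root.spawn(2 + config.n_replicates)
    return panel_ss, catalog_ss, rep_ss


def simulate_cohort(config, replicate: int, rep_ss, panel, catalog):
    """Genotypes, haplotypes and read batches for one replicate.

    Yields (sample_id, truth, diploid, {arm: batches}) per sample.
    """
    gt_ss, *sample_ss = rep_ss.spawn(1 + config.n_samples)
    truth = assign_genotypes(
        catalog, config.sample_ids, np.random.default_rng(gt_ss)
    )
    arm_names = sorted(config.arms)
    per_sample = []
    for i, sample_id in enumerate(config.sample_ids):
        hap_ss, *arm_ss = sample_ss[i].spawn(1 + len(arm_names))
        diploid = make_diploid_sequences(
            panel, truth, sample_id, np.random.default_rng(hap_ss)
        )
        batches = {}
        for arm, ss in zip(arm_names, arm_ss):
            depth = config.arms[arm]
            read_length = config.read_length or config.amplicon_length
            batches[arm] = simulate_reads(
                diploid,
                depth,
                read_length,
                config.error_model,
                np.random.default_rng(ss),
            )
        per_sample.append((sample_id, diploid, batches))
    return truth, per_sample


def run_pipeline(config, outdir=None) -> PipelineResult:
    """Execute the full tuning pipeline for every coverage arm.

    With ``outdir`` set, all artifacts (truth table, labeled calls,
    rules, reports, manifest, optionally per-sample VCF/FASTQ) are
    written there; the result object is returned either way.
    """
    t0 = time.time()
    stages: list[dict] = []

    def stage(name: str, rows: int) -> None:
        stages.append(
            {"name": name, "rows": int(rows), "elapsed_s": round(time.time() - t0, 2)}
        )
        logger.info("stage %-10s rows=%d (%.1fs)", name, rows, time.time() - t0)

    panel_ss, catalog_ss, rep_ss = _spawned_rngs(config)
    panel = random_panel(
        config.n_amplicons,
        config.amplicon_length,
        np.random.default_rng(panel_ss),
    )
    catalog = build_catalog(
        panel,
        config.n_snv,
        config.n_indel,
        seed=np.random.default_rng(catalog_ss),
    )

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        pfio.write_panel_fasta(out / "panel.fasta", panel)

    labeled: list[LabeledCall] = []
    truths: list[TruthCatalog] = []
    truth_frames = []
    n_reads_total = 0
    for r in range(config.n_replicates):
        truth, per_sample = simulate_cohort(config, r, rep_ss[r], panel, catalog)
        truths.append(truth)
        tdf = pd.DataFrame(
            truth.truth_rows(),
            columns=["sample", "chrom", "pos", "ref", "alt", "genotype"],
        )
        tdf.insert(0, "replicate", r)
        truth_frames.append(tdf)
        for sample_id, diploid, batches in per_sample:
            if out is not None and config.write_fastq:
                sdir = out / "samples" / f"rep{r:03d}"
                sdir.mkdir(parents=True, exist_ok=True)
                pfio.write_haplotype_fasta(
                    sdir / f"{sample_id}_haplotypes.fasta", sample_id, diploid
                )
            for arm, arm_batches in batches.items():
                n_reads_total += sum(b.n_reads for b in arm_batches.values())
                calls = call_batches(arm_batches, config.caller)
                lab = label_calls(
                    [(sample_id, c) for c in calls],
                    truth,
                    coverage_arm=arm,
                    replicate_id=r,
                    panel=panel,
                )
                labeled.extend(lab)
                if out is not None and config.write_fastq:
                    reads = [
                        rd
                        for amp_id in sorted(arm_batches)
                        for rd in arm_batches[amp_id].to_reads()
                    ]
                    pfio.write_fastq(
                        out / "samples" / f"rep{r:03d}" / f"{sample_id}_{arm}.fastq",
                        reads,
                    )
                if out is not None and config.write_vcfs:
                    sdir = out / "samples" / f"rep{r:03d}"
                    sdir.mkdir(parents=True, exist_ok=True)
                    pfio.write_vcf(
                        sdir / f"{sample_id}_{arm}.vcf",
                        sample_id,
                        pfio.annotated_calls(calls),
                        panel=panel,
                    )
    stage("simulate", n_reads_total)
    stage("call", len(labeled))
    stage("annotate", len(labeled))

    frame = calls_to_frame(labeled)
    stage("label", len(frame))

    model = HardFilterModel(
        frame,
        tree_params=config.tree,
        selection_params=config.selection,
    )
    results = model.fit()
    n_rules = sum(len(rs.rules) for rs in results.rule_sets.values())
    stage("train", n_rules)

    retained, removed = results.apply()
    stage("filter", len(retained))

    selection = results.selection_table()
    auc = results.auc_by_stratum()
    stage("evaluate", len(selection) + auc.size)

    flank_frames = []
    for arm in sorted(config.arms):
        for vtype in ("SNV", "INDEL"):
            for zyg in ("hom", "het"):
                tab = fv_flank_table(
                    frame, panel, vtype=vtype, zygosity=zyg, arm=arm
                )
                if len(tab):
                    tab.insert(0, "arm", arm)
                    tab.insert(1, "vtype", vtype)
                    tab.insert(2, "zygosity", zyg)
                    flank_frames.append(tab)
    flank_table = (
        pd.concat(flank_frames, ignore_index=True)
        if flank_frames
        else pd.DataFrame(
            columns=[
                "arm", "vtype", "zygosity", "chrom", "pos",
                "flank", "display", "occurrences", "max_run",
            ]
        )
    )
    stage("flanks", len(flank_table))

    from . import __version__
    from .rules import rule_sets_to_json

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "conservation": {
            "labeled": len(frame),
            "retained": len(retained),
            "removed": len(removed),
        },
    }

    if out is not None:
        pd.concat(truth_frames, ignore_index=True).to_csv(
            out / "truth.tsv", sep="\t", index=False
        )
        frame.to_csv(out / "labeled_calls.tsv", sep="\t", index=False)
        retained.to_csv(out / "retained_calls.tsv", sep="\t", index=False)
        (out / "rules.json").write_text(rule_sets_to_json(results.rule_sets))
        (out / "summary.txt").write_text(results.summary() + "\n")
        selection.to_csv(out / "selection_by_stratum.tsv", sep="\t", index=False)
        auc.to_csv(out / "auc_by_stratum.tsv", sep="\t")
        for arm in sorted(config.arms):
            for vtype in ("SNV", "INDEL"):
                results.descriptive_table(arm, vtype).to_csv(
                    out / f"descriptive_{arm}_{vtype}.tsv", sep="\t", index=False
                )
        flank_table.to_csv(out / "fv_flanks.tsv", sep="\t", index=False)
        pfio.write_json(out / "manifest.json", manifest)

    return PipelineResult(
        config=config,
        panel=panel,
        catalog=catalog,
        truths=truths,
        labeled=frame,
        results=results,
        retained=retained,
        removed=removed,
        flank_table=flank_table,
        manifest=manifest,
    )
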