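"""End-to-end orchestration: scan -> network -> targets -> FDR -> modules -> enrichment.

Every run is a pure function of (inputs, config, seed): the resolved
configuration is written beside the outputs, all randomness flows from the
single config seed, and each stage logs its wall time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import modules as mod
from . import network as net
from . import synthetic as syn
from . import targets as tgt
from .promoters import (
    DEFAULT_SCAN_PVALUE,
    PWM,
    PromoterSet,
    hits_to_frame,
    load_jaspar_pwm,
    pwm_score_threshold,
    scan_promoters,
)

logger = logging.getLogger("motifnet")


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run.

    The defaults are the NF-Y-style configuration: promoters 1000 bp
    upstream of the TSS only, Z >= 3.5, enrichment p <= 1e-5.  The
    ``sp1`` preset switches to 2500 bp upstream / 200 bp downstream with
    Z >= 4 and p <= 1e-4.
    """

    upstream: int = 1000
    downstream: int = 0
    scan_pvalue: float = DEFAULT_SCAN_PVALUE
    pcor_cutoff: float = net.DEFAULT_PCOR_CUTOFF
    z_cutoff: float = 3.5
    p_cutoff: float = 1e-5
    min_occurrences: int = tgt.DEFAULT_MIN_OCCURRENCES
    inflation: float = mod.DEFAULT_INFLATION
    n_perm: int = 10
    seed: int = 0
    # file inputs
    promoters_fasta: str | None = None
    pwm_file: str | None = None
    pwm_id: str | None = None
    expression_tsv: str | None = None
    edge_list_tsv: str | None = None
    gmt_file: str | None = None
    binding_tsv: str | None = None

    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        presets = {
            "nfy": dict(upstream=1000, downstream=0, z_cutoff=3.5, p_cutoff=1e-5),
            "sp1": dict(upstream=2500, downstream=200, z_cutoff=4.0, p_cutoff=1e-4),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r} (choose from {sorted(presets)})")
        return cls(**{**presets[name], **overrides})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def validated(self) -> "PipelineConfig":
        if self.upstream < 0 or self.downstream < 0 or self.upstream + self.downstream < 1:
            raise ValueError("invalid promoter geometry")
        if not 0 < self.scan_pvalue <= 1 or not 0 < self.p_cutoff <= 1:
            raise ValueError("p-value cutoffs must be in (0, 1]")
        if self.inflation <= 1:
            raise ValueError("MCL inflation must be > 1")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        return self


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate with the stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


# -- synthetic study ---------------------------------------------------------

#: study conditions for the synthetic end-to-end fixture
SYNTH_DEFAULTS = dict(
    n_module_genes=10,
    n_modules=4,
    n_background_genes=160,
    n_samples=1500,
    within_pcor=0.09,
    mask_fraction=0.10,
    motif_word="CCAATCAG",
    per_gene_count=2,
    placement_scale=50.0,
)


def simulate_study(
    out_dir,
    seed: int = 0,
    upstream: int = 1000,
    downstream: int = 0,
    **overrides,
) -> dict:
    """Write a complete synthetic input set with planted truth to ``out_dir``.

    Generates (1) an expression matrix with planted co-expression blocks,
    (2) promoters for the same genes with the study motif planted
    TSS-biased in every module gene, (3) a binding table enriched among
    module genes, and (4) the ground-truth table.  Returns the file paths
    plus the in-memory truth.
    """
    p = {**SYNTH_DEFAULTS, **overrides}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    s_expr, s_prom, s_plant, s_bind = rng.integers(0, 2**31 - 1, size=4)

    X, truth_expr = syn.generate_expression(
        [p["n_module_genes"]] * p["n_modules"],
        p["n_background_genes"], p["n_samples"], p["within_pcor"], int(s_expr),
    )
    promoters = syn.generate_promoters(
        X.shape[0], upstream, downstream, p["mask_fraction"], int(s_prom),
        gene_ids=list(X.index),
    )
    pwm = PWM.from_consensus(p["motif_word"], name="planted")
    module_genes = sorted(truth_expr.module_labels)
    promoters, truth_plant = syn.plant_motif(
        promoters, pwm, module_genes, placement="tss_biased",
        per_gene_count=p["per_gene_count"], seed=int(s_plant),
        scale=p["placement_scale"],
    )
    groups = {g: ("module" if g in truth_expr.module_labels else "background")
              for g in X.index}
    binding, truth_bind = syn.generate_binding_table(
        list(X.index), {"module": 0.6, "background": 0.25}, int(s_bind), group_by=groups,
    )
    truth = truth_expr.merge(truth_plant).merge(truth_bind)

    paths = {
        "expression_tsv": str(out / "expression.tsv"),
        "promoters_fasta": str(out / "promoters.fa"),
        "pwm_file": str(out / "motif.jaspar"),
        "binding_tsv": str(out / "binding.tsv"),
        "truth_tsv": str(out / "truth.tsv"),
    }
    X.to_csv(paths["expression_tsv"], sep="\t")
    promoters.to_fasta(paths["promoters_fasta"])
    with open(paths["pwm_file"], "w") as fh:
        fh.write(">PLANTED planted\n")
        counts = (pwm.probabilities * 100).astype(int)
        for base, row in zip("ACGT", counts):
            fh.write(f"{base} [ " + " ".join(f"{c:3d}" for c in row) + " ]\n")
    binding.to_csv(paths["binding_tsv"], sep="\t", index=False)
    truth.to_tsv(paths["truth_tsv"])
    logger.info("simulate_study: wrote synthetic study to %s (seed=%d)", out, seed)
    return {**paths, "truth": truth, "upstream": upstream, "downstream": downstream}


# -- pipeline ----------------------------------------------------------------


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write all artifacts into ``out_dir``.

    Stages: load inputs -> scan promoters -> build network (estimate pcor
    from expression, or load a prebuilt edge list) -> call targets ->
    promoter-randomization FDR -> extract target sub-network -> MCL
    modules -> optional annotation/binding enrichment.  Returns the summary
    dict that is also written as ``summary.json``.
    """
    config = config.validated()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    @_stage("load_inputs")
    def load_inputs():
        if config.promoters_fasta is None or config.pwm_file is None:
            raise ValueError("promoters_fasta and pwm_file are required")
        promoters = PromoterSet.from_fasta(
            config.promoters_fasta, config.upstream, config.downstream
        )
        pwm = load_jaspar_pwm(config.pwm_file, motif_id=config.pwm_id)
        return promoters, pwm

    promoters, pwm = load_inputs()

    @_stage("scan")
    def scan():
        threshold = pwm_score_threshold(pwm, config.scan_pvalue)
        hits = scan_promoters(promoters, pwm, threshold)
        hits_to_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False)
        return threshold, hits

    threshold, hits = scan()

    @_stage("network")
    def build():
        if config.edge_list_tsv:
            return net.CoexpressionNetwork.from_tsv(config.edge_list_tsv, config.pcor_cutoff)
        if not config.expression_tsv:
            raise ValueError("need expression_tsv or edge_list_tsv")
        X = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        pcor = net.estimate_pcor(X)
        network = net.build_network(pcor, config.pcor_cutoff)
        network.to_tsv(out / "network_edges.tsv")
        return network

    network = build()
    # only genes with promoters can be analyzed
    network = mod.extract_subnetwork(network, [g for g in network.nodes if g in promoters])

    @_stage("targets")
    def targets():
        ts = tgt.call_targets(
            network, promoters, hits,
            z_cutoff=config.z_cutoff, p_cutoff=config.p_cutoff,
            min_occurrences=config.min_occurrences, motif_id=pwm.name,
        )
        ts.to_tsv(out / "targets.tsv")
        ts.neighborhoods_to_tsv(out / "neighborhoods.tsv")
        return ts

    target_set = targets()

    fdr = None
    if config.n_perm > 0 and target_set.targets:
        @_stage("fdr")
        def run_fdr():
            return tgt.permutation_fdr(
                network, promoters, pwm, threshold,
                z_cutoff=config.z_cutoff, p_cutoff=config.p_cutoff,
                min_occurrences=config.min_occurrences,
                n_perm=config.n_perm, seed=config.seed,
            )
        fdr = run_fdr()

    @_stage("modules")
    def cluster():
        sub = mod.extract_subnetwork(network, target_set.targets)
        partition = mod.mcl_cluster(sub, inflation=config.inflation)
        partition.to_tsv(out / "modules.tsv")
        partition.summary().to_csv(out / "module_summary.tsv", sep="\t", index=False)
        return partition

    partition = cluster()

    enrich_df = None
    n_enriched = None
    if config.gmt_file or config.binding_tsv:
        @_stage("enrich")
        def enrich():
            population = set(network.nodes)
            term_sets: dict[str, set[str]] = {}
            if config.gmt_file:
                term_sets.update(enr.read_gmt(config.gmt_file))
            if config.binding_tsv:
                tab = pd.read_csv(config.binding_tsv, sep="\t")
                term_sets["bound"] = set(tab.loc[tab["bound"] == 1, "gene"])
            df = enr.enrich_modules(partition, term_sets, population)
            df.to_csv(out / "module_enrichment.tsv", sep="\t", index=False)
            return df
        enrich_df = enrich()
        if not enrich_df.empty:
            n_enriched = int((enrich_df["p_enrich"] <= 0.05).groupby(
                enrich_df["module"]).any().sum())

    by_method = target_set.genes_by_method()
    summary = {
        "n_promoters": len(promoters),
        "n_network_genes": len(network.nodes),
        "n_network_edges": network.n_edges,
        "scan_threshold_bits": round(threshold, 4),
        "n_motif_genes": len({h.gene_id for h in hits}),
        "n_targets": len(target_set.targets),
        "n_targets_bias": len(by_method["bias"]),
        "n_targets_enrichment": len(by_method["enrichment"]),
        "n_targets_both": len(by_method["both"]),
        "fdr": None if fdr is None else fdr.fdr,
        "mean_perm_target_count": None if fdr is None else fdr.mean_perm_count,
        "n_modules": len(partition.modules),
        "n_singletons": len(partition.singletons),
        "n_enriched_modules": n_enriched,
        "seed": config.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("run_pipeline: %s", summary)
    return summary
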