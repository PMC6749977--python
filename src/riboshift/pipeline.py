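"""End-to-end pipeline: simulate -> qc -> normalize -> dte -> classify ->
enrich -> cohort, with a reproducibility manifest.

Outputs are deterministic given the configuration seed: the manifest records
package and library versions, thresholds, the seed, input checksums and
per-stage gene counts, and contains no timestamps, so two runs with the same
configuration produce byte-identical output trees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify as classify_genes, cluster_profiles
from . import cohort as _cohort
from . import enrich as _enrich
from . import io as _io
from . import qc as _qc
from . import simulate as _sim
from .dte import run_dte
from .errors import ConfigError
from .expression import compute_tpm, filter_expressed, size_factors

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and sizes for a full synthetic run.

    Thresholds default to the analysis conventions: adjusted-p 0.05, mean
    TPM >= 1 in both assays, eCLIP fold >= 8 and p < 1e-5, pair/hub alpha
    0.05, minimum cluster size 20, |rho| >= 0.45 for network display.
    """

    seed: int = 7
    out_dir: str = "riboshift_out"
    # simulation sizes
    n_genes: int = 2000
    n_patients: int = 4
    depth_per_library: float = 2e6
    effect_size_lfc: float = 2.0
    n_qc_reads: int = 20000
    in_frame_fraction: float = 0.9
    n_rbps: int = 8
    cohort_patients: int = 30
    n_targets_per_hub: int = 50
    hub_strength: float = 1.0
    # thresholds
    alpha: float = 0.05
    min_tpm: float = 1.0
    eclip_min_fold: float = 8.0
    eclip_max_p: float = 1e-5
    pair_alpha: float = 0.05
    hub_alpha: float = 0.05
    min_cluster_size: int = 20
    display_rho: float = 0.45
    n_perm_enrich: int = 10000
    n_perm_hub: int = 10000
    dispersion_mode: str = "moderated"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must lie in [0, 1]")
        if self.n_perm_enrich < 1000 or self.n_perm_hub < 1000:
            raise ConfigError("permutation counts must be at least 1000")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a simulated dataset; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    h = _io.config_hash(cfg_dict)
    manifest = {"package": "riboshift", "version": __version__,
                "numpy": np.__version__, "pandas": pd.__version__,
                "config": cfg_dict, "config_hash": h, "stages": {}}

    def _stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # --- simulate ---------------------------------------------------------
    st = _stage("simulate")
    sim_cfg = _sim.SimConfig(
        n_genes=config.n_genes, n_patients=config.n_patients,
        depth_per_library=config.depth_per_library,
        effect_size_lfc=config.effect_size_lfc, seed=config.seed)
    table, truth = _sim.generate_counts(sim_cfg)
    _io.write_count_table(table, out / "counts.tsv", out / "meta.tsv",
                          out / "cds_lengths.tsv")
    _io.write_tsv(truth.genes, out / "truth_genes.tsv", "simulate", h)
    st["n_genes"] = int(config.n_genes)

    cds_model = _sim.make_cds_model(n_genes=30, seed=config.seed + 1)
    footprints = _sim.generate_footprints(
        config.n_qc_reads, config.in_frame_fraction, cds_model,
        seed=config.seed + 2, sample="sim")
    _io.write_bed6(footprints, out / "footprints.bed")
    _io.write_gtf_cds(cds_model, out / "annotation.gtf")

    # --- qc ---------------------------------------------------------------
    st = _stage("qc")
    qc_table = _qc.qc_summary(footprints, cds_model)
    _io.write_tsv(qc_table, out / "qc.tsv", "qc", h, index=False)
    st["n_psites"] = int(qc_table["n_psites"].sum())

    # --- normalize --------------------------------------------------------
    st = _stage("normalize")
    tpm = compute_tpm(table)
    kept = filter_expressed(tpm, threshold=config.min_tpm)
    table_f = table.subset_genes(kept)
    sf = size_factors(table_f.counts)
    _io.write_tsv(sf.to_frame(), out / "size_factors.tsv", "normalize", h)
    st["n_genes_in"] = int(config.n_genes)
    st["n_genes_kept"] = int(len(kept))

    # --- dte --------------------------------------------------------------
    st = _stage("dte")
    dte = run_dte(table_f, size_factors=sf, alpha=config.alpha,
                  dispersion_mode=config.dispersion_mode)
    _io.write_tsv(dte.per_time, out / "dte_per_time.tsv", "dte", h, index=False)
    _io.write_tsv(dte.per_gene, out / "dte_per_gene.tsv", "dte", h)
    st["n_dtegs"] = int(dte.per_gene["dteg"].sum())
    st["n_dtgs"] = int(dte.per_gene["dtg"].sum())

    # --- classify ---------------------------------------------------------
    st = _stage("classify")
    calls = classify_genes(dte, alpha=config.alpha)
    clusters = cluster_profiles(calls, dte,
                                          min_cluster_size=config.min_cluster_size)
    merged = calls.join(clusters.assignments[["cluster", "displayable"]])
    _io.write_tsv(merged, out / "regulation_calls.tsv", "classify", h)
    _io.write_tsv(clusters.profiles, out / "cluster_profiles.tsv", "classify",
                  h, index=False)
    st["class_counts"] = {k: int(v) for k, v in
                          calls["class"].value_counts().items()}

    # --- enrich -----------------------------------------------------------
    st = _stage("enrich")
    background = sorted(set(dte.dtegs) | set(dte.dtgs))
    if len(background) >= 10:
        rng = np.random.default_rng(config.seed + 3)
        rbp_truth = {
            f"RBP{i + 1:02d}": list(rng.choice(background,
                                               size=max(5, len(background) // 10),
                                               replace=False))
            for i in range(config.n_rbps)}
        annotation = _sim.make_gene_annotation(background, seed=config.seed + 4)
        peaks = _sim.generate_peaks(rbp_truth, annotation,
                                    fraction_passing_filters=0.8,
                                    seed=config.seed + 5,
                                    min_fold=config.eclip_min_fold,
                                    max_p=config.eclip_max_p)
        target_sets = {}
        for rbp, pk in peaks.items():
            _io.write_narrowpeak(pk, out / f"peaks_{rbp}.narrowPeak")
            filt = _enrich.filter_eclip_peaks(pk, config.eclip_min_fold,
                                              config.eclip_max_p)
            target_sets[rbp] = _enrich.peaks_to_targets(filt, annotation,
                                                        background)
        groups = {}
        for (cls, direction), sub in calls.groupby(["class8", "direction"]):
            if cls != "none" and len(sub):
                members = [g for g in sub.index if g in set(background)]
                if members:
                    groups[f"{cls}_{direction}"] = members
        res = _enrich.enrich_all(target_sets, groups, background,
                                 n_perm=config.n_perm_enrich,
                                 seed=config.seed + 6, alpha=config.alpha)
        _io.write_tsv(res.table, out / "enrichment.tsv", "enrich", h,
                      index=False)
        st["n_pairs"] = int(len(res.table))
    else:
        logger.warning("too few background genes; enrichment skipped")
        st["skipped"] = True

    # --- cohort -----------------------------------------------------------
    st = _stage("cohort")
    cmat, ctruth = _sim.generate_cohort(
        n_patients=config.cohort_patients, n_rbps=config.n_rbps,
        n_targets_per_hub=config.n_targets_per_hub,
        hub_strength=config.hub_strength, seed=config.seed + 7,
        rbp_severity_shift=0.5)
    pairs = [(rbp, t) for rbp, tgts in ctruth.rbp_targets.items() for t in tgts]
    edges = _cohort.correlate_pairs(cmat, pairs, pair_alpha=config.pair_alpha)
    hubs = _cohort.hub_test(edges, cmat, analyzed_genes=ctruth.target_genes,
                            n_perm=config.n_perm_hub, seed=config.seed + 8,
                            pair_alpha=config.pair_alpha,
                            hub_alpha=config.hub_alpha)
    strat = _cohort.stratify_patients(
        cmat.tpm_mrna.loc[ctruth.marker_genes])
    ttests = _cohort.compare_rbp_by_severity(
        cmat.tpm_mrna.loc[ctruth.rbp_genes], strat)
    display = _cohort.filter_edges_for_display(edges, config.display_rho)
    _io.write_tsv(edges, out / "cohort_edges.tsv", "cohort", h, index=False)
    _io.write_tsv(hubs, out / "cohort_hubs.tsv", "cohort", h, index=False)
    _io.write_tsv(strat, out / "cohort_severity.tsv", "cohort", h)
    _io.write_tsv(ttests, out / "cohort_rbp_ttests.tsv", "cohort", h)
    _io.write_tsv(display, out / "cohort_edges_display.tsv", "cohort", h,
                  index=False)
    st["n_edges"] = int(len(edges))
    st["n_hubs"] = int(hubs["hub"].sum()) if len(hubs) else 0

    manifest["input_checksums"] = {
        p.name: _io.sha256_file(p)
        for p in sorted(out.glob("counts.tsv"))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
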