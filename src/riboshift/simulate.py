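"""Synthetic-data generators with known ground truth.

The generators emulate the statistical structure of a TGFb1 stimulation
time-course in primary cardiac fibroblasts and of a DCM patient cohort:

* paired RNA-seq / ribosome-footprint count libraries for 4 patients over 5
  time points, negative-binomially distributed with log-normal patient batch
  effects and per-gene planted fold changes drawn per regulatory class;
* ribosome footprints with a tunable in-frame fraction, for QC benchmarks;
* a 30-patient cohort where hub-RBP footprint abundance drives the
  translational efficiency of its targets through a monotone link, with
  marker genes whose expression defines fibrosis-severity groups;
* narrowPeak CLIP files over the targets of each RBP.

Regulatory classes are planted as constraints on the (dRNA, dTE) pair at the
affected time points; dRPF is always their sum, never sampled independently:

================== ======= ========
class              dRNA    dTE
================== ======= ========
none               0        0
forwarded          +-e      0
exclusive          0        +-e
buffered           +-e      -+e/2   (partial counteraction; dRPF = +-e/2)
buffered_complete  +-e      -+e     (footprints unchanged; dRPF = 0)
intensified        +-e      +-e     (same sign; dRPF = +-2e)
================== ======= ========
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortMatrix
from .errors import ConfigError, InputError
from .expression import CountTable
from .qc import CdsModel

REG_CLASSES = ("none", "forwarded", "exclusive", "buffered",
               "buffered_complete", "intensified")

DEFAULT_TIME_POINTS = ("0", "45min", "2h", "6h", "24h")

DEFAULT_CLASS_PROPORTIONS = {
    "none": 0.70,
    "forwarded": 0.08,
    "exclusive": 0.08,
    "buffered": 0.06,
    "buffered_complete": 0.03,
    "intensified": 0.05,
}


@dataclass
class SimConfig:
    """Study-design parameters for the count simulator.

    Defaults mirror the emulated design: 4 patients, 5 time points, one RNA
    and one footprint library per (patient, time), ~2e6 counts per library.
    """

    n_genes: int = 2000
    n_patients: int = 4
    time_points: tuple = DEFAULT_TIME_POINTS
    depth_per_library: float = 2e6
    dispersion_range: tuple = (0.01, 0.1)
    patient_sd: float = 0.5          # log2 SD of the patient batch effect
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    effect_size_lfc: float = 2.0     # log2 magnitude of planted effects
    transient_fraction: float = 0.0  # fraction of affected genes regulated at
                                     # a single interior time point only
    depth_jitter_sd: float = 0.1     # log2 SD of per-library depth wobble
    baseline_log10_sd: float = 0.8   # spread of baseline gene abundance
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.class_proportions) - set(REG_CLASSES)
        if bad:
            raise ConfigError(f"unknown regulatory class in proportions: {sorted(bad)}")
        total = float(sum(self.class_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, expected 1")
        if self.n_patients < 2:
            raise ConfigError("at least 2 patients required")
        if len(self.time_points) < 2:
            raise ConfigError("at least 2 time points required")
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise ConfigError("dispersion range must be positive")


@dataclass
class GroundTruth:
    """Planted truth channel for tests.

    ``genes`` has one row per gene (class, direction, dispersion); the
    ``d_*`` frames hold the planted log2 effects per non-baseline time point
    and satisfy d_rpf = d_rna + d_te exactly.  Cohort and RBP generators
    populate the remaining fields.
    """

    genes: pd.DataFrame | None = None
    d_rna: pd.DataFrame | None = None
    d_te: pd.DataFrame | None = None
    d_rpf: pd.DataFrame | None = None
    rbp_targets: dict | None = None
    hub_rbps: list | None = None
    severity: pd.Series | None = None


def _class_effects(cls: str, sign: int, e: float):
    """(dRNA, dTE) for a planted class at an affected time point."""
    if cls == "none":
        return 0.0, 0.0
    if cls == "forwarded":
        return sign * e, 0.0
    if cls == "exclusive":
        return 0.0, sign * e
    if cls == "buffered":
        return sign * e, -sign * e / 2.0
    if cls == "buffered_complete":
        return sign * e, -sign * e
    if cls == "intensified":
        return sign * e, sign * e
    raise ConfigError(f"unknown class {cls!r}")


def generate_counts(config: SimConfig):
    """Simulate paired RNA/RPF NB count libraries with planted effects.

    Returns (CountTable, GroundTruth).  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    times = list(config.time_points)
    patients = [f"P{i + 1}" for i in range(config.n_patients)]

    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    gene_class = rng.choice(classes, size=config.n_genes, p=probs)
    sign = rng.choice([1, -1], size=config.n_genes)
    alpha = rng.uniform(*config.dispersion_range, size=config.n_genes)

    # planted per-time effects (log2); affected at all post-baseline times,
    # or at one interior time for the transient subset
    n_t = len(times) - 1
    d_rna = np.zeros((config.n_genes, n_t))
    d_te = np.zeros((config.n_genes, n_t))
    transient = rng.random(config.n_genes) < config.transient_fraction
    trans_t = rng.integers(0, max(n_t - 1, 1), size=config.n_genes)
    for g in range(config.n_genes):
        if gene_class[g] == "none":
            continue
        r, t = _class_effects(gene_class[g], int(sign[g]), config.effect_size_lfc)
        if transient[g]:
            d_rna[g, trans_t[g]] = r
            d_te[g, trans_t[g]] = t
        else:
            d_rna[g, :] = r
            d_te[g, :] = t
    d_rpf = d_rna + d_te

    base = rng.normal(0.0, config.baseline_log10_sd, size=config.n_genes)
    weight = np.power(10.0, base)
    weight /= weight.sum()
    pat_eff = rng.normal(0.0, config.patient_sd, size=config.n_patients)

    counts = {}
    meta_rows = []
    for pi, pat in enumerate(patients):
        for ti, time in enumerate(times):
            for assay in ("RNA", "RPF"):
                lfc = np.zeros(config.n_genes)
                if ti > 0:
                    lfc = d_rna[:, ti - 1].copy()
                    if assay == "RPF":
                        lfc = lfc + d_te[:, ti - 1]
                depth = config.depth_per_library * np.power(
                    2.0, rng.normal(0.0, config.depth_jitter_sd))
                mu = depth * weight * np.power(2.0, pat_eff[pi] + lfc)
                mu = np.maximum(mu, 0.1)
                n_param = 1.0 / alpha
                p_param = n_param / (n_param + mu)
                sid = f"{pat}_{time}_{assay}"
                counts[sid] = rng.negative_binomial(n_param, p_param)
                meta_rows.append({"sample_id": sid, "patient": pat,
                                  "time": time, "assay": assay})

    counts_df = pd.DataFrame(counts, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["time"] = pd.Categorical(meta["time"], categories=times, ordered=True)
    cds_length = pd.Series(rng.integers(100, 1000, size=config.n_genes) * 3,
                           index=genes, name="cds_length")
    table = CountTable(counts_df, meta, cds_length)

    direction = np.where(gene_class == "none", "",
                         np.where(gene_class == "forwarded",
                                  np.where(sign > 0, "up", "down"),
                                  np.where(d_te.sum(axis=1) > 0, "up",
                                           np.where(d_te.sum(axis=1) < 0, "down", ""))))
    truth = GroundTruth(
        genes=pd.DataFrame({"class": gene_class, "direction": direction,
                            "dispersion": alpha}, index=genes),
        d_rna=pd.DataFrame(d_rna, index=genes, columns=times[1:]),
        d_te=pd.DataFrame(d_te, index=genes, columns=times[1:]),
        d_rpf=pd.DataFrame(d_rpf, index=genes, columns=times[1:]),
    )
    return table, truth


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def make_cds_model(n_genes: int = 20, seed: int = 0,
                   utr5: int = 30, utr3: int = 60) -> CdsModel:
    """Random transcript geometry: CDS of 120–900 nt (multiple of 3) flanked
    by fixed-length UTRs, on alternating strands."""
    rng = np.random.default_rng(seed)
    cds_len = rng.integers(40, 300, size=n_genes) * 3
    rows = pd.DataFrame({
        "tx_len": utr5 + cds_len + utr3,
        "strand": np.where(np.arange(n_genes) % 2 == 0, "+", "-"),
        "cds_start": utr5,
        "cds_len": cds_len,
    }, index=[f"tx{i:04d}" for i in range(n_genes)])
    return CdsModel(rows)


def generate_footprints(n_reads: int, in_frame_fraction: float, cds_model: CdsModel,
                        seed: int = 0, read_length: int = 29,
                        psite_offset: int = 12,
                        readthrough_fraction: float = 0.0,
                        sample: str | None = None) -> pd.DataFrame:
    """BED6 footprints whose +offset P-sites fall in frame 0 with probability
    ``in_frame_fraction`` (remaining mass uniform over the three frames).

    ``readthrough_fraction`` is the per-nucleotide P-site density past the
    stop codon relative to the CDS body (i.e. the fraction of ribosomes that
    fail to terminate), emulated by weighting a 30-nt post-stop window
    accordingly.  5' ends are strand-aware.
    """
    if not 0.0 <= in_frame_fraction <= 1.0:
        raise InputError("in_frame_fraction must be in [0, 1]")
    if len(cds_model.table) == 0:
        raise InputError("empty CDS model")
    rng = np.random.default_rng(seed)
    t = cds_model.table
    gene_p = (t["cds_len"] / t["cds_len"].sum()).to_numpy()
    gene_idx = rng.choice(len(t), size=n_reads, p=gene_p)
    frame_p = np.array([
        in_frame_fraction + (1.0 - in_frame_fraction) / 3.0,
        (1.0 - in_frame_fraction) / 3.0,
        (1.0 - in_frame_fraction) / 3.0,
    ])
    frames = rng.choice(3, size=n_reads, p=frame_p)

    rows = []
    tx_len = t["tx_len"].to_numpy()
    cds_start = t["cds_start"].to_numpy()
    cds_len = t["cds_len"].to_numpy()
    strands = t["strand"].to_numpy()
    names = t.index.to_numpy()
    rt_window = 30
    # post-stop window weighted by the relative ribosome density there
    rt_prob = (readthrough_fraction * rt_window
               / (cds_len - 3 + readthrough_fraction * rt_window))
    readthrough = rng.random(n_reads) < rt_prob[gene_idx]
    for i in range(n_reads):
        g = gene_idx[i]
        if readthrough[i]:
            lo = cds_len[g]  # just past the stop codon in CDS coordinates
            hi = min(cds_len[g] + rt_window,
                     tx_len[g] - cds_start[g] - read_length)
            cds_pos = int(rng.integers(lo, max(hi, lo + 1)))
        else:
            # codon positions whose frame matches, keeping the read inside
            # the transcript: psite - offset >= 0 and psite + rest <= tx_len
            n_codons = (cds_len[g] - 3) // 3  # stop codon excluded
            codon = int(rng.integers(0, max(n_codons, 1)))
            cds_pos = 3 * codon + int(frames[i])
        psite = cds_start[g] + cds_pos
        t5 = psite - psite_offset
        if t5 < 0 or t5 + read_length > tx_len[g]:
            continue
        if strands[g] == "+":
            start = t5
        else:
            start = tx_len[g] - 1 - (t5 + read_length - 1)
        rows.append({"chrom": names[g], "start": int(start),
                     "end": int(start + read_length),
                     "name": f"read{i}", "score": 0, "strand": strands[g]})
    fp = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "score", "strand"])
    if sample is not None:
        fp["sample"] = sample
    return fp


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(n_patients: int = 30, n_rbps: int = 21,
                    n_targets_per_hub: int = 50, hub_strength: float = 1.0,
                    n_markers: int = 5, seed: int = 0, n_genes: int = 400,
                    n_hubs: int = 1, noise_sd: float = 0.15,
                    severity_separation: float = 2.0,
                    rbp_severity_shift: float = 0.0,
                    marker_noise_sd: float = 0.1):
    """Patient cohort with planted hub RBPs and severity marker genes.

    Hub RBP footprint abundance drives target log10(TE) with slope
    ``hub_strength`` plus Normal(0, noise_sd) noise; decoy RBPs get random
    target sets with independent TE.  Marker log10 expression increases with
    the planted severity level (extreme groups separated by
    ``severity_separation`` log10 units).  ``rbp_severity_shift`` adds a
    severity-proportional log10 shift to hub RBP expression.
    Returns (CohortMatrix, GroundTruth).
    """
    if n_patients < 5:
        raise ConfigError("at least 5 patients required")
    if n_targets_per_hub > n_genes:
        raise ConfigError("n_targets_per_hub exceeds n_genes")
    rng = np.random.default_rng(seed)
    patients = [f"D{i + 1:02d}" for i in range(n_patients)]
    genes = [f"t{i:04d}" for i in range(n_genes)]
    rbps = [f"RBP{i + 1:02d}" for i in range(n_rbps)]
    markers = [f"MARK{i + 1}" for i in range(n_markers)]
    hubs = rbps[:n_hubs]

    # planted severity: four near-equal groups
    order = rng.permutation(n_patients)
    severity = np.empty(n_patients, dtype=int)
    for lvl, chunk in enumerate(np.array_split(order, 4), start=1):
        severity[chunk] = lvl

    # RBP abundance (log10 TPM_RPF), comfortably above the TPM>5 floor
    rbp_rpf = rng.normal(1.3, 0.35, size=(n_rbps, n_patients))
    for i, rbp in enumerate(rbps):
        if rbp in hubs and rbp_severity_shift != 0.0:
            rbp_rpf[i] += (severity - 1) / 3.0 * rbp_severity_shift
    rbp_mrna = rbp_rpf - rng.normal(0.1, 0.05, size=(n_rbps, n_patients))

    # targets
    targets = {}
    used = rng.permutation(n_genes)
    pos = 0
    for rbp in hubs:
        targets[rbp] = [genes[j] for j in used[pos:pos + n_targets_per_hub]]
        pos += n_targets_per_hub
    for rbp in rbps[n_hubs:]:
        targets[rbp] = [genes[j] for j in
                        rng.choice(n_genes, size=min(n_targets_per_hub, n_genes),
                                   replace=False)]

    # gene expression: log10 TPM_mRNA baseline and TE
    g_mrna = rng.normal(1.2, 0.3, size=(n_genes, n_patients))
    g_logte = rng.normal(0.0, 0.25, size=(n_genes, n_patients))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for h, rbp in enumerate(hubs):
        drive = rbp_rpf[rbps.index(rbp)] - rbp_rpf[rbps.index(rbp)].mean()
        for g in targets[rbp]:
            g_logte[gene_pos[g]] = (hub_strength * drive
                                    + rng.normal(0.0, noise_sd, size=n_patients))
    g_rpf = g_mrna + g_logte

    # markers: severity-graded expression
    step = severity_separation / 3.0
    m_mrna = (rng.normal(1.0, 0.05, size=(n_markers, 1))
              + (severity - 1)[None, :] * step
              + rng.normal(0.0, marker_noise_sd, size=(n_markers, n_patients)))
    m_rpf = m_mrna + rng.normal(0.0, 0.05, size=(n_markers, n_patients))

    index = genes + rbps + markers
    tpm_mrna = pd.DataFrame(
        np.power(10.0, np.vstack([g_mrna, rbp_mrna, m_mrna])),
        index=index, columns=patients)
    tpm_rpf = pd.DataFrame(
        np.power(10.0, np.vstack([g_rpf, rbp_rpf, m_rpf])),
        index=index, columns=patients)
    cohort = CohortMatrix(tpm_mrna, tpm_rpf)
    truth = GroundTruth(
        rbp_targets=targets,
        hub_rbps=list(hubs),
        severity=pd.Series(severity, index=patients, name="severity"),
    )
    truth.marker_genes = markers
    truth.rbp_genes = rbps
    truth.target_genes = genes
    return cohort, truth


# ---------------------------------------------------------------------------
# CLIP peaks
# ---------------------------------------------------------------------------

def make_gene_annotation(genes, seed: int = 0, span: int = 2000,
                         gap: int = 500) -> pd.DataFrame:
    """Toy gene spans laid end-to-end on one contig, alternating strands."""
    rng = np.random.default_rng(seed)
    starts = np.arange(len(genes)) * (span + gap)
    return pd.DataFrame({
        "gene": list(genes),
        "chrom": "chr1",
        "start": starts,
        "end": starts + span,
        "strand": np.where(rng.random(len(genes)) < 0.5, "+", "-"),
    })


def generate_peaks(rbp_targets: dict, annotation: pd.DataFrame,
                   fraction_passing_filters: float = 1.0, seed: int = 0,
                   min_fold: float = 8.0, max_p: float = 1e-5) -> dict:
    """One narrowPeak record per (RBP, target); exactly
    round(fraction * n_targets) records pass the fold/p filters."""
    if not 0.0 <= fraction_passing_filters <= 1.0:
        raise ConfigError("fraction_passing_filters must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ann = annotation.set_index("gene")
    out = {}
    for rbp, tgts in rbp_targets.items():
        tgts = [g for g in tgts if g in ann.index]
        n = len(tgts)
        n_pass = int(round(fraction_passing_filters * n))
        passing = set(rng.choice(n, size=n_pass, replace=False)) if n else set()
        rows = []
        for i, g in enumerate(tgts):
            grow = ann.loc[g]
            width = int(rng.integers(30, 80))
            start = int(rng.integers(grow["start"], grow["end"] - width))
            if i in passing:
                signal = float(rng.uniform(min_fold, 4 * min_fold))
                p_log10 = float(rng.uniform(-np.log10(max_p) + 0.5,
                                            -np.log10(max_p) + 15.0))
            else:
                if rng.random() < 0.5:
                    signal = float(rng.uniform(1.0, min_fold * 0.98))
                    p_log10 = float(rng.uniform(1.0, -np.log10(max_p) - 0.5))
                else:
                    signal = float(rng.uniform(min_fold, 4 * min_fold))
                    p_log10 = float(rng.uniform(1.0, -np.log10(max_p) - 0.5))
            rows.append({"chrom": grow["chrom"], "start": start,
                         "end": start + width, "name": f"{rbp}_peak{i}",
                         "score": int(min(signal * 100, 1000)),
                         "strand": grow["strand"],
                         "signal_value": round(signal, 4),
                         "p_log10": round(p_log10, 4),
                         "q_log10": round(max(p_log10 - 1.0, 0.0), 4),
                         "peak_point": width // 2})
        out[rbp] = pd.DataFrame(rows, columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "signal_value", "p_log10", "q_log10", "peak_point"])
    return out
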