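"""Patient-cohort RBP-target network: Spearman edges, permutation hub calling,
fibrosis-severity stratification and low-vs-high RBP comparison.

If an RNA-binding protein controls the translation of its targets, its
footprint abundance (log10 TPM_RPF) should track the targets' translational
efficiency (log10 TE = log10 of the footprint/mRNA TPM ratio) across
patients.  Edges are Spearman rank correlations; an RBP is a hub when it has
significantly more correlated candidate pairs than random same-size target
sets drawn from the analyzed genes (empirical permutation p, BH across RBPs).
Patients are stratified into four fibrosis-severity levels by hierarchical
clustering of marker-gene expression, and hub expression is compared between
the lowest and highest level with an equal-variance two-sample t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage

from .dte import bh_adjust
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class CohortMatrix:
    """Per-patient mRNA and footprint TPM (genes x patients)."""

    tpm_mrna: pd.DataFrame
    tpm_rpf: pd.DataFrame
    expression_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.tpm_mrna.columns.equals(self.tpm_rpf.columns):
            raise InputError("mRNA and RPF tables must share patient columns")
        self.tpm_rpf = self.tpm_rpf.reindex(self.tpm_mrna.index)

    @property
    def patients(self) -> pd.Index:
        return self.tpm_mrna.columns

    def log10_te(self) -> pd.DataFrame:
        """log10(TPM_RPF / TPM_mRNA); NaN where either TPM fails the floor."""
        ok = (self.tpm_mrna > max(self.expression_floor, 0.0)) & \
             (self.tpm_rpf > max(self.expression_floor, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            te = np.log10(self.tpm_rpf / self.tpm_mrna)
        return te.where(ok)

    def log10_rpf(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return np.log10(self.tpm_rpf.where(self.tpm_rpf > 0))


def _spearman(x: np.ndarray, y: np.ndarray):
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 5:
        return np.nan, np.nan, int(ok.sum())
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p), int(ok.sum())


def correlate_pairs(cohort: CohortMatrix, candidate_pairs,
                    pair_alpha: float = 0.05) -> pd.DataFrame:
    """Spearman rho between RBP log10(TPM_RPF) and target log10(TE) per pair.

    Pairs with fewer than 5 patients of complete data, or a constant vector,
    are skipped (logged).
    """
    te = cohort.log10_te()
    rpf = cohort.log10_rpf()
    rows = []
    for rbp, target in candidate_pairs:
        if rbp not in rpf.index or target not in te.index:
            logger.info("skipping pair (%s, %s): gene absent", rbp, target)
            continue
        x = rpf.loc[rbp].to_numpy(dtype=float)
        y = te.loc[target].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 5:
            logger.info("skipping pair (%s, %s): <5 complete patients", rbp, target)
            continue
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            logger.info("skipping pair (%s, %s): constant vector", rbp, target)
            continue
        rho, p, n = _spearman(x, y)
        rows.append({"rbp": rbp, "target": target, "rho": rho, "p": p,
                     "n_patients": n, "significant": bool(p < pair_alpha)})
    return pd.DataFrame(rows, columns=["rbp", "target", "rho", "p",
                                       "n_patients", "significant"])


def hub_test(edges: pd.DataFrame, cohort: CohortMatrix,
             analyzed_genes=None, n_perm: int = 10000, seed: int = 0,
             pair_alpha: float = 0.05, hub_alpha: float = 0.05) -> pd.DataFrame:
    """Permutation test for hubs: is the number of significantly correlated
    pairs of an RBP larger than for random same-size target sets?

    The null redraws the target set (patient labels intact): for each RBP the
    correlation significance against every analyzed gene's TE is computed
    once, and each permutation counts significant hits in a random gene
    subset of the observed candidate-set size.
    """
    te = cohort.log10_te()
    rpf = cohort.log10_rpf()
    if analyzed_genes is None:
        analyzed_genes = te.index[te.notna().sum(axis=1) >= 5]
    analyzed_genes = pd.Index(analyzed_genes)
    te_arr = te.loc[analyzed_genes].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rbp, grp in edges.groupby("rbp"):
        k = len(grp)
        if k == 0:
            continue
        observed = int(grp["significant"].sum())
        x = rpf.loc[rbp].to_numpy(dtype=float)
        sig = _pairwise_significance(x, te_arr, pair_alpha)
        null = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            null[i] = sig[rng.choice(len(analyzed_genes), size=k, replace=False)].sum()
        emp_p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
        rows.append({"rbp": rbp, "n_candidates": k, "observed": observed,
                     "null_mean": float(null.mean()), "null_sd": float(null.std()),
                     "empirical_p": float(emp_p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["empirical_p"])
        out["hub"] = out["padj"] < hub_alpha
    return out


def _pairwise_significance(x: np.ndarray, te_arr: np.ndarray,
                           pair_alpha: float) -> np.ndarray:
    """Boolean vector: Spearman p < alpha between x and each row of te_arr."""
    out = np.zeros(te_arr.shape[0], dtype=bool)
    for i in range(te_arr.shape[0]):
        y = te_arr[i]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 5 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            continue
        _, p = stats.spearmanr(x[ok], y[ok])
        out[i] = p < pair_alpha
    return out


def stratify_patients(marker_tpm: pd.DataFrame, k_levels: int = 4) -> pd.DataFrame:
    """Cluster patients on log10 marker TPM (complete linkage, Euclidean) and
    order the clusters by mean marker expression into severity levels 1..k.

    ``marker_tpm`` is markers x patients.  Level 1 = lowest marker
    expression ("low"), level k = highest ("high").
    """
    if marker_tpm.shape[1] < k_levels:
        raise InputError("fewer patients than severity levels")
    if marker_tpm.shape[0] < 1:
        raise InputError("at least one marker gene required")
    logx = np.log10(marker_tpm.clip(lower=1e-6)).T  # patients x markers
    if np.allclose(logx.to_numpy(), logx.to_numpy()[0], atol=1e-12):
        raise InputError("identical marker profiles across patients; no structure")
    if k_levels == 1:
        labels = np.zeros(len(logx), dtype=int)
    else:
        Z = linkage(logx.to_numpy(), method="complete", metric="euclidean")
        labels = cut_tree(Z, n_clusters=k_levels).ravel()
    means = logx.mean(axis=1).groupby(labels).mean()
    order = means.sort_values().index
    level_of = {lab: i + 1 for i, lab in enumerate(order)}
    severity = np.array([level_of[lab] for lab in labels])
    out = pd.DataFrame({"patient": logx.index, "severity": severity})
    out["group"] = np.where(out["severity"] == 1, "low",
                            np.where(out["severity"] == severity.max(), "high", "mid"))
    return out.set_index("patient")


def compare_rbp_by_severity(rbp_tpm: pd.DataFrame,
                            assignment: pd.DataFrame) -> pd.DataFrame:
    """Equal-variance two-sample t test of log10 RBP TPM, low vs high severity."""
    low = assignment.index[assignment["group"] == "low"]
    high = assignment.index[assignment["group"] == "high"]
    if len(low) == 0 or len(high) == 0:
        raise InputError("both low and high severity groups must be non-empty")
    if len(low) < 2 or len(high) < 2:
        raise InputError("severity groups must have at least 2 patients each")
    rows = []
    for rbp, row in rbp_tpm.iterrows():
        a = np.log10(row[low].clip(lower=1e-6).astype(float))
        b = np.log10(row[high].clip(lower=1e-6).astype(float))
        t, p = stats.ttest_ind(b, a, equal_var=True)
        rows.append({"rbp": rbp, "t": float(t), "p": float(p),
                     "mean_low": float(a.mean()), "mean_high": float(b.mean())})
    return pd.DataFrame(rows).set_index("rbp")


def marker_rbp_correlation(cohort: CohortMatrix, rbps, markers,
                           alpha: float = 0.05):
    """Spearman rho between RBP log10(TPM_mRNA) and each fibrosis marker's
    log10(TPM_mRNA); returns the rho/p table and the mean number of
    significantly correlated markers per RBP."""
    with np.errstate(divide="ignore"):
        logm = np.log10(cohort.tpm_mrna.where(cohort.tpm_mrna > 0))
    rows = []
    for rbp in rbps:
        for marker in markers:
            rho, p, n = _spearman(logm.loc[rbp].to_numpy(dtype=float),
                                  logm.loc[marker].to_numpy(dtype=float))
            rows.append({"rbp": rbp, "marker": marker, "rho": rho, "p": p,
                         "significant": bool(p < alpha) if p == p else False})
    table = pd.DataFrame(rows)
    mean_sig = float(table.groupby("rbp")["significant"].sum().mean())
    return table, mean_sig


def filter_edges_for_display(edges: pd.DataFrame, min_abs_rho: float = 0.45):
    """Visualization-only filter |rho| >= threshold; never alters hub calls."""
    return edges.loc[edges["rho"].abs() >= min_abs_rho]
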