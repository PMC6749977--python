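"""RBP target sets from CLIP peaks, and permutation overrepresentation tests.

eCLIP narrowPeak records are filtered for signal (fold enrichment >= 8) and
significance (peak p < 1e-5); a gene is a target when at least one surviving
peak overlaps its annotated span on the matching strand.  Overrepresentation
of an RBP's targets in a gene group (regulatory class or temporal cluster) is
assessed against a permutation null: target counts in random same-size gene
sets drawn from the analysis background (the union of DTGs and DTEGs),
100 000 draws by default.  The empirical p uses the +1 correction, z-scores
give the effect size, and BH correction runs across all (RBP, group) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dte import bh_adjust
from .errors import InputError

NARROWPEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                      "signal_value", "p_log10", "q_log10", "peak_point"]


def filter_eclip_peaks(peaks: pd.DataFrame, min_fold: float = 8.0,
                       max_p: float = 1e-5) -> pd.DataFrame:
    """Keep peaks with signal_value >= min_fold and p < max_p.

    The fold boundary is inclusive; the p boundary is strict.
    """
    need = {"signal_value", "p_log10"}
    missing = need - set(peaks.columns)
    if missing:
        raise InputError(f"narrowPeak table missing columns: {sorted(missing)}")
    keep = (peaks["signal_value"] >= min_fold) & \
           (peaks["p_log10"] > -np.log10(max_p))
    return peaks.loc[keep]


def peaks_to_targets(peaks: pd.DataFrame, annotation: pd.DataFrame,
                     background=None) -> set:
    """Genes with >= 1 peak overlapping their span on the matching strand.

    ``annotation`` needs columns gene, chrom, start, end, strand (0-based
    half-open).  When ``background`` is given the target set is intersected
    with it.
    """
    targets = set()
    for chrom, grp in annotation.groupby("chrom"):
        sub = peaks.loc[peaks["chrom"] == chrom]
        if len(sub) == 0:
            continue
        ps = sub["start"].to_numpy()
        pe = sub["end"].to_numpy()
        pstr = sub["strand"].to_numpy()
        for _, g in grp.iterrows():
            hit = (ps < g["end"]) & (pe > g["start"]) & (pstr == g["strand"])
            if hit.any():
                targets.add(g["gene"])
    if background is not None:
        targets &= set(background)
    return targets


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # rbp, group, observed, null_mean, null_sd, z,
                         # empirical_p, padj, overrepresented


def permutation_overrepresentation(targets: set, group, background,
                                   n_perm: int = 100_000, seed: int = 0,
                                   rng=None) -> dict:
    """Permutation test for one (target set, group) pair.

    Null: number of targets among ``len(group)`` genes drawn uniformly
    without replacement from the background, ``n_perm`` times.
    """
    background = list(background)
    group = set(group)
    if not group <= set(background):
        raise InputError("group must be a subset of the background")
    if n_perm < 1000:
        raise InputError("n_perm must be at least 1000")
    if rng is None:
        rng = np.random.default_rng(seed)
    is_target = np.array([g in targets for g in background])
    observed = int(len(group & set(targets)))
    k = len(group)
    null = np.empty(n_perm, dtype=int)
    n_bg = len(background)
    for i in range(n_perm):
        null[i] = is_target[rng.choice(n_bg, size=k, replace=False)].sum()
    mean, sd = float(null.mean()), float(null.std())
    z = (observed - mean) / sd if sd > 0 else np.nan
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return {"observed": observed, "null_mean": mean, "null_sd": sd,
            "z": z, "empirical_p": float(p),
            "degenerate": sd == 0.0}


def enrich_all(target_sets: dict, groups: dict, background,
               n_perm: int = 100_000, seed: int = 0,
               alpha: float = 0.05) -> EnrichmentResult:
    """Overrepresentation of every RBP target set in every gene group.

    Permutation draws are shared across RBPs within a group (the null subset
    draws depend only on the group size), which keeps 1e5 draws tractable for
    many RBPs.  BH correction is applied across all (RBP, group) pairs.
    """
    background = list(background)
    n_bg = len(background)
    pos = {g: i for i, g in enumerate(background)}
    rbps = list(target_sets)
    memb = np.zeros((n_bg, len(rbps)), dtype=bool)
    for j, rbp in enumerate(rbps):
        for g in target_sets[rbp]:
            if g in pos:
                memb[pos[g], j] = True
    rng = np.random.default_rng(seed)
    rows = []
    for gname, group in groups.items():
        group = set(group)
        if not group <= set(background):
            raise InputError(f"group {gname!r} is not a subset of the background")
        k = len(group)
        if k == 0:
            continue
        null = np.zeros((n_perm, len(rbps)), dtype=np.int32)
        chunk = max(1, int(2e7 // max(k * len(rbps), 1)))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            idx = np.empty((m, k), dtype=np.int64)
            for i in range(m):
                idx[i] = rng.choice(n_bg, size=k, replace=False)
            null[done:done + m] = memb[idx].sum(axis=1)
            done += m
        gidx = np.array([pos[g] for g in group])
        observed = memb[gidx].sum(axis=0)
        mean = null.mean(axis=0)
        sd = null.std(axis=0)
        geq = (null >= observed[None, :]).sum(axis=0)
        p = (1.0 + geq) / (n_perm + 1.0)
        for j, rbp in enumerate(rbps):
            z = (observed[j] - mean[j]) / sd[j] if sd[j] > 0 else np.nan
            rows.append({"rbp": rbp, "group": gname,
                         "observed": int(observed[j]),
                         "null_mean": float(mean[j]), "null_sd": float(sd[j]),
                         "z": float(z) if z == z else np.nan,
                         "empirical_p": float(p[j]),
                         "degenerate": bool(sd[j] == 0.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["padj"] = bh_adjust(table["empirical_p"])
        table["overrepresented"] = table["padj"] < alpha
    return EnrichmentResult(table=table)
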