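"""Ribosome-footprint quality control: P-site inference, 3-nt periodicity and
stop-codon drop-off.

Footprints arrive as BED6 records on per-transcript contigs (alignment to the
genome is upstream of this package; the QC arithmetic is coordinate-frame
independent).  The peptidyl site of the ribosome sits a fixed +12 nt
downstream of the footprint 5' end for ~29-nt fragments; mapped into CDS
coordinates its position modulo 3 gives the reading frame.  Genuine
elongating ribosomes step three nucleotides at a time, so the fraction of
P-sites in frame 0 ("periodicity") approaches 1 for clean libraries and 1/3
for random fragmentation, and P-site density collapses immediately after the
stop codon when ribosomes dissociate on termination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_PSITE_OFFSET = 12

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class CdsModel:
    """Per-gene transcript geometry.

    ``table`` is indexed by gene id with columns ``tx_len`` (contig length),
    ``strand``, ``cds_start`` (transcript coordinate of the first CDS nt,
    0-based) and ``cds_len`` (nt, a multiple of 3, stop codon included).
    Transcript coordinates run 5'->3'; on the minus strand transcript
    position p corresponds to contig coordinate ``tx_len - 1 - p``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"tx_len", "strand", "cds_start", "cds_len"}
        missing = need - set(self.table.columns)
        if missing:
            raise InputError(f"CDS model missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise InputError("empty CDS model")
        t = self.table
        if (t["cds_len"] < 9).any() or (t["cds_len"] % 3 != 0).any():
            raise InputError("CDS lengths must be >= 9 and divisible by 3")
        if ((t["cds_start"] + t["cds_len"]) > t["tx_len"]).any():
            raise InputError("CDS extends past transcript end")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def to_transcript(self, gene: str, contig_pos: np.ndarray) -> np.ndarray:
        row = self.table.loc[gene]
        if row["strand"] == "-":
            return int(row["tx_len"]) - 1 - contig_pos
        return contig_pos

    def to_contig(self, gene: str, tx_pos: np.ndarray) -> np.ndarray:
        return self.to_transcript(gene, tx_pos)  # the map is an involution


def infer_psites(footprints: pd.DataFrame, cds: CdsModel,
                 offset: int = DEFAULT_PSITE_OFFSET) -> pd.DataFrame:
    """Shift footprint 5' ends by ``offset`` nt (strand-aware) into P-sites.

    Returns one row per retained footprint: gene, P-site transcript position,
    CDS-relative position, frame, and whether it lies within the CDS body.
    Footprints on contigs absent from the CDS model are dropped (counted in
    the log).
    """
    miss = ~footprints["chrom"].isin(cds.genes)
    if miss.any():
        logger.warning("dropping %d footprints on unannotated transcripts",
                       int(miss.sum()))
    fp = footprints.loc[~miss]
    out = []
    for gene, grp in fp.groupby("chrom", sort=False):
        row = cds.table.loc[gene]
        plus = grp["strand"].to_numpy() == "+"
        contig5 = np.where(plus, grp["start"].to_numpy(),
                           grp["end"].to_numpy() - 1)
        tx5 = cds.to_transcript(gene, contig5)
        psite = tx5 + offset
        cds_pos = psite - int(row["cds_start"])
        in_cds = (cds_pos >= 0) & (cds_pos < int(row["cds_len"]))
        valid = (psite >= 0) & (psite < int(row["tx_len"]))
        sub = pd.DataFrame({
            "gene": gene,
            "psite": psite[valid],
            "cds_pos": cds_pos[valid],
            "frame": np.mod(cds_pos[valid], 3),
            "in_cds": in_cds[valid],
        })
        if "sample" in grp.columns:
            sub["sample"] = grp.loc[valid, "sample"].to_numpy()
        out.append(sub)
    if not out:
        return pd.DataFrame(columns=["gene", "psite", "cds_pos", "frame", "in_cds"])
    return pd.concat(out, ignore_index=True)


def periodicity(psites: pd.DataFrame) -> float | pd.Series:
    """Fraction of CDS-internal P-sites in frame 0.

    If a ``sample`` column is present the fraction is reported per sample.
    """
    body = psites.loc[psites["in_cds"]]
    if len(body) == 0:
        logger.warning("no CDS-internal P-sites; periodicity undefined")
        return np.nan
    if "sample" in body.columns:
        return body.groupby("sample")["frame"].apply(lambda f: float((f == 0).mean()))
    return float((body["frame"] == 0).mean())


def frame_fractions(psites: pd.DataFrame) -> np.ndarray:
    body = psites.loc[psites["in_cds"]]
    counts = np.bincount(body["frame"].to_numpy(), minlength=3).astype(float)
    return counts / counts.sum() if counts.sum() else np.full(3, np.nan)


def stop_dropoff_profile(psites: pd.DataFrame, cds: CdsModel, window: int = 30):
    """Meta-gene P-site density around the stop codon.

    Offsets are relative to the first nt of the stop codon; the profile over
    [-window, +window] is normalized so the upstream (offset < 0) mean is 1.
    The drop-off ratio is mean density after the stop codon (offset >= 3)
    over mean density before it — near 0 when ribosomes terminate cleanly,
    approximately the read-through fraction otherwise.
    """
    shortest = int(cds.table["cds_len"].min())
    if window > shortest // 2:
        raise InputError(f"window {window} exceeds half the shortest CDS ({shortest})")
    # offset from the first nt of the stop codon, in CDS coordinates
    cds_len = cds.table["cds_len"].reindex(psites["gene"]).to_numpy()
    rel = psites["cds_pos"].to_numpy() - (cds_len - 3)
    offsets = np.arange(-window, window + 1)
    keep = (rel >= -window) & (rel <= window)
    counts = np.bincount((rel[keep] + window).astype(int),
                         minlength=2 * window + 1).astype(float)
    upstream = counts[offsets < 0]
    norm = upstream.mean() if upstream.mean() > 0 else 1.0
    density = counts / norm
    post = counts[offsets >= 3]
    pre = counts[offsets < 0]
    ratio = float(post.mean() / pre.mean()) if pre.mean() > 0 else np.nan
    return pd.DataFrame({"offset": offsets, "density": density}), ratio


def qc_summary(footprints: pd.DataFrame, cds: CdsModel,
               offset: int = DEFAULT_PSITE_OFFSET, window: int = 30) -> pd.DataFrame:
    """Per-sample QC table: number of P-sites, periodicity, drop-off ratio."""
    ps = infer_psites(footprints, cds, offset=offset)
    if "sample" not in ps.columns:
        ps = ps.assign(sample="all")
    rows = []
    for sample, grp in ps.groupby("sample"):
        _, ratio = stop_dropoff_profile(grp, cds, window=window)
        rows.append({
            "sample": sample,
            "n_psites": int(len(grp)),
            "periodicity": periodicity(grp),
            "dropoff_ratio": ratio,
        })
    return pd.DataFrame(rows)
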