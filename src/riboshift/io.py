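"""Plain-text readers and writers: count/metadata TSV, BED6, narrowPeak and a
minimal GTF for CDS geometry.  All outputs are TSV for diffability; ``.gz``
paths are handled transparently.  Every table written by a pipeline stage
carries a comment header naming the stage and the configuration hash."""

from __future__ import annotations

import gzip
import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import NARROWPEAK_COLUMNS
from .errors import InputError
from .expression import CountTable
from .qc import BED6_COLUMNS, CdsModel


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = repr(sorted((str(k), str(v)) for k, v in config.items()))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, stage: str | None = None,
              cfg_hash: str | None = None, index: bool = True) -> None:
    with _open_text(path, "wt") as fh:
        if stage is not None:
            fh.write(f"# stage={stage} config={cfg_hash or 'na'}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# counts + metadata
# ---------------------------------------------------------------------------

def read_count_table(path, meta_path, cds_path=None) -> CountTable:
    """Counts TSV (gene rows, sample columns) + metadata TSV
    (sample_id, patient, time, assay); optional CDS length TSV
    (gene, cds_length).  Validation errors name the offending cell."""
    counts = read_tsv(path, index_col=0)
    meta = read_tsv(meta_path)
    need = {"sample_id", "patient", "time", "assay"}
    missing = need - set(meta.columns)
    if missing:
        raise InputError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    cds = None
    if cds_path is not None:
        cds_df = read_tsv(cds_path)
        if not {"gene", "cds_length"} <= set(cds_df.columns):
            raise InputError("CDS length table needs columns gene, cds_length")
        cds = cds_df.set_index("gene")["cds_length"]
    for col in counts.columns:
        bad = pd.to_numeric(counts[col], errors="coerce").isna()
        if bad.any():
            raise InputError(
                f"non-numeric count at gene {counts.index[bad][0]!r}, "
                f"sample {col!r}")
    return CountTable(counts, meta, cds)


def write_count_table(table: CountTable, counts_path, meta_path,
                      cds_path=None) -> None:
    write_tsv(table.counts, counts_path)
    meta = table.meta.copy()
    meta.index.name = "sample_id"
    write_tsv(meta, meta_path)
    if cds_path is not None and table.cds_length is not None:
        cds = table.cds_length.rename("cds_length").to_frame()
        cds.index.name = "gene"
        write_tsv(cds, cds_path)


# ---------------------------------------------------------------------------
# BED6 / narrowPeak
# ---------------------------------------------------------------------------

def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=BED6_COLUMNS)
    if (df["start"] >= df["end"]).any():
        raise InputError("BED record with start >= end")
    return df

def write_bed6(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=NARROWPEAK_COLUMNS)
    except pd.errors.ParserError as e:
        raise InputError(f"malformed narrowPeak file {path}: {e}") from e
    bad = df["start"] >= df["end"]
    if bad.any():
        raise InputError(
            f"malformed narrowPeak line {int(np.flatnonzero(bad)[0]) + 1}: "
            "start >= end")
    return df

def write_narrowpeak(df: pd.DataFrame, path) -> None:
    df[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GTF (per-transcript contigs; 1-based inclusive on disk)
# ---------------------------------------------------------------------------

def write_gtf_cds(cds: CdsModel, path) -> None:
    """One ``transcript`` and one ``CDS`` feature per gene, on a contig named
    after the gene; coordinates 1-based inclusive."""
    with _open_text(path, "wt") as fh:
        for gene, row in cds.table.iterrows():
            attrs = f'gene_id "{gene}"; transcript_id "{gene}";'
            fh.write("\t".join([gene, "riboshift", "transcript", "1",
                                str(int(row["tx_len"])), ".", row["strand"],
                                ".", attrs]) + "\n")
            if row["strand"] == "+":
                c1 = int(row["cds_start"]) + 1
                c2 = int(row["cds_start"] + row["cds_len"])
            else:
                c2 = int(row["tx_len"] - row["cds_start"])
                c1 = int(row["tx_len"] - row["cds_start"] - row["cds_len"] + 1)
            fh.write("\t".join([gene, "riboshift", "CDS", str(c1), str(c2),
                                ".", row["strand"], ".", attrs]) + "\n")


def read_gtf_cds(path) -> CdsModel:
    """Inverse of :func:`write_gtf_cds`; converts 1-based inclusive
    coordinates back to 0-based half-open transcript geometry."""
    tx_len, strand, cds_span = {}, {}, {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise InputError(f"malformed GTF line: {line[:60]!r}")
            contig, _, feat, start, end, _, strd = f[:7]
            if feat == "transcript":
                tx_len[contig] = int(end)
                strand[contig] = strd
            elif feat == "CDS":
                cds_span[contig] = (int(start) - 1, int(end))
    rows = {}
    for gene in tx_len:
        if gene not in cds_span:
            continue
        c1, c2 = cds_span[gene]
        L = tx_len[gene]
        if strand[gene] == "+":
            cds_start = c1
        else:
            cds_start = L - c2
        rows[gene] = {"tx_len": L, "strand": strand[gene],
                      "cds_start": cds_start, "cds_len": c2 - c1}
    if not rows:
        raise InputError("no transcript/CDS features found in GTF")
    return CdsModel(pd.DataFrame.from_dict(rows, orient="index"))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
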