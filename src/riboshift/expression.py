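"""Count containers, TPM computation, expression filtering and size factors.

Counts are quantified on the coding sequence, so TPM uses the CDS length as
the per-gene length term.  The expression filter removes genes whose mean TPM
falls below a threshold in *either* assay (RNA or ribosome footprints): lowly
expressed genes produce unstable fold changes in the count model downstream.
Size factors follow the median-of-ratios convention and are computed jointly
on RNA and footprint libraries; the assay main effect of the model absorbs
the systematic depth difference between the two library types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

ASSAYS = ("RNA", "RPF")

META_COLUMNS = ("patient", "time", "assay")


@dataclass
class CountTable:
    """Gene x sample integer counts with sample metadata and CDS lengths.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
    meta
        DataFrame indexed by sample id with columns ``patient``, ``time``
        (ordered categorical; first level is the unstimulated baseline) and
        ``assay`` (``RNA`` or ``RPF``).
    cds_length
        Series of CDS lengths (nt) indexed by gene id.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    cds_length: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise InputError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            raise InputError("duplicate sample ids in count table")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise InputError(f"sample metadata missing columns: {missing}")
        unknown = self.meta.index.difference(self.counts.columns)
        if len(unknown):
            raise InputError(
                f"samples in metadata but not in counts: {sorted(unknown)}"
            )
        absent = self.counts.columns.difference(self.meta.index)
        if len(absent):
            raise InputError(
                f"samples in counts but not in metadata: {sorted(absent)}"
            )
        # align metadata row order with the count columns
        self.meta = self.meta.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise InputError("counts must be numeric")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise InputError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
            raise InputError(
                f"non-integer count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        bad = set(self.meta["assay"]) - set(ASSAYS)
        if bad:
            raise InputError(f"unknown assay labels: {sorted(bad)}")
        if self.cds_length is not None:
            self.cds_length = self.cds_length.reindex(self.counts.index)
            if self.cds_length.isna().any():
                miss = self.cds_length.index[self.cds_length.isna()][0]
                raise InputError(f"missing CDS length for gene {miss!r}")
            if (self.cds_length <= 0).any():
                raise InputError("CDS lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "CountTable":
        cds = None if self.cds_length is None else self.cds_length.loc[genes]
        return CountTable(self.counts.loc[genes], self.meta.copy(), cds)


@dataclass
class TpmTable:
    """Transcripts-per-million table; columns sum to 1e6 over the genes kept."""

    tpm: pd.DataFrame
    meta: pd.DataFrame

    def mean_by_assay(self) -> pd.DataFrame:
        """Per-gene mean TPM across all samples of each assay."""
        out = {}
        for assay in ASSAYS:
            cols = self.meta.index[self.meta["assay"] == assay]
            if len(cols):
                out[assay] = self.tpm[cols].mean(axis=1)
        return pd.DataFrame(out)


def compute_tpm(table: CountTable) -> TpmTable:
    """Length-normalized expression: rate_gj = count_gj / len_g, scaled so each
    sample column sums to one million."""
    if table.cds_length is None:
        raise InputError("CDS lengths required to compute TPM")
    rates = table.counts.div(table.cds_length, axis=0)
    totals = rates.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise InputError(f"sample {zero[0]!r} has no counts; cannot compute TPM")
    return TpmTable(rates.div(totals, axis=1) * 1e6, table.meta)


def filter_expressed(tpm: TpmTable, threshold: float = 1.0) -> pd.Index:
    """Genes with mean TPM >= threshold in BOTH assays.

    A gene below the threshold in either the RNA or the footprint libraries is
    removed; the boundary is inclusive (a mean of exactly ``threshold`` stays).
    """
    means = tpm.mean_by_assay()
    for assay in ASSAYS:
        if assay not in means.columns:
            raise InputError(f"no {assay} samples present; both assays required")
    keep = (means >= threshold).all(axis=1)
    return tpm.tpm.index[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Genes with a zero count in any sample are excluded from the reference set
    (their geometric mean would be zero).
    """
    vals = counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise InputError(
            "no gene has nonzero counts in every sample; "
            "consider filtering samples or genes first"
        )
    ref = vals[allpos]
    geo = np.exp(np.log(ref).mean(axis=1))
    s = np.median(ref / geo[:, None], axis=0)
    s /= np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")
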