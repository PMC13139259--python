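"""OTU count tables: reading, validation, QC filtering and abundance summaries.

The substrate of the pipeline is a samples × OTUs count matrix with per-sample
metadata (inbred line, diet, replicate) and per-OTU taxonomy (genus, species).
Quality control follows the standard amplicon workflow for pooled fly samples:
Good's coverage per sample, a minimum-depth cutoff, exclusion of the
*Wolbachia* endosymbiont, and an AUC concordance check of observed endosymbiont
reads against the lines' known infection status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("microgdi")

DIETS = ("control", "restricted")

META_COLUMNS = ["sample_id", "line_id", "diet", "replicate"]


@dataclass
class OtuTable:
    """An OTU count matrix with aligned sample metadata and taxonomy.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, samples as rows, OTU ids as columns.
    meta : pandas.DataFrame
        Indexed by sample id with columns ``line_id``, ``diet``,
        ``replicate``; ``total_reads`` is (re)computed from ``counts``.
    taxonomy : pandas.DataFrame
        Indexed by OTU id with columns ``genus`` and ``species``; unknown
        assignments are the string ``"unknown"``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    taxonomy: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        counts, meta, tax = self.counts, self.meta, self.taxonomy
        if counts.index.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if meta.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        missing = counts.index.difference(meta.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
        extra = meta.index.difference(counts.index)
        if len(extra):
            raise ValueError(f"metadata samples missing from counts: {list(extra)[:5]}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts in OTU table")
        missing_tax = counts.columns.difference(tax.index)
        if len(missing_tax):
            raise ValueError(f"OTUs missing from taxonomy: {list(missing_tax)[:5]}")
        bad_diet = set(meta["diet"].unique()) - set(DIETS)
        if bad_diet:
            raise ValueError(f"unknown diet labels: {sorted(bad_diet)}")
        # keep metadata ordered like the count matrix and depths current
        counts.index.name = "sample_id"
        counts.columns.name = None
        self.meta = meta.loc[counts.index].copy()
        self.meta["total_reads"] = counts.sum(axis=1).astype(int)

    # -- conveniences -----------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def total_reads(self) -> pd.Series:
        return self.meta["total_reads"]

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(
            self.counts.loc[sample_ids],
            self.meta.loc[sample_ids],
            self.taxonomy,
            dict(self.flags),
        )


def read_otu_table(counts_path, metadata_path, taxonomy_path) -> OtuTable:
    """Read and validate an OTU table from three TSV files.

    ``counts_path``: first column OTU id, remaining columns samples
    (OTUs as rows is the on-disk convention; the in-memory matrix is
    samples × OTUs). ``metadata_path``: header sample_id, line_id, diet,
    replicate. ``taxonomy_path``: header otu_id, genus, species.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts = raw.T
    counts.index.name = "sample_id"
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata file")
    meta = meta.set_index("sample_id")
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).set_index("otu_id")
    tax = tax.fillna("unknown")
    return OtuTable(counts, meta, tax)


def write_otu_table(table: OtuTable, counts_path, metadata_path, taxonomy_path) -> None:
    """Write a table back to the same three-file TSV dialect."""
    table.counts.T.rename_axis("otu_id").to_csv(counts_path, sep="\t")
    table.meta.drop(columns="total_reads").rename_axis("sample_id").to_csv(
        metadata_path, sep="\t"
    )
    table.taxonomy.rename_axis("otu_id").to_csv(taxonomy_path, sep="\t")


def goods_coverage(table: OtuTable) -> pd.Series:
    """Good's coverage per sample, in percent.

    ``100 * (1 - n1 / N_T)`` where ``n1`` is the number of singleton OTUs
    (exactly one read) and ``N_T`` the sample's total reads. Estimates the
    probability that one more read would fall in an already-observed OTU.
    """
    depths = table.total_reads
    if (depths < 1).any():
        zero = depths.index[depths < 1].tolist()
        raise ValueError(f"samples with zero reads have undefined coverage: {zero[:5]}")
    n1 = (table.counts == 1).sum(axis=1)
    return 100.0 * (1.0 - n1 / depths)


def filter_low_depth(table: OtuTable, min_reads: int = 1000) -> OtuTable:
    """Drop samples with fewer than ``min_reads`` total reads (boundary kept)."""
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    keep = table.total_reads >= min_reads
    dropped = int((~keep).sum())
    if dropped:
        logger.warning(
            "depth filter (min_reads=%d) removed %d of %d samples",
            min_reads, dropped, len(keep),
        )
    if not keep.any():
        logger.warning("depth filter removed every sample")
    return table.subset_samples(table.sample_ids[keep])


def exclude_taxon(table: OtuTable, taxon_label: str = "Wolbachia") -> OtuTable:
    """Drop every OTU whose genus matches ``taxon_label`` (case-insensitive).

    Per-sample depths are recomputed. Samples left with zero reads are kept
    and flagged under ``flags["zero_read_samples"]``.
    """
    genus = table.taxonomy["genus"].str.lower()
    hit = genus == taxon_label.lower()
    hit_otus = table.taxonomy.index[hit]
    matched = table.counts.columns.intersection(hit_otus)
    if not len(matched):
        logger.info("exclude_taxon: no OTUs assigned to %r", taxon_label)
        return table
    counts = table.counts.drop(columns=matched)
    flags = dict(table.flags)
    zero = counts.index[counts.sum(axis=1) == 0].tolist()
    if zero:
        logger.warning(
            "%d samples have zero reads after excluding %s", len(zero), taxon_label
        )
        flags["zero_read_samples"] = zero
    return OtuTable(counts, table.meta, table.taxonomy.drop(index=hit_otus), flags)


def taxon_read_counts(table: OtuTable, taxon_label: str) -> pd.Series:
    """Total reads per sample assigned to one genus (e.g. the endosymbiont)."""
    genus = table.taxonomy["genus"].str.lower()
    otus = table.counts.columns.intersection(
        table.taxonomy.index[genus == taxon_label.lower()]
    )
    return table.counts[otus].sum(axis=1)


def concordance_auc(
    reads_per_sample: pd.Series,
    known_status: dict,
    meta: pd.DataFrame,
    by_diet: bool = False,
):
    """Concordance between observed taxon reads and known per-line status.

    Returns the probability that a randomly chosen sample from a positive
    line carries strictly more reads of the taxon than one from a negative
    line, ties counted 1/2 — the Mann–Whitney U statistic normalised by
    ``n_pos * n_neg`` (identical to the ROC AUC of reads as a classifier
    score for status).

    With ``by_diet=True`` returns a dict diet → AUC computed within each
    diet separately, plus ``"combined"``.
    """
    if by_diet:
        out = {}
        for diet, sub in meta.groupby("diet", observed=True):
            out[str(diet)] = concordance_auc(
                reads_per_sample.loc[sub.index], known_status, sub
            )
        out["combined"] = concordance_auc(reads_per_sample, known_status, meta)
        return out

    status = meta["line_id"].map(known_status)
    if status.isna().any():
        missing = meta["line_id"][status.isna()].unique().tolist()
        raise ValueError(f"lines without known status: {missing[:5]}")
    reads = reads_per_sample.loc[meta.index].to_numpy(dtype=float)
    pos = reads[status.to_numpy(dtype=bool)]
    neg = reads[~status.to_numpy(dtype=bool)]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both infection-status classes must be present")
    # Mann-Whitney U via midranks: U = R_pos - n_pos(n_pos+1)/2
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def relative_abundance(
    table: OtuTable, rank: str = "genus", drop_unknown: bool = False
) -> pd.DataFrame:
    """Relative abundance per sample and taxon, in percent (rows sum to 100).

    ``R = 100 * n_i / N`` with ``n_i`` reads assigned to taxon *i* at the
    requested rank and ``N`` the sample total. At species rank, unknown
    species are reported as ``"unclassified <genus>"``; ``drop_unknown``
    removes those columns after the percentages are computed (no
    renormalisation), so known-species values keep their share of reads.
    """
    if rank not in ("genus", "species"):
        raise ValueError("rank must be 'genus' or 'species'")
    depths = table.total_reads
    if (depths == 0).any():
        zero = depths.index[depths == 0].tolist()
        raise ValueError(f"zero-read samples have no relative abundance: {zero[:5]}")
    tax = table.taxonomy.loc[table.otu_ids]
    if rank == "genus":
        labels = tax["genus"]
    else:
        unknown = tax["species"].str.lower().isin(["unknown", "", "na"])
        labels = tax["species"].where(~unknown, "unclassified " + tax["genus"])
    grouped = table.counts.T.groupby(labels.to_numpy()).sum().T
    pct = 100.0 * grouped.div(depths, axis=0)
    if rank == "species" and drop_unknown:
        pct = pct.loc[:, ~pct.columns.str.startswith("unclassified ")]
    return pct


def prevalent_taxa(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    threshold: float = 1.0,
    by_line_means: bool = False,
) -> list:
    """Taxa reaching a mean relative abundance >= threshold on >= one diet.

    The mean is taken over samples of each diet (default), or over per-line
    means within each diet when ``by_line_means`` is set.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must be in (0, 100]")
    keep = pd.Series(False, index=abund.columns)
    for _, sub in meta.loc[abund.index].groupby("diet", observed=True):
        vals = abund.loc[sub.index]
        if by_line_means:
            vals = vals.groupby(sub["line_id"]).mean()
        keep |= vals.mean(axis=0) >= threshold
    return list(abund.columns[keep])


def qc_report(table: OtuTable, min_reads: int = 1000) -> pd.DataFrame:
    """Per-sample QC summary: depth, Good's coverage, retained flag."""
    cov = goods_coverage(table)
    return pd.DataFrame(
        {
            "total_reads": table.total_reads,
            "goods_coverage": cov,
            "retained": table.total_reads >= min_reads,
        }
    ).rename_axis("sample_id")
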