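"""Data model and TSV I/O for abundance tables, metadata and gene matrices.

All tabular inputs are tab-separated with a header row and a label
column.  Abundance tables default to samples-as-rows; the orientation
can be flipped with a flag.  Metadata carries one record per sample with
columns ``sample, region, ecosystem, latitude, longitude, altitude_m``
followed by arbitrary numeric environmental columns ("NA" marks a
missing value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("aquassembly")

#: Default ecosystem vocabulary for metadata validation.
ECOSYSTEMS = (
    "saline lake",
    "freshwater lake",
    "river",
    "hot spring",
    "wetland",
    "glacier",
)

METADATA_COLUMNS = ("region", "ecosystem", "latitude", "longitude", "altitude_m")


class TableFormatError(ValueError):
    """Malformed tabular input (negative cells, duplicates, bad dtype)."""


class AlignmentError(ValueError):
    """Sample sets of the supplied inputs cannot be reconciled."""


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {what} labels: {dup}")


@dataclass
class CountTable:
    """Sample-by-taxon read counts with per-sample depths."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableFormatError("count matrix shape does not match labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise TableFormatError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")

    @property
    def depths(self) -> np.ndarray:
        """Per-sample total read count."""
        return self.counts.sum(axis=1)


@dataclass
class AbundanceTable:
    """Sample-by-taxon relative abundances; every row sums to one.

    ``depths`` optionally retains the sequencing depth of each sample so
    downstream detection limits (one read per sample) can be derived.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    abundance: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableFormatError("abundance matrix shape does not match labels")
        if (self.abundance < 0).any():
            i, j = np.argwhere(self.abundance < 0)[0]
            raise TableFormatError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=self.sample_ids, columns=self.taxon_ids
        )

    def select_samples(self, sample_ids) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        depths = None if self.depths is None else np.asarray(self.depths)[idx]
        return AbundanceTable(
            list(sample_ids), list(self.taxon_ids), self.abundance[idx], depths
        )


@dataclass
class GenePresenceMatrix:
    """Sample-by-unigene boolean presence matrix."""

    sample_ids: list[str]
    gene_ids: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.dtype != bool:
            vals = np.unique(self.presence)
            if not np.isin(vals, (0, 1)).all():
                raise TableFormatError("gene matrix must be 0/1")
            self.presence = self.presence.astype(bool)
        if self.presence.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise TableFormatError("presence matrix shape does not match labels")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")

    def select_samples(self, sample_ids) -> "GenePresenceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenePresenceMatrix(
            list(sample_ids), list(self.gene_ids), self.presence[idx]
        )


@dataclass
class OrfCatalog:
    """Total map from predicted ORFs to their non-redundant unigene."""

    orf_ids: list[str]
    unigene_of: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.orf_ids, "ORF")
        missing = [o for o in self.orf_ids if o not in self.unigene_of]
        if missing:
            raise TableFormatError(f"ORFs without a unigene: {missing[:5]}")

    @property
    def n_unigenes(self) -> int:
        return len(set(self.unigene_of[o] for o in self.orf_ids))


@dataclass
class AlignedBundle:
    """Inputs restricted, in identical order, to their shared samples."""

    table: AbundanceTable
    metadata: pd.DataFrame
    genes: GenePresenceMatrix | None = None
    dropped: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance_table(
    path,
    orientation: str = "samples-as-rows",
    renormalize: bool = True,
) -> AbundanceTable:
    """Read a TSV abundance (or count) table and validate it.

    Rows whose sums differ from one are renormalized, so count tables
    are accepted transparently; a row of all zeros is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa-as-rows":
        df = df.T
    elif orientation != "samples-as-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"non-numeric value {df.iat[i, j]!r} at sample {df.index[i]!r}, "
            f"taxon {df.columns[j]!r}"
        )
    table = AbundanceTable(
        [str(s) for s in df.index], [str(t) for t in df.columns], body.astype(float)
    )
    sums = table.abundance.sum(axis=1)
    if (sums == 0).any():
        empty = [table.sample_ids[i] for i in np.flatnonzero(sums == 0)]
        raise TableFormatError(f"empty sample(s): {empty}")
    if renormalize and np.abs(sums - 1.0).max() > 1e-6:
        table.abundance = table.abundance / sums[:, None]
    return table


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.to_frame().rename_axis("sample").to_csv(path, sep="\t")


def read_metadata(path, vocabulary=ECOSYSTEMS) -> pd.DataFrame:
    """Read and validate a sample metadata TSV.

    Returns a DataFrame indexed by sample id; environmental columns keep
    their NA markers as NaN.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    _check_unique(df.index, "sample")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"metadata missing columns: {missing}")
    lat, lon = df["latitude"], df["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise TableFormatError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise TableFormatError("longitude outside [-180, 180]")
    if vocabulary is not None:
        unknown = set(df["ecosystem"].dropna()) - set(vocabulary)
        if unknown:
            raise TableFormatError(f"unknown ecosystem labels: {sorted(unknown)}")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample").to_csv(path, sep="\t", na_rep="NA")


def read_gene_matrix(path) -> GenePresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenePresenceMatrix(
        [str(s) for s in df.index],
        [str(g) for g in df.columns],
        df.to_numpy(),
    )


def write_gene_matrix(genes: GenePresenceMatrix, path) -> None:
    pd.DataFrame(
        genes.presence.astype(int), index=genes.sample_ids, columns=genes.gene_ids
    ).rename_axis("sample").to_csv(path, sep="\t")


def read_orf_catalog(path) -> OrfCatalog:
    df = pd.read_csv(path, sep="\t")
    if not {"orf", "unigene"} <= set(df.columns):
        raise TableFormatError("ORF map needs columns 'orf' and 'unigene'")
    orfs = df["orf"].astype(str).tolist()
    return OrfCatalog(orfs, dict(zip(orfs, df["unigene"].astype(str))))


def write_orf_catalog(catalog: OrfCatalog, path) -> None:
    pd.DataFrame(
        {"orf": catalog.orf_ids,
         "unigene": [catalog.unigene_of[o] for o in catalog.orf_ids]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations


def normalize_counts(counts: CountTable) -> AbundanceTable:
    """Convert counts to relative abundances, retaining depths."""
    depths = counts.depths
    if (depths == 0).any():
        empty = [counts.sample_ids[i] for i in np.flatnonzero(depths == 0)]
        raise TableFormatError(f"zero-depth sample(s): {empty}")
    return AbundanceTable(
        list(counts.sample_ids),
        list(counts.taxon_ids),
        counts.counts / depths[:, None],
        depths=depths,
    )


def align_inputs(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    genes: GenePresenceMatrix | None = None,
) -> AlignedBundle:
    """Restrict all inputs to their shared samples, in a stable order.

    The order of the abundance table is preserved for samples that
    survive; dropped samples are logged and reported in the bundle.
    """
    shared = set(table.sample_ids) & set(metadata.index)
    if genes is not None:
        shared &= set(genes.sample_ids)
    if not shared:
        raise AlignmentError("no samples shared across inputs")
    keep = [s for s in table.sample_ids if s in shared]
    dropped = {
        "table": [s for s in table.sample_ids if s not in shared],
        "metadata": [s for s in metadata.index if s not in shared],
    }
    if genes is not None:
        dropped["genes"] = [s for s in genes.sample_ids if s not in shared]
    for source, lost in dropped.items():
        if lost:
            logger.info("align_inputs: dropped %d samples from %s: %s",
                        len(lost), source, lost[:10])
    return AlignedBundle(
        table=table.select_samples(keep),
        metadata=metadata.loc[keep],
        genes=None if genes is None else genes.select_samples(keep),
        dropped=dropped,
    )


def filter_taxa(
    table: AbundanceTable,
    min_prevalence: float = 0.0,
    min_mean_abundance: float = 0.0,
    renormalize: bool = False,
) -> AbundanceTable:
    """Drop taxa below prevalence/mean-abundance thresholds.

    Both thresholds default to zero (no filtering), matching network
    construction without an abundance pre-filter.  Rows are not
    renormalized unless requested, so relative abundances stay
    comparable across filter settings.
    """
    if not (0 <= min_prevalence <= 1 and 0 <= min_mean_abundance <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    prevalence = (table.abundance > 0).mean(axis=0)
    mean_ab = table.abundance.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (mean_ab >= min_mean_abundance)
    if not keep.any():
        raise ValueError("filter removed every taxon")
    ab = table.abundance[:, keep]
    if renormalize:
        sums = ab.sum(axis=1, keepdims=True)
        ab = np.divide(ab, sums, out=np.zeros_like(ab), where=sums > 0)
    return AbundanceTable(
        list(table.sample_ids),
        [t for t, k in zip(table.taxon_ids, keep) if k],
        ab,
        depths=table.depths,
    )
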