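"""Readers, writers, and core transforms for OTU tables.

In-memory conventions (used throughout the package)
---------------------------------------------------
* **Counts / relative abundances**: :class:`pandas.DataFrame`, OTU ids on the
  index, sample ids on the columns.  Counts are non-negative integers;
  relative abundances are proportions whose columns each sum to 1.
* **Sample metadata**: DataFrame indexed by sample id with columns
  ``compartment`` (rhizosphere / endosphere), ``zone`` (one of the four
  bioclimatic zones), ``zone_rank`` (0 = humid … 3 = lower-arid, i.e.
  increasing aridity) and ``site_id``.
* **Taxonomy**: DataFrame indexed by OTU id with one column per rank
  (domain, phylum, class, order, family, genus); missing ranks are NaN.
* **Soil profiles**: DataFrame indexed by site id, one column per
  physicochemical parameter (pH, humidity, TP, TOC, TN, Fe, Ca, K, CEC).

The canonical on-disk format is plain TSV; BIOM 2.x (HDF5) tables are
supported read-only.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

logger = logging.getLogger("aridinet")

#: Bioclimatic zones ordered by increasing aridity (decreasing precipitation).
ZONES = ("humid", "semi_arid", "upper_arid", "lower_arid")
#: zone -> integer rank along the aridity gradient.
ZONE_RANK = {zone: rank for rank, zone in enumerate(ZONES)}
COMPARTMENTS = ("rhizosphere", "endosphere")
#: Taxonomic ranks, most to least inclusive.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")
#: Soil physicochemical parameters (units: pH unitless; humidity/TOC/TN %;
#: TP mg/l; Fe/Ca/K mg/kg; CEC mol/kg).
SOIL_COLUMNS = ("pH", "humidity", "TP", "TOC", "TN", "Fe", "Ca", "K", "CEC")

#: Proteobacterial classes reported individually when a phylum-level summary
#: splits Proteobacteria by class.
PROTEOBACTERIAL_CLASSES = frozenset(
    {
        "Alphaproteobacteria",
        "Betaproteobacteria",
        "Gammaproteobacteria",
        "Deltaproteobacteria",
    }
)

_GG_PREFIX = re.compile(r"^[a-zA-Z]__")
_ORGANELLE_TOKENS = ("chloroplast", "mitochondri")


class ParseError(ValueError):
    """Raised when an on-disk table violates its format contract."""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {what}: {dupes}")


def read_otu_table(path, format: str = "tsv") -> pd.DataFrame:
    """Read an OTU count table (OTU rows x sample columns).

    Parameters
    ----------
    path
        TSV file whose first column is ``otu_id``, or a BIOM 2.x HDF5 file.
    format
        ``"tsv"`` or ``"biom"``.

    Returns
    -------
    DataFrame of non-negative integer counts, OTU ids on the index.

    Raises
    ------
    ParseError
        On duplicate ids, or negative / non-integer cells (the error names
        the offending OTU row and sample column).
    """
    if format == "biom":
        return _read_biom(path)
    if format != "tsv":
        raise ValueError(f"unknown format: {format!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: malformed header (need otu_id + >=1 sample)")
    _check_unique(header[1:], "sample ids")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.columns = header[1:]
    df.index = df.index.astype(str)
    df.index.name = "otu_id"
    _check_unique(df.index, "otu ids")
    return _validate_counts(df)


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ParseError(
                f"non-numeric count at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        df, values = coerced, coerced.to_numpy()
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(f"missing count at OTU {df.index[i]!r}, sample {df.columns[j]!r}")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(
            f"negative count at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ParseError(
            f"non-integer count at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df.astype(np.int64)


def write_otu_table(counts: pd.DataFrame, path) -> None:
    """Write a count table as TSV (first column ``otu_id``)."""
    out = counts.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def _read_biom(path) -> pd.DataFrame:
    """Minimal BIOM 2.x (HDF5) reader: observation-major CSR matrix."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        otu_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(otu_ids), len(sample_ids)),
        )
    _check_unique(otu_ids, "otu ids")
    _check_unique(sample_ids, "sample ids")
    df = pd.DataFrame(mat.toarray(), index=pd.Index(otu_ids, name="otu_id"),
                      columns=sample_ids)
    return _validate_counts(df)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, compartment, zone, site_id).

    Adds a ``zone_rank`` column (humid=0 ... lower_arid=3).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "compartment", "zone", "site_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing columns: {sorted(missing)}")
    _check_unique(df["sample_id"], "sample ids")
    df = df.set_index("sample_id")
    return validate_metadata(df)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate compartment/zone enums and (re)derive ``zone_rank``."""
    bad_comp = set(meta["compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise ParseError(f"unknown compartment values: {sorted(bad_comp)}")
    bad_zone = set(meta["zone"]) - set(ZONES)
    if bad_zone:
        raise ParseError(f"unknown zone values: {sorted(bad_zone)}")
    meta = meta.copy()
    meta["zone_rank"] = meta["zone"].map(ZONE_RANK).astype(int)
    return meta


def parse_lineage(lineage: str) -> list:
    """Split a semicolon-delimited lineage, stripping Greengenes-style
    ``k__`` prefixes; returns up to six rank names (None where missing)."""
    parts = [p.strip() for p in str(lineage).split(";")]
    parts = [_GG_PREFIX.sub("", p) for p in parts]
    parts = [p if p else None for p in parts]
    parts = parts[: len(RANKS)]
    parts += [None] * (len(RANKS) - len(parts))
    return parts


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV: ``otu_id`` + semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError("taxonomy needs otu_id and lineage columns")
    otu_col, lineage_col = df.columns[:2]
    _check_unique(df[otu_col], "otu ids")
    rows = [parse_lineage(s) for s in df[lineage_col]]
    tax = pd.DataFrame(rows, index=df[otu_col].astype(str).values, columns=list(RANKS))
    tax.index.name = "otu_id"
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    lineages = tax[list(RANKS)].apply(
        lambda row: ";".join("" if pd.isna(v) else str(v) for v in row), axis=1
    )
    out = pd.DataFrame({"otu_id": tax.index, "lineage": lineages.values})
    out.to_csv(path, sep="\t", index=False)


def read_soil(path) -> pd.DataFrame:
    """Read a soil physicochemical TSV (site_id + the nine parameters)."""
    df = pd.read_csv(path, sep="\t")
    if "site_id" not in df.columns:
        raise ParseError("soil table missing site_id column")
    _check_unique(df["site_id"], "site ids")
    df = df.set_index("site_id")
    missing = set(SOIL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"soil table missing columns: {sorted(missing)}")
    return df[list(SOIL_COLUMNS)].astype(float)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def filter_organelle_otus(counts: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Drop OTUs whose lineage names a plant organelle.

    An OTU is removed when any rank of its lineage contains the token
    ``chloroplast`` or ``mitochondri`` (case-insensitive); reference
    taxonomies place chloroplasts at class and mitochondria at family level,
    so every rank is scanned.  OTUs absent from the taxonomy are kept.
    """
    tax = taxonomy.reindex(counts.index)
    joined = tax.astype("string").fillna("").agg(";".join, axis=1).str.lower()
    organelle = joined.str.contains("|".join(_ORGANELLE_TOKENS), regex=True)
    n_removed = int(organelle.sum())
    if n_removed:
        logger.info("filter_organelle_otus: removed %d organelle OTUs", n_removed)
    out = counts.loc[~organelle.values]
    if out.shape[0] == 0:
        logger.warning("filter_organelle_otus: all OTUs removed; table is empty")
    return out


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample proportions (columns sum to 1).

    Raises
    ------
    ValueError
        Naming the offending sample(s), if any column total is zero.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    return counts / totals


def aggregate_taxa(
    rel: pd.DataFrame,
    taxonomy: pd.DataFrame,
    level: str = "phylum",
    split_proteobacteria: bool = False,
) -> pd.DataFrame:
    """Sum relative abundances within taxa at the requested rank.

    With ``split_proteobacteria`` and ``level="phylum"``, OTUs of phylum
    Proteobacteria are reported by class (Alpha/Beta/Gamma/Delta, anything
    else as ``other-Proteobacteria``), the convention of phylum-level
    community summaries in this literature.  OTUs lacking the rank (or
    absent from the taxonomy) fall into an ``Unclassified`` bucket so that
    per-sample totals are conserved.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank: {level!r}")
    tax = taxonomy.reindex(rel.index)
    labels = tax[level].astype(object).where(tax[level].notna(), "Unclassified")
    if split_proteobacteria and level == "phylum":
        is_proteo = labels == "Proteobacteria"
        cls = tax["class"].astype(object)
        proteo_label = cls.where(cls.isin(PROTEOBACTERIAL_CLASSES), "other-Proteobacteria")
        labels = labels.mask(is_proteo, proteo_label)
    out = rel.groupby(labels.values).sum()
    out.index.name = level
    return out
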