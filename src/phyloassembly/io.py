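"""Readers, writers and validators for the pipeline's file formats.

Inputs are the standard amplicon-survey bundle: a rooted Newick phylogeny
whose tips are ASV identifiers, a sample x ASV count table (TSV), a
taxonomy table mapping ASVs to ranked lineage strings, and a sample
metadata table carrying the study design (floodplain, stream type,
region) plus covariates (chlorophyll a, bacterial abundance).  All
outputs are UTF-8 TSV with a header row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

#: canonical rank order for lineages (SILVA-style, domain to genus)
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: SILVA-style rank prefixes, aligned with RANKS
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")

#: lineage substrings marking non-bacterial reads to drop (case-insensitive)
DEFAULT_EXCLUDE_LINEAGES = ("archaea", "chloroplast", "mitochondria")


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass
class CommunityMatrix:
    """Sample x ASV abundance table.

    ``counts`` is a samples-by-ASVs DataFrame of non-negative integers.
    Relative abundances are derived on demand; rows of all-zero samples
    stay all-zero (the pairwise stages skip such samples).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise FormatError("duplicate sample or ASV identifiers in count table")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric cells in count table")
        if (arr < 0).any():
            r, col = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at sample {c.index[r]!r}, ASV {c.columns[col]!r}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def asvs(self) -> pd.Index:
        return self.counts.columns

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples stay zero."""
        totals = self.counts.sum(axis=1)
        empty = totals == 0
        if empty.any():
            logger.warning(
                "%d sample(s) have zero total count: %s",
                int(empty.sum()),
                list(self.counts.index[empty]),
            )
        safe = totals.replace(0, 1)
        return self.counts.div(safe, axis=0)

    def absolute(self, bacterial_abundance: pd.Series) -> pd.DataFrame:
        """Absolute abundances (cells/g): relative abundance scaled by the
        per-sample bacterial abundance from flow cytometry."""
        ba = bacterial_abundance.reindex(self.samples)
        return self.relative().mul(ba, axis=0)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0


@dataclass
class AlignedBundle:
    """Mutually consistent tree / counts / taxonomy / metadata."""

    tree: skbio.TreeNode
    counts: CommunityMatrix
    taxonomy: pd.DataFrame | None
    metadata: pd.DataFrame | None
    dropped: dict = field(default_factory=dict)


def read_tree(path) -> skbio.TreeNode:
    """Read and validate a rooted Newick tree with branch lengths."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"unreadable Newick file {path}: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: skbio.TreeNode) -> skbio.TreeNode:
    tips = [t.name for t in tree.tips()]
    if not tips:
        raise FormatError("tree has no tips")
    if len(set(tips)) != len(tips):
        seen, dups = set(), set()
        for t in tips:
            (dups if t in seen else seen).add(t)
        raise FormatError(f"duplicate tip labels: {sorted(dups)}")
    if any(t is None for t in tips):
        raise FormatError("unnamed tip in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(f"missing branch length above node {node.name!r}")
        if node.length < 0:
            raise FormatError(f"negative branch length above node {node.name!r}")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_counts(path, orientation: str = "asv_rows") -> CommunityMatrix:
    """Read a TSV count table.

    ``orientation`` declares the layout: ``"asv_rows"`` (QIIME2 export
    convention, rows are ASVs and columns samples) or ``"sample_rows"``.
    """
    if orientation not in ("asv_rows", "sample_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "asv_rows":
        df = df.T
    bad = df.map(lambda v: isinstance(v, str))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"missing cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        warnings.warn("non-integer counts rounded to nearest integer")
    df = df.round().astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "sample_id"
    df.columns.name = "asv_id"
    return CommunityMatrix(df)


def write_counts(cm: CommunityMatrix, path, orientation: str = "asv_rows") -> None:
    df = cm.counts.T if orientation == "asv_rows" else cm.counts
    df.to_csv(path, sep="\t")


def parse_lineage(lineage: str) -> dict:
    """Parse a lineage string into the canonical ranks.

    Accepts both the prefixed SILVA dialect (``d__Bacteria; p__X``) and
    bare names (``Bacteria;X``); empty ranks map to missing.
    """
    out = {r: None for r in RANKS}
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return out
    parts = [p.strip() for p in str(lineage).split(";")]
    for i, part in enumerate(parts[: len(RANKS)]):
        name = part
        for j, pref in enumerate(_RANK_PREFIXES):
            if part.startswith(pref):
                name = part[len(pref):].strip()
                i = j
                break
        out[RANKS[i]] = name or None
    return out


def read_taxonomy(path) -> pd.DataFrame:
    """Read a two-column TSV (asv_id <TAB> lineage) into an ASV x rank table."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise FormatError("taxonomy table needs asv_id and lineage columns")
    asv_col, lin_col = raw.columns[:2]
    if raw[asv_col].duplicated().any():
        dups = raw[asv_col][raw[asv_col].duplicated()].tolist()
        raise FormatError(f"duplicate ASV ids in taxonomy: {dups}")
    rows = {a: parse_lineage(l) for a, l in zip(raw[asv_col], raw[lin_col])}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "asv_id"
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    lineages = taxonomy.apply(
        lambda row: ";".join(
            f"{pref}{row[rank]}" if pd.notna(row[rank]) and row[rank] else pref
            for pref, rank in zip(_RANK_PREFIXES, RANKS)
        ),
        axis=1,
    )
    out = pd.DataFrame({"asv_id": taxonomy.index, "lineage": lineages.to_numpy()})
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path, categorical_levels: dict | None = None) -> pd.DataFrame:
    """Read the sample metadata TSV (first column = sample id).

    ``categorical_levels`` maps column name -> allowed levels and is
    validated when given, e.g. ``{"stream_type": ("GFS", "TRIB")}``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    if categorical_levels:
        for col, levels in categorical_levels.items():
            if col not in df.columns:
                continue
            bad = set(df[col].dropna()) - set(levels)
            if bad:
                raise FormatError(f"invalid levels in {col!r}: {sorted(bad)}")
    for col in ("chlorophyll_a", "bacterial_abundance"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise FormatError(f"negative values in {col!r}")
            df[col] = vals
    return df


def align_inputs(
    tree: skbio.TreeNode,
    counts: CommunityMatrix,
    taxonomy: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> AlignedBundle:
    """Restrict all inputs to their common identifiers.

    ASVs are restricted to the intersection of tree tips and count
    columns (the tree is pruned accordingly); samples to the
    intersection of counts and metadata.  All drops are reported.
    """
    tip_names = {t.name for t in tree.tips()}
    asvs = [a for a in counts.asvs if a in tip_names]
    if not asvs:
        raise FormatError("no ASV shared between tree and count table")
    dropped = {
        "asvs_not_in_tree": [a for a in counts.asvs if a not in tip_names],
        "tips_not_in_counts": sorted(tip_names - set(counts.asvs)),
        "samples_not_in_metadata": [],
        "metadata_not_in_counts": [],
    }
    samples = list(counts.samples)
    meta = metadata
    if metadata is not None:
        samples = [s for s in counts.samples if s in metadata.index]
        if not samples:
            raise FormatError("no sample shared between counts and metadata")
        dropped["samples_not_in_metadata"] = [
            s for s in counts.samples if s not in metadata.index
        ]
        dropped["metadata_not_in_counts"] = [
            s for s in metadata.index if s not in set(counts.samples)
        ]
        meta = metadata.loc[samples]
    pruned = tree.shear(asvs) if dropped["tips_not_in_counts"] else tree
    tax = taxonomy.reindex(asvs) if taxonomy is not None else None
    sub = CommunityMatrix(counts.counts.loc[samples, asvs])
    for key, vals in dropped.items():
        if vals:
            logger.info("align_inputs dropped %d %s: %s", len(vals), key, vals[:10])
    return AlignedBundle(pruned, sub, tax, meta, dropped)


def filter_asvs(
    counts: CommunityMatrix,
    floodplain: pd.Series,
    taxonomy: pd.DataFrame | None = None,
    exclude_lineages: tuple = DEFAULT_EXCLUDE_LINEAGES,
) -> CommunityMatrix:
    """Apply the study's ASV filter.

    Discards singletons (total count 1 across all samples), ASVs present
    in fewer than two samples of every floodplain, and — when taxonomy is
    given — lineages matching any of ``exclude_lineages`` (archaea,
    chloroplasts, mitochondria by default), case-insensitively.
    """
    c = counts.counts
    fp = floodplain.reindex(c.index)
    total = c.sum(axis=0)
    keep = total != 1
    # presence in >= 2 samples within at least one floodplain
    pres = c > 0
    enough = pd.Series(False, index=c.columns)
    for _, rows in pres.groupby(fp, observed=True):
        enough |= rows.sum(axis=0) >= 2
    keep &= enough
    if taxonomy is not None and exclude_lineages:
        lineage_str = (
            taxonomy.reindex(c.columns)
            .fillna("")
            .agg(";".join, axis=1)
            .str.lower()
        )
        nonbact = lineage_str.apply(
            lambda s: any(x.lower() in s for x in exclude_lineages)
        )
        keep &= ~nonbact
    removed = [a for a in c.columns if not keep[a]]
    if removed:
        logger.info("filter_asvs removed %d ASVs", len(removed))
    return CommunityMatrix(c.loc[:, keep])


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
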