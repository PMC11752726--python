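"""Sample-table and tree I/O plus the standard preprocessing filters.

The central container is :class:`SampleTable`: a taxa x samples integer
count matrix with per-taxon taxonomy strings and per-sample metadata
(species, site, role, body site).  Readers accept tab-delimited count
tables (``#OTU ID``-style headers included) and JSON-BIOM v1.0; trees are
Newick via scikit-bio.

Preprocessing follows the standard 16S amplicon workflow for this kind of
study: drop taxa that are not Bacteria/Archaea, drop shallow samples
(< 10,000 reads by default), rarefy everything to a common depth, and
optionally pool amplicon sequence variants (ASVs) to a taxonomic rank.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

ROLES = ("hybrid", "maternal", "paternal")
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = {"d": 0, "k": 0, "p": 1, "c": 2, "o": 3, "f": 4, "g": 5, "s": 6}


@dataclass
class SampleTable:
    """Taxa x samples count matrix with taxonomy and sample metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Nonnegative integer counts, index = taxon ids, columns = sample ids.
    taxonomy : dict
        Taxon id -> semicolon-separated lineage string (may be empty).
    metadata : pandas.DataFrame
        Indexed by sample id with columns ``species``, ``site``, ``role``,
        ``body_site``.  Every count column must appear here.
    """

    counts: pd.DataFrame
    taxonomy: dict = field(default_factory=dict)
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValueError(f"duplicate taxon id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if (c.values < 0).any():
            bad = c.index[(c.values < 0).any(axis=1)][0]
            raise ValueError(f"negative count in taxon {bad!r}")
        if self.metadata is not None:
            missing = set(c.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def taxa(self) -> list:
        return list(self.counts.index)

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def incidence(self) -> pd.DataFrame:
        """Boolean presence/absence view."""
        return self.counts > 0

    def copy(self) -> "SampleTable":
        return SampleTable(
            self.counts.copy(),
            dict(self.taxonomy),
            None if self.metadata is None else self.metadata.copy(),
        )

    def subset_samples(self, sample_ids) -> "SampleTable":
        sample_ids = list(sample_ids)
        md = None if self.metadata is None else self.metadata.loc[sample_ids]
        return SampleTable(self.counts[sample_ids], dict(self.taxonomy), md)

    def samples_where(self, **conditions) -> list:
        """Sample ids whose metadata match all keyword conditions."""
        if self.metadata is None:
            raise ValueError("table has no metadata")
        mask = pd.Series(True, index=self.metadata.index)
        for key, value in conditions.items():
            mask &= self.metadata[key] == value
        return list(self.metadata.index[mask])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.index.name = "taxon_id"
    try:
        df = df.astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer counts ({exc})") from exc
    return df


def read_metadata_tsv(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    md.index = md.index.astype(str)
    md.index.name = "sample_id"
    return md


def read_biom_json(path) -> SampleTable:
    """Read a JSON-BIOM v1.0 table (dense or sparse)."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = doc["rows"]
    cols = doc["columns"]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    data = doc["data"]
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(data)
    else:
        for r, c, v in data:
            mat[int(r), int(c)] = v
    taxon_ids = [str(r["id"]) for r in rows]
    sample_ids = [str(c["id"]) for c in cols]
    taxonomy = {}
    for r in rows:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy", "")
        if isinstance(tax, (list, tuple)):
            tax = ";".join(str(t) for t in tax)
        taxonomy[str(r["id"])] = tax
    counts = pd.DataFrame(mat, index=taxon_ids, columns=sample_ids)
    counts.index.name = "taxon_id"
    return SampleTable(counts, taxonomy)


def read_table(path, taxonomy=None, metadata=None) -> SampleTable:
    """Read a count table from TSV or JSON-BIOM, with optional sidecars.

    `taxonomy` may be a path to a two-column TSV (taxon id, lineage) or a
    dict; `metadata` a path to a metadata TSV or a DataFrame.
    """
    path = str(path)
    if path.endswith(".biom") or path.endswith(".json"):
        table = read_biom_json(path)
    else:
        table = SampleTable(read_counts_tsv(path))
    if taxonomy is not None:
        if isinstance(taxonomy, dict):
            table.taxonomy = dict(taxonomy)
        else:
            tx = pd.read_csv(taxonomy, sep="\t", index_col=0, dtype=str)
            table.taxonomy = tx.iloc[:, 0].fillna("").to_dict()
    if metadata is not None:
        md = metadata if isinstance(metadata, pd.DataFrame) else read_metadata_tsv(metadata)
        table = SampleTable(table.counts, table.taxonomy, md)
    return table


def write_counts_tsv(table: SampleTable, path, header="#OTU ID"):
    out = table.counts.copy()
    out.index.name = header
    out.to_csv(path, sep="\t")


def write_metadata_tsv(table: SampleTable, path):
    if table.metadata is None:
        raise ValueError("table has no metadata")
    table.metadata.to_csv(path, sep="\t")


def write_taxonomy_tsv(table: SampleTable, path):
    pd.Series(table.taxonomy, name="lineage").rename_axis("taxon_id").to_csv(
        path, sep="\t"
    )


def write_biom_json(table: SampleTable, path, generated_by="hybridbiome"):
    counts = table.counts
    data = []
    arr = counts.values
    for r, c in zip(*np.nonzero(arr)):
        data.append([int(r), int(c), int(arr[r, c])])
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": generated_by,
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(arr.shape),
        "rows": [
            {"id": t, "metadata": {"taxonomy": table.taxonomy.get(t, "")}}
            for t in counts.index
        ],
        "columns": [{"id": s, "metadata": None} for s in counts.columns],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_tree(path) -> TreeNode:
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValueError(f"unparseable newick in {path}: {exc}") from exc
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate tip labels")
    return tree


def write_tree(tree: TreeNode, path):
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# filters and transforms
# ---------------------------------------------------------------------------

def _top_rank(lineage: str) -> str:
    first = lineage.split(";")[0].strip()
    if "__" in first:
        first = first.split("__", 1)[1]
    return first.strip()


def filter_domain(table: SampleTable) -> SampleTable:
    """Keep only taxa identified as Bacteria or Archaea.

    Taxa without a taxonomy string are treated as unidentified and removed
    (with a warning), mirroring the removal of likely artifacts and
    non-microbial contamination.
    """
    keep = []
    n_missing = 0
    for taxon in table.taxa:
        lineage = table.taxonomy.get(taxon, "")
        if not lineage:
            n_missing += 1
            continue
        if _top_rank(lineage).lower() in ("bacteria", "archaea"):
            keep.append(taxon)
    if n_missing:
        warnings.warn(
            f"{n_missing} taxa had no taxonomy string and were removed",
            stacklevel=2,
        )
    removed = len(table.taxa) - len(keep)
    logger.info("filter_domain removed %d of %d taxa", removed, len(table.taxa))
    counts = table.counts.loc[keep]
    taxonomy = {t: table.taxonomy.get(t, "") for t in keep}
    return SampleTable(counts, taxonomy, table.metadata)


def filter_depth(table: SampleTable, min_reads: int = 10000) -> SampleTable:
    """Remove samples with read depth lower than `min_reads`.

    The threshold is strict ("lower than"): a sample with exactly
    `min_reads` reads is retained.
    """
    sums = table.sample_sums()
    keep = sums.index[sums >= min_reads]
    dropped = sorted(set(table.samples) - set(keep))
    if dropped:
        logger.info("filter_depth removed samples: %s", dropped)
    md = None if table.metadata is None else table.metadata.loc[keep]
    return SampleTable(table.counts[keep], dict(table.taxonomy), md)


def rarefy(table: SampleTable, depth: int, seed: int) -> SampleTable:
    """Subsample every sample to exactly `depth` reads without replacement."""
    sums = table.sample_sums()
    too_small = sums.index[sums < depth]
    if len(too_small):
        raise ValueError(
            f"rarefaction depth {depth} exceeds read depth of sample(s) "
            f"{list(too_small)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.values)
    for j, sample in enumerate(table.counts.columns):
        col = table.counts[sample].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return SampleTable(counts, dict(table.taxonomy), table.metadata)


def parse_lineage(lineage: str) -> dict:
    """Split a semicolon lineage into rank -> label, honouring g__-style
    prefixes when present, else assuming domain-to-species order."""
    out = {}
    fields = [f.strip() for f in lineage.split(";")] if lineage else []
    for i, fld in enumerate(fields):
        if not fld:
            continue
        if "__" in fld:
            prefix, label = fld.split("__", 1)
            idx = _RANK_PREFIXES.get(prefix.strip().lower())
            if idx is None or not label.strip():
                continue
            out[RANKS[idx]] = label.strip()
        elif i < len(RANKS):
            out[RANKS[i]] = fld
    return out


def pool_to_rank(table: SampleTable, rank: str = "genus") -> SampleTable:
    """Sum counts over taxa sharing the same label at `rank`.

    Taxa without a label at that rank are pooled into a single
    ``unclassified@<rank>`` bucket.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    bucket = f"unclassified@{rank}"
    labels = []
    for taxon in table.taxa:
        label = parse_lineage(table.taxonomy.get(taxon, "")).get(rank)
        labels.append(label if label else bucket)
    grouped = table.counts.groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    taxonomy = {label: label if label != bucket else "" for label in grouped.index}
    return SampleTable(grouped, taxonomy, table.metadata)


def to_relative(table: SampleTable) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1)."""
    sums = table.sample_sums()
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"cannot normalise zero-sum sample(s) {list(zero)}")
    return table.counts / sums


def prune_tree_to_table(tree: TreeNode, table: SampleTable) -> TreeNode:
    """Prune tree tips absent from the table; error if the table has taxa
    missing from the tree (phylogenetic metrics would be undefined)."""
    tips = {t.name for t in tree.tips()}
    missing = set(table.taxa) - tips
    if missing:
        raise ValueError(
            f"table taxa absent from the tree: {sorted(missing)[:5]}"
            f"{'...' if len(missing) > 5 else ''}"
        )
    extra = tips - set(table.taxa)
    if not extra:
        return tree
    pruned = tree.shear(set(table.taxa))
    pruned.prune()
    return pruned
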