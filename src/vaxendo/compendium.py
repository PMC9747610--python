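"""Core data structures: expression compendium, sample metadata and gene sets.

The compendium bundles a log2 expression matrix (genes x samples), a sample
metadata table and (optionally) a gene-set collection. All downstream stages
consume this object. File formats are plain TSV and the Broad/MSigDB GMT
format; gene identifiers are symbols matched case-sensitively.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven cell-subset / canonical-pathway supersets used to group
#: hallmark and blood-transcriptional-module gene sets.
SUPERSET_LABELS = (
    "T_cells",
    "NK_cells",
    "B_cells",
    "monocytes_DCs",
    "inflammation",
    "E2F_MYC",
    "ISGs",
)

#: Required columns of the sample-metadata table.
META_COLUMNS = (
    "sample_id",
    "participant_id",
    "study_id",
    "platform",
    "sample_type",
    "vaccine",
    "day",
)

#: Optional metadata columns carried through when present.
OPTIONAL_META_COLUMNS = ("age_years", "sex", "ethnicity")

#: Days treated as pre-vaccination throughout the pipeline.
PREVACCINATION_DAYS = (-7, 0)

#: Tokens interpreted as missing in TSV files.
NA_TOKENS = ("NA", "")


class CompendiumError(ValueError):
    """Raised when an input file or compendium violates a structural invariant."""


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional superset (cell subset / pathway) map.

    Parameters
    ----------
    sets
        Mapping from set name to an ordered list of unique gene symbols.
    superset_map
        Optional mapping from set name to one of the seven superset labels.
    """

    sets: dict[str, list[str]]
    superset_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise CompendiumError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise CompendiumError(f"gene set {name!r} contains duplicate genes")
        bad = {v for v in self.superset_map.values()} - set(SUPERSET_LABELS)
        if bad:
            raise CompendiumError(
                f"superset_map values {sorted(bad)} not in {SUPERSET_LABELS}"
            )

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclass
class Compendium:
    """A validated expression compendium.

    Attributes
    ----------
    expression
        Log2 expression values, genes (rows, indexed by symbol) x samples
        (columns, indexed by sample id). Finite after loading.
    samples
        Metadata table indexed by ``sample_id`` with the columns of
        :data:`META_COLUMNS` (minus the index) and any optional columns.
    gene_sets
        Optional :class:`GeneSetCollection`; required only by the enrichment
        stages.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    gene_sets: GeneSetCollection | None = None

    def __post_init__(self) -> None:
        expr, meta = self.expression, self.samples
        if expr.index.has_duplicates:
            dups = expr.index[expr.index.duplicated()].unique().tolist()
            raise CompendiumError(f"duplicate gene symbols: {dups[:10]}")
        if any(g == "" or pd.isna(g) for g in expr.index):
            raise CompendiumError("empty or missing gene symbol in expression index")
        extra_expr = expr.columns.difference(meta.index)
        extra_meta = meta.index.difference(expr.columns)
        if len(extra_expr) or len(extra_meta):
            raise CompendiumError(
                "sample mismatch between expression and metadata; "
                f"expression-only={list(extra_expr)[:10]}, "
                f"metadata-only={list(extra_meta)[:10]}"
            )
        if not np.isfinite(expr.to_numpy(dtype=float)).all():
            bad = np.argwhere(~np.isfinite(expr.to_numpy(dtype=float)))
            g, s = bad[0]
            raise CompendiumError(
                f"non-finite expression value at gene {expr.index[g]!r}, "
                f"sample {expr.columns[s]!r} ({len(bad)} total)"
            )
        missing_cols = [c for c in META_COLUMNS if c != "sample_id" and c not in meta.columns]
        if missing_cols:
            raise CompendiumError(f"metadata missing required columns: {missing_cols}")
        # align metadata row order to expression column order
        self.samples = meta.loc[expr.columns]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def prevaccination_mask(self) -> pd.Series:
        """Boolean mask (indexed by sample id) of pre-vaccination samples (day -7/0)."""
        return self.samples["day"].isin(PREVACCINATION_DAYS)

    def subset_samples(self, sample_ids) -> "Compendium":
        """Return a compendium restricted to the given sample ids (order preserved)."""
        ids = list(sample_ids)
        return Compendium(
            expression=self.expression[ids],
            samples=self.samples.loc[ids],
            gene_sets=self.gene_sets,
        )


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file (tab-separated: name, description, genes...).

    Duplicate genes within a line are deduplicated preserving first occurrence;
    the description field is discarded. Raises :class:`CompendiumError` on a
    malformed line (fewer than 3 fields) or a duplicate set name.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CompendiumError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise CompendiumError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g != ""))
            if not genes:
                raise CompendiumError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    """Write a collection to GMT. The description field is written as ``na``."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_superset_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (set name, superset label) into a superset map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "superset"], dtype=str)
    return dict(zip(df["set"], df["superset"]))


def load_compendium(
    expr_path: str | os.PathLike,
    meta_path: str | os.PathLike,
    gene_sets: GeneSetCollection | None = None,
    missing_policy: str = "reject",
) -> Compendium:
    """Load and validate a compendium from an expression TSV and a metadata TSV.

    The expression TSV has a header row of sample ids and a first column of
    gene symbols; the metadata TSV has one row per sample id. ``missing_policy``
    is ``"reject"`` (default: any NA expression cell is an error) or
    ``"impute"`` (per-gene median imputation).
    """
    expr = pd.read_csv(
        expr_path, sep="\t", index_col=0, na_values=list(NA_TOKENS), keep_default_na=False
    )
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise CompendiumError(f"non-numeric expression cell: {exc}") from exc

    if expr.isna().any().any():
        if missing_policy == "reject":
            bad = np.argwhere(expr.isna().to_numpy())
            coords = [(expr.index[g], expr.columns[s]) for g, s in bad[:10]]
            raise CompendiumError(
                f"missing expression values (policy=reject): first offenders "
                f"(gene, sample) = {coords}"
            )
        elif missing_policy == "impute":
            medians = expr.median(axis=1)
            expr = expr.apply(lambda row: row.fillna(medians[row.name]), axis=1)
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")

    meta = pd.read_csv(
        meta_path, sep="\t", dtype=str, na_values=list(NA_TOKENS), keep_default_na=False
    )
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise CompendiumError(f"metadata missing required columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise CompendiumError(f"duplicate sample ids in metadata: {dups[:10]}")
    meta = meta.set_index("sample_id")
    meta["day"] = meta["day"].astype(int)
    if "age_years" in meta.columns:
        meta["age_years"] = pd.to_numeric(meta["age_years"], errors="coerce")
    return Compendium(expression=expr, samples=meta, gene_sets=gene_sets)


def write_tables(compendium: Compendium, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write expression/metadata (and gene sets when present) TSVs to ``out_dir``.

    Round-trip guarantee: reloading the written files reproduces expression
    values to <=1e-9 absolute difference and identical metadata.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir!r} is not writable")
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
    }
    compendium.expression.to_csv(
        paths["expression"], sep="\t", index_label="gene", float_format="%.12g"
    )
    meta = compendium.samples.reset_index()
    if meta.columns[0] != "sample_id":
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta.to_csv(paths["metadata"], sep="\t", index=False, na_rep="NA")
    if compendium.gene_sets is not None:
        paths["gene_sets"] = os.path.join(out_dir, "gene_sets.gmt")
        write_gmt(compendium.gene_sets, paths["gene_sets"])
        if compendium.gene_sets.superset_map:
            paths["supersets"] = os.path.join(out_dir, "supersets.tsv")
            pd.Series(compendium.gene_sets.superset_map).rename_axis("set").rename(
                "superset"
            ).to_csv(paths["supersets"], sep="\t", header=False)
    return paths
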