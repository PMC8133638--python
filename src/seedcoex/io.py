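"""Reading, validation and filtering of expression matrices and auxiliary tables.

The expression unit is FPKM-like: nonnegative, continuous, heavily
right-skewed. All downstream correlation work assumes the matrix produced
here has unique gene and sample identifiers, finite nonnegative values and
at least two samples.

File dialects
-------------
* Expression matrix: TSV (or CSV) with header ``gene_id<TAB>sample1...``;
  first column gene identifiers, remaining columns one per sample.
* Seed list: one gene id per line, ``#`` starts a comment. An optional
  ``!exclude`` directive line marks genes that are never used as seeds but
  remain rankable targets (accessory reductases such as QR2/NDC1 analogs).
* GO map: two-column TSV ``gene_id<TAB>term_id`` (repeated gene rows merge).
* Ortholog table: long 3-column TSV ``species<TAB>gene<TAB>orthogroup`` or
  the OrthoFinder ``Orthogroups.tsv`` wide dialect (auto-detected by header).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("seedcoex")

__all__ = [
    "ExpressionMatrix",
    "SeedGeneSet",
    "GOAnnotationMap",
    "OrthologTable",
    "read_expression",
    "write_expression",
    "filter_expressed",
    "drop_constant_genes",
    "read_seed_list",
    "write_seed_list",
    "read_go_map",
    "write_go_map",
    "read_ortholog_table",
    "write_ortholog_table",
]


class ExpressionMatrix:
    """Genes x samples matrix of nonnegative expression values.

    Thin validated wrapper around a :class:`pandas.DataFrame` whose index
    holds gene ids and whose columns hold sample ids.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if data.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        values = data.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value at gene {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        neg = values < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValueError(
                f"negative value {values[r, c]} at gene {data.index[r]!r}, "
                f"sample {data.columns[c]!r}"
            )
        self._df = data.astype(float)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def n_genes(self) -> int:
        return self._df.shape[0]

    @property
    def n_samples(self) -> int:
        return self._df.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._df.index

    def row(self, gene_id: str) -> np.ndarray:
        return self._df.loc[gene_id].to_numpy()

    def subset(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self._df.index]
        if missing:
            raise KeyError(f"genes missing from matrix: {missing}")
        return ExpressionMatrix(self._df.loc[list(gene_ids)])

    def log2_transform(self) -> "ExpressionMatrix":
        """Return log2(x + 1)-transformed copy (optional pre-transform)."""
        return ExpressionMatrix(np.log2(self._df + 1.0))

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass
class SeedGeneSet:
    """Ordered seed (pathway) gene ids plus genes excluded from seeding.

    Excluded genes (accessory reductases in the phylloquinone use case) are
    never used as seeds but stay eligible as neighbors of other seeds.
    """

    seeds: list[str]
    excluded_as_seed: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("duplicate seed ids")
        overlap = set(self.seeds) & set(self.excluded_as_seed)
        if overlap:
            raise ValueError(f"genes both seed and excluded: {sorted(overlap)}")

    def reconcile(self, matrix: ExpressionMatrix, permissive: bool = False) -> "SeedGeneSet":
        """Check seeds against a (filtered) matrix.

        Missing seeds abort by default — a seed network without its seeds is
        meaningless. With ``permissive=True`` they are dropped with a warning.
        """
        missing = [s for s in self.seeds if s not in matrix]
        if missing:
            if not permissive:
                raise ValueError(
                    f"seed genes absent from the filtered matrix: {missing}"
                )
            warnings.warn(f"WARN seeds_missing dropped={missing}", stacklevel=2)
            logger.warning("WARN seeds_missing dropped=%s", ",".join(missing))
        kept = [s for s in self.seeds if s in matrix]
        if not kept:
            raise ValueError("no seed genes remain after reconciliation")
        excl = [g for g in self.excluded_as_seed if g in matrix]
        return SeedGeneSet(kept, excl)


@dataclass
class GOAnnotationMap:
    """gene id -> set of term ids; optional term labels."""

    gene_to_terms: dict[str, set[str]]
    term_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        empty = [g for g, t in self.gene_to_terms.items() if not t]
        if empty:
            raise ValueError(f"empty term sets for genes: {empty[:5]}")

    @property
    def annotated_genes(self) -> set[str]:
        """Background universe: all annotated genes."""
        return set(self.gene_to_terms)

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())

    def genes_with(self, term: str) -> set[str]:
        return {g for g, t in self.gene_to_terms.items() if term in t}

    def restrict(self, genes) -> "GOAnnotationMap":
        sub = {g: set(t) for g, t in self.gene_to_terms.items() if g in set(genes)}
        return GOAnnotationMap(sub, dict(self.term_labels))


class OrthologTable:
    """Long table of (species, gene, orthogroup) rows.

    A (species, gene) pair maps to exactly one orthogroup.
    """

    def __init__(self, rows: pd.DataFrame):
        expected = ["species", "gene", "orthogroup"]
        if list(rows.columns) != expected:
            rows = rows.copy()
            rows.columns = expected
        dup = rows.duplicated(subset=["species", "gene"], keep=False)
        if dup.any():
            conflicting = rows.loc[dup].groupby(["species", "gene"])["orthogroup"].nunique()
            bad = conflicting[conflicting > 1]
            if len(bad):
                sp, g = bad.index[0]
                raise ValueError(
                    f"gene {g!r} of species {sp!r} assigned to multiple orthogroups"
                )
            rows = rows.drop_duplicates()
        self.rows = rows.reset_index(drop=True)

    def group_of(self, species: str, gene: str) -> str | None:
        hit = self.rows[(self.rows.species == species) & (self.rows.gene == gene)]
        return None if hit.empty else hit.orthogroup.iloc[0]

    def species_map(self, species: str) -> dict[str, str]:
        sub = self.rows[self.rows.species == species]
        return dict(zip(sub.gene, sub.orthogroup))

    def members(self, orthogroup: str, species: str) -> list[str]:
        sub = self.rows[(self.rows.orthogroup == orthogroup) & (self.rows.species == species)]
        return sorted(sub.gene)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OrthologTable):
            return NotImplemented
        a = self.rows.sort_values(["species", "gene"]).reset_index(drop=True)
        b = other.rows.sort_values(["species", "gene"]).reset_index(drop=True)
        return a.equals(b)

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV.

    First column gene ids, header row sample ids. Non-numeric, NaN or
    negative cells raise with row/column coordinates.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        numeric = df.apply(pd.to_numeric, errors="coerce")
    except Exception as exc:  # pragma: no cover - pandas raises above instead
        raise ValueError(f"unparsable expression table: {exc}") from exc
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric value {df.iloc[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    matrix.df.to_csv(path, sep=sep, index_label="gene_id")


def filter_expressed(
    matrix: ExpressionMatrix, min_value: float = 2.0, min_samples: int = 2
) -> ExpressionMatrix:
    """Keep genes expressed at >= ``min_value`` in >= ``min_samples`` samples.

    Both thresholds are inclusive. Defaults reproduce the standard
    "FPKM >= 2 in at least two samples" transcriptome filter. Sample set and
    gene order are preserved; an empty result is allowed (with a warning).
    """
    n_pass = (matrix.values >= min_value).sum(axis=1)
    keep = n_pass >= min_samples
    if not keep.any():
        warnings.warn("WARN filter_empty no genes pass the expression filter", stacklevel=2)
    out = matrix.df.loc[keep]
    logger.info("INFO filter_expressed kept=%d of=%d", int(keep.sum()), matrix.n_genes)
    return ExpressionMatrix(out)


def drop_constant_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop zero-variance genes (Gini correlation is undefined for them)."""
    values = matrix.values
    constant = np.all(values == values[:, [0]], axis=1) if values.size else np.array([], bool)
    n = int(constant.sum())
    if n:
        logger.warning("WARN constant_genes_dropped count=%d", n)
    return ExpressionMatrix(matrix.df.loc[~constant]) if n else matrix


def read_seed_list(path) -> SeedGeneSet:
    """Read a seed list: one id per line, ``#`` comments, ``!exclude`` directive."""
    seeds: list[str] = []
    excluded: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("!exclude"):
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed !exclude directive")
                excluded.extend(parts[1].split())
            elif len(line.split()) != 1:
                raise ValueError(f"{path}:{lineno}: expected one gene id per line")
            else:
                seeds.append(line)
    return SeedGeneSet(seeds, excluded)


def write_seed_list(seed_set: SeedGeneSet, path) -> None:
    with open(path, "w") as fh:
        for s in seed_set.seeds:
            fh.write(s + "\n")
        if seed_set.excluded_as_seed:
            fh.write("!exclude " + " ".join(seed_set.excluded_as_seed) + "\n")


def read_go_map(path) -> GOAnnotationMap:
    """Read a 2-column gene->term TSV (3rd column, if any, is the term label)."""
    gene_to_terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed GO map row {line!r}")
            gene, term = parts[0].strip(), parts[1].strip()
            gene_to_terms.setdefault(gene, set()).add(term)
            if len(parts) >= 3 and parts[2].strip():
                labels[term] = parts[2].strip()
    return GOAnnotationMap(gene_to_terms, labels)


def write_go_map(annotations: GOAnnotationMap, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations.gene_to_terms):
            for term in sorted(annotations.gene_to_terms[gene]):
                label = annotations.term_labels.get(term, "")
                fh.write(f"{gene}\t{term}\t{label}\n" if label else f"{gene}\t{term}\n")


def _parse_orthofinder_wide(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        species = header[1:]
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            og = parts[0].strip()
            if not og:
                raise ValueError(f"{path}:{lineno}: missing orthogroup id")
            cells = parts[1:]
            for sp, cell in zip(species, cells):
                for gene in (g.strip() for g in cell.split(",")):
                    if gene:
                        records.append((sp, gene, og))
    return pd.DataFrame(records, columns=["species", "gene", "orthogroup"])


def read_ortholog_table(path) -> OrthologTable:
    """Read an ortholog table; long 3-column or OrthoFinder wide dialect.

    Auto-detected by header: a first header field of ``species`` means the
    long dialect, anything else (e.g. ``Orthogroup``) the wide one.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header and header[0].lower() == "species":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.isna().any().any():
            row = int(np.argwhere(df.isna().any(axis=1).to_numpy())[0]) + 2
            raise ValueError(f"{path}:{row}: malformed ortholog row")
        df.columns = ["species", "gene", "orthogroup"]
        return OrthologTable(df)
    return OrthologTable(_parse_orthofinder_wide(path))


def write_ortholog_table(table: OrthologTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
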