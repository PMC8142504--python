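"""Readers, writers and shared domain containers.

All tabular formats are plain TSV (UTF-8, header row); gene sets are GMT;
somatic mutations are MAF (TCGA column names). Every reader validates the
container invariants at load time, and every writer/reader pair round-trips
losslessly on the retained fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION_UNITS = ("raw_counts", "log2cpm", "intensity")

#: MAF variant classifications accepted by :func:`read_maf`.
VARIANT_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Silent",
        "Splice_Site",
        "Splice_Region",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Translation_Start_Site",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "RNA",
        "IGR",
    }
)

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class ExpressionMatrix:
    """Gene x sample nonnegative expression values with a unit tag.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample ids
    as columns. ``unit`` is one of ``raw_counts`` (integer counts),
    ``log2cpm`` or ``intensity``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}")
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        if v.isna().any().any():
            raise FormatError("missing values in expression matrix")
        if self.unit == "raw_counts":
            arr = v.to_numpy()
            if (arr < 0).any():
                g, s = np.argwhere(arr < 0)[0]
                raise FormatError(
                    f"negative count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("raw_counts matrix contains non-integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.unit)

    def restrict_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.unit)


@dataclass
class GeneSetCollection:
    """Named gene lists (GMT-backed)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                self.sets[name] = list(dict.fromkeys(genes))

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints (times in months) and covariates."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        if "os_time" not in t.columns or "os_event" not in t.columns:
            raise FormatError("clinical table requires os_time and os_event columns")
        for col in ("os_time", "pfs_time"):
            if col in t.columns:
                vals = t[col].dropna()
                if (vals < 0).any():
                    raise FormatError(f"negative {col}")
        for col in ("os_event", "pfs_event"):
            if col in t.columns:
                vals = t[col].dropna()
                if not vals.isin([0, 1]).all():
                    raise FormatError(f"{col} must be binary 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def survival(self, endpoint: str = "os") -> pd.DataFrame:
        """Time/event for one endpoint, samples with missing values dropped."""
        cols = [f"{endpoint}_time", f"{endpoint}_event"]
        if not all(c in self.table.columns for c in cols):
            raise KeyError(f"endpoint {endpoint!r} not present")
        sub = self.table[cols].dropna()
        return sub.rename(columns={cols[0]: "time", cols[1]: "event"})


@dataclass
class MafTable:
    """Per-variant somatic mutation records (MAF columns)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records
        missing = [c for c in MAF_COLUMNS if c not in r.columns]
        if missing:
            raise FormatError(f"MAF missing required columns: {missing}")
        if len(r) and (r["Start_Position"] < 1).any():
            raise FormatError("MAF positions must be >= 1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["Tumor_Sample_Barcode"].unique())


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels, harmonized as sub1..subK.

    By convention sub1 is the immune-enriched cluster.
    """

    labels: pd.Series  # sample_id -> "sub1".."subK"
    cohort: str = ""
    k: int = 0

    def __post_init__(self) -> None:
        if self.k == 0:
            self.k = self.labels.nunique()
        expected = {f"sub{i}" for i in range(1, self.k + 1)}
        seen = set(self.labels.unique())
        if not seen <= expected:
            raise ValueError(f"labels {seen - expected} outside sub1..sub{self.k}")
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate sample ids in assignment")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def samples_of(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, unit: str) -> ExpressionMatrix:
    """Read a gene x sample expression TSV (first column gene symbols).

    Duplicate gene symbols are collapsed by keeping the row with the highest
    mean (logged); rows with missing entries are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.index.name = "gene_id"
    df.columns = df.columns.astype(str).str.strip()
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise FormatError(f"missing values in rows {bad[:5]} of {path}")
    if df.index.duplicated().any():
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        keep_first = df.iloc[order].groupby(level=0, sort=False).head(1)
        dropped = len(df) - len(keep_first)
        logger.warning("collapsed %d duplicate gene rows by max-mean rule", dropped)
        df = keep_first.loc[pd.unique(df.index)]
    return ExpressionMatrix(df, unit)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has no genes")
            name, desc = parts[0].strip(), parts[1]
            genes = [g.strip() for g in parts[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name!r} has zero genes")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def _variant_type_consistent(row) -> bool:
    ref, alt, vtype = row["Reference_Allele"], row["Tumor_Seq_Allele2"], row["Variant_Type"]
    ref, alt = str(ref), str(alt)
    if vtype == "SNP":
        return len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-"
    if vtype == "INS":
        return alt != "-" and (ref == "-" or len(alt) > len(ref))
    if vtype == "DEL":
        return ref != "-" and (alt == "-" or len(ref) > len(alt))
    return False


def read_maf(path) -> MafTable:
    """Read a tab-separated MAF; extra columns are ignored.

    Records with an unknown variant classification or an allele/type
    mismatch are rejected with a warning (not fatal); position < 1 is fatal.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str})
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF {path} missing columns {missing}")
    df = df[MAF_COLUMNS].copy()
    df["Start_Position"] = df["Start_Position"].astype(int)
    if len(df) and (df["Start_Position"] < 1).any():
        raise FormatError(f"MAF {path} has position < 1")
    known = df["Variant_Classification"].isin(VARIANT_CLASSIFICATIONS)
    if not known.all():
        bad = df.loc[~known, "Variant_Classification"].unique().tolist()
        warnings.warn(f"rejected {int((~known).sum())} MAF records with unknown "
                      f"classifications {bad}", stacklevel=2)
        df = df[known]
    ok = df.apply(_variant_type_consistent, axis=1) if len(df) else pd.Series(dtype=bool)
    if len(df) and not ok.all():
        warnings.warn(
            f"rejected {int((~ok).sum())} MAF records with allele/type mismatch",
            stacklevel=2,
        )
        df = df[ok]
    return MafTable(df.reset_index(drop=True))


def write_maf(maf: MafTable, path) -> None:
    maf.records.to_csv(path, sep="\t", index=False)


def read_assignment(path, cohort: str = "") -> SubtypeAssignment:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = df.iloc[:, 0].astype(str)
    labels.index = labels.index.astype(str)
    return SubtypeAssignment(labels, cohort=cohort)


def write_assignment(assignment: SubtypeAssignment, path) -> None:
    assignment.labels.rename("subtype").to_csv(path, sep="\t", index_label="sample_id")


def read_gene_list(path) -> list[str]:
    """Plain text gene list, one symbol per line, '#' comments allowed."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            g = line.split("#")[0].strip()
            if g:
                genes.append(g)
    return list(dict.fromkeys(genes))


def intersect_samples(*sample_lists) -> tuple[list[str], list[str]]:
    """Ordered intersection of sample id lists; also returns dropped ids."""
    common = set(sample_lists[0])
    for s in sample_lists[1:]:
        common &= set(s)
    ordered = [s for s in sample_lists[0] if s in common]
    dropped = sorted({s for lst in sample_lists for s in lst} - common)
    if dropped:
        logger.info("dropped %d samples absent from some inputs", len(dropped))
    return ordered, dropped


def cpm(expr: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Counts per million using total-count library sizes.

    Library sizes are always computed over the full matrix; pass ``genes``
    to subset rows afterwards (restricting before normalization would let
    the selected genes define the library and cancel their own signal).
    """
    if expr.unit != "raw_counts":
        out = expr.values
    else:
        lib = expr.values.sum(axis=0)
        out = expr.values / lib * 1e6
    if genes is not None:
        out = out.loc[[g for g in genes if g in out.index]]
    return out.copy()


def log2cpm(expr: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """log2(CPM+1) for counts; intensities/log2cpm returned unchanged."""
    if expr.unit == "raw_counts":
        return np.log2(cpm(expr, genes=genes) + 1.0)
    out = expr.values
    if genes is not None:
        out = out.loc[[g for g in genes if g in out.index]]
    return out.copy()
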