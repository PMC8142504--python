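"""Per-subtype mutation landscape: top mutated genes, classification
counts, the six-class SNV substitution spectrum, and driver-gene frequency
comparison between subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MafTable, SubtypeAssignment

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SPECTRUM_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]


@dataclass
class MutationLandscape:
    gene_frequency: pd.DataFrame       # gene x subtype mutated-sample fraction
    top_genes: list[str]               # top-n by sub1 frequency
    classification_counts: pd.DataFrame  # classification x subtype
    spectrum: pd.DataFrame             # six-class SNV counts x subtype


def _nonsilent(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["Variant_Classification"] != "Silent"]


def summarize_maf(
    maf: MafTable, assignment: SubtypeAssignment, top_n: int = 20
) -> MutationLandscape:
    """Mutation landscape per subtype.

    Gene frequency is the fraction of subtype samples carrying >= 1
    nonsilent variant in the gene (a sample counts once per gene). Top
    genes are ranked by sub1 frequency and re-used for the other subtypes.
    """
    rec = maf.records
    labels = assignment.labels
    known = rec["Tumor_Sample_Barcode"].isin(labels.index)
    if not known.all():
        warnings.warn(f"dropped {int((~known).sum())} MAF records from samples "
                      "without a subtype", stacklevel=2)
        rec = rec[known]
    subtypes = [f"sub{i}" for i in range(1, assignment.k + 1)]
    sizes = {s: len(assignment.samples_of(s)) for s in subtypes}
    if any(v == 0 for v in sizes.values()):
        raise ValueError("empty subtype")

    ns = _nonsilent(rec)
    if len(ns):
        pairs = ns[["Hugo_Symbol", "Tumor_Sample_Barcode"]].drop_duplicates()
        pairs = pairs.assign(subtype=labels.loc[pairs["Tumor_Sample_Barcode"]].values)
        counts = pairs.groupby(["Hugo_Symbol", "subtype"]).size().unstack(fill_value=0)
        counts = counts.reindex(columns=subtypes, fill_value=0)
        freq = counts / pd.Series(sizes)
    else:
        freq = pd.DataFrame(columns=subtypes, dtype=float)
    top = freq.sort_values(
        by=freq.columns[0] if len(freq.columns) else None,
        ascending=False, kind="stable",
    ).head(top_n).index.tolist() if len(freq) else []

    if len(rec):
        cls = rec.assign(subtype=labels.loc[rec["Tumor_Sample_Barcode"]].values)
        cls_counts = (cls.groupby(["Variant_Classification", "subtype"]).size()
                      .unstack(fill_value=0).reindex(columns=subtypes, fill_value=0))
    else:
        cls_counts = pd.DataFrame(columns=subtypes, dtype=int)

    spec_cols = {}
    for s in subtypes:
        sub_rec = rec[labels.loc[rec["Tumor_Sample_Barcode"]].values == s] if len(rec) \
            else rec
        spec_cols[s] = snv_spectrum(MafTable(sub_rec.reset_index(drop=True)))
    spectrum = pd.DataFrame(spec_cols)
    return MutationLandscape(
        gene_frequency=freq, top_genes=top,
        classification_counts=cls_counts, spectrum=spectrum,
    )


def snv_spectrum(maf: MafTable) -> pd.Series:
    """Six-class pyrimidine-collapsed SNV substitution counts.

    Purine-reference substitutions are reverse-complemented (G>A counts as
    C>T). Non-SNP records are ignored; ref == alt records are rejected.
    """
    rec = maf.records
    snp = rec[rec["Variant_Type"] == "SNP"]
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    for ref, alt in zip(snp["Reference_Allele"], snp["Tumor_Seq_Allele2"]):
        ref, alt = str(ref).upper(), str(alt).upper()
        if ref == alt:
            raise ValueError(f"SNV with ref == alt ({ref})")
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    return pd.Series(counts, name="count")


def driver_compare(
    maf: MafTable, assignment: SubtypeAssignment, driver_genes: list[str]
) -> pd.DataFrame:
    """Per-driver-gene mutated-sample frequencies and a 2x2 test.

    Chi-square with Yates continuity correction; Fisher's exact test when
    any expected cell count is below 5. Only supports k=2 subtypes.
    """
    if assignment.k != 2:
        raise ValueError("driver comparison is defined for two subtypes")
    labels = assignment.labels
    sub1 = set(assignment.samples_of("sub1"))
    sub2 = set(assignment.samples_of("sub2"))
    ns = _nonsilent(maf.records)
    ns = ns[ns["Tumor_Sample_Barcode"].isin(labels.index)]
    rows = []
    for gene in driver_genes:
        carriers = set(ns.loc[ns["Hugo_Symbol"] == gene, "Tumor_Sample_Barcode"])
        a, b = len(carriers & sub1), len(sub1 - carriers)
        c, d = len(carriers & sub2), len(sub2 - carriers)
        freq1 = a / len(sub1)
        freq2 = c / len(sub2)
        if a + c == 0:
            rows.append((gene, freq1, freq2, np.nan, np.nan, "none"))
            continue
        table = np.array([[a, b], [c, d]])
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            _, p = stats.fisher_exact(table)
            stat, test = np.nan, "fisher"
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=True)
            test = "chi2"
        rows.append((gene, freq1, freq2, stat, float(p), test))
    return pd.DataFrame(
        rows, columns=["gene", "freq_sub1", "freq_sub2", "chi2", "p", "test"]
    ).set_index("gene")
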