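"""Curation of raw clinical variant tables into analysis datasets.

Builds two nested datasets from a ClinVar-style table:

* **Dataset 1** — variants of genes whose *definitive* fraction
  (benign + pathogenic over all retrieved variants of the gene) exceeds
  10%; only benign/pathogenic rows are kept, labelled 0/1.
* **Dataset 2** — variants of genes whose *extended* fraction (additionally
  counting likely_benign and likely_pathogenic in the numerator) exceeds
  10%; likely_benign maps to 0 and likely_pathogenic to 1.  Dataset 1 is a
  subset of Dataset 2 by construction.

Before the gene rule, two record-level filters run in a fixed, audited
order: (1) variants with conflicting clinical significance between sources
are dropped; (2) the population-frequency filter removes benign-side
variants with allele frequency below 0.01 and pathogenic-side variants with
allele frequency above 0.01.  Records with no observed frequency are kept
by default.  VUS rows survive the filters but never appear in either output
dataset.

Boundary conventions (documented, deliberate): the 10% rule is a strict
inequality ("larger than 10%"), so a gene at exactly 0.10 is excluded; the
frequency filter keeps a benign variant at exactly 0.01 (the rule excludes
only *below* 0.01) and a pathogenic variant at exactly 0.01 (only *above*
is excluded).  The 10% denominator is the gene's total variant count across
all significance classes, configurable via ``denominator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BENIGN_LIKE",
    "PATHOGENIC_LIKE",
    "DEFINITIVE",
    "CurationReport",
    "assign_dataset",
    "apply_frequency_filter",
    "drop_conflicting",
    "build_datasets",
]

BENIGN_LIKE = ("benign", "likely_benign")
PATHOGENIC_LIKE = ("pathogenic", "likely_pathogenic")
DEFINITIVE = ("benign", "pathogenic")
_LABEL_MAP = {
    "benign": 0,
    "likely_benign": 0,
    "pathogenic": 1,
    "likely_pathogenic": 1,
}


@dataclass
class CurationReport:
    """Stage-by-stage bookkeeping for one curation run.

    At every filter stage, removed + retained equals the stage input, so
    the pipeline is auditable end to end.
    """

    n_input: int = 0
    n_conflicting_removed: int = 0
    n_frequency_removed: int = 0
    n_after_filters: int = 0
    gene_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_membership: dict[str, str] = field(default_factory=dict)
    dataset1_size: int = 0
    dataset2_size: int = 0
    dataset1_benign: int = 0
    dataset1_pathogenic: int = 0
    dataset2_benign: int = 0
    dataset2_pathogenic: int = 0

    def reconciles(self) -> bool:
        return (
            self.n_input - self.n_conflicting_removed - self.n_frequency_removed
            == self.n_after_filters
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_conflicting_removed": self.n_conflicting_removed,
            "n_frequency_removed": self.n_frequency_removed,
            "n_after_filters": self.n_after_filters,
            "gene_fractions": self.gene_fractions,
            "gene_membership": self.gene_membership,
            "dataset1": {
                "size": self.dataset1_size,
                "benign": self.dataset1_benign,
                "pathogenic": self.dataset1_pathogenic,
            },
            "dataset2": {
                "size": self.dataset2_size,
                "benign": self.dataset2_benign,
                "pathogenic": self.dataset2_pathogenic,
            },
        }


def drop_conflicting(records: pd.DataFrame) -> pd.DataFrame:
    """Remove rows whose clinical significance conflicts between sources."""
    return records[records["clin_sig"] != "conflicting"]


def apply_frequency_filter(
    records: pd.DataFrame, cutoff: float = 0.01, keep_missing: bool = True
) -> pd.DataFrame:
    """Population-frequency filter.

    Benign-side variants (benign, likely_benign) are removed when their
    allele frequency is strictly below ``cutoff``; pathogenic-side variants
    (pathogenic, likely_pathogenic) when strictly above.  VUS and
    conflicting rows pass through untouched.  Rows with missing frequency
    are retained unless ``keep_missing`` is False.
    """
    af = pd.to_numeric(records["allele_freq"], errors="coerce")
    missing = af.isna()
    benign_side = records["clin_sig"].isin(BENIGN_LIKE)
    pathogenic_side = records["clin_sig"].isin(PATHOGENIC_LIKE)
    remove = (benign_side & (af < cutoff)) | (pathogenic_side & (af > cutoff))
    remove &= ~missing
    if not keep_missing:
        remove |= missing & (benign_side | pathogenic_side)
    return records[~remove]


def assign_dataset(
    records_of_one_gene: pd.DataFrame,
    threshold: float = 0.10,
    denominator: str = "all",
) -> str:
    """Classify one gene as 'dataset1', 'dataset2' or 'excluded'.

    dataset1 when count(benign) + count(pathogenic) over the denominator is
    strictly greater than ``threshold``; dataset2 when the numerator also
    counts likely_benign and likely_pathogenic.  dataset1 membership implies
    dataset2 membership (the extended numerator can only be larger).

    ``denominator``: "all" (default) counts every retrieved variant of the
    gene; "labeled" counts only benign/pathogenic/likely rows.
    """
    if records_of_one_gene.empty:
        raise ValueError("assign_dataset: empty record list")
    genes = records_of_one_gene["gene"].unique()
    if len(genes) != 1:
        raise ValueError(f"assign_dataset: expected one gene, got {list(genes)}")
    sig = records_of_one_gene["clin_sig"]
    if denominator == "all":
        total = len(sig)
    elif denominator == "labeled":
        total = int(sig.isin(BENIGN_LIKE + PATHOGENIC_LIKE).sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if total == 0:
        return "excluded"
    definitive = int(sig.isin(DEFINITIVE).sum())
    extended = int(sig.isin(BENIGN_LIKE + PATHOGENIC_LIKE).sum())
    if definitive / total > threshold:
        return "dataset1"
    if extended / total > threshold:
        return "dataset2"
    return "excluded"


def gene_fractions(records_of_one_gene: pd.DataFrame) -> tuple[float, float]:
    """(definitive fraction, extended fraction) for one gene's records."""
    sig = records_of_one_gene["clin_sig"]
    total = len(sig)
    if total == 0:
        return 0.0, 0.0
    return (
        float(sig.isin(DEFINITIVE).sum() / total),
        float(sig.isin(BENIGN_LIKE + PATHOGENIC_LIKE).sum() / total),
    )


def build_datasets(
    raw_table: pd.DataFrame,
    threshold: float = 0.10,
    frequency_cutoff: float = 0.01,
    keep_missing_af: bool = True,
    denominator: str = "all",
) -> tuple[pd.DataFrame, pd.DataFrame, CurationReport]:
    """Full curation: conflict drop → frequency filter → per-gene rule.

    Returns (dataset1, dataset2, report).  dataset1 rows carry label 0
    (benign) / 1 (pathogenic); dataset2 additionally maps likely_benign → 0
    and likely_pathogenic → 1.  VUS never appear in either output, and
    dataset1 ⊆ dataset2 row-wise.
    """
    report = CurationReport(n_input=len(raw_table))

    step1 = drop_conflicting(raw_table)
    report.n_conflicting_removed = len(raw_table) - len(step1)
    step2 = apply_frequency_filter(step1, frequency_cutoff, keep_missing_af)
    report.n_frequency_removed = len(step1) - len(step2)
    report.n_after_filters = len(step2)

    ds1_parts: list[pd.DataFrame] = []
    ds2_parts: list[pd.DataFrame] = []
    if not step2.empty:
        for gene, grp in step2.groupby("gene", sort=True):
            membership = assign_dataset(grp, threshold, denominator)
            frac_def, frac_ext = gene_fractions(grp)
            report.gene_fractions[str(gene)] = {
                "definitive": frac_def,
                "extended": frac_ext,
            }
            report.gene_membership[str(gene)] = membership
            if membership == "dataset1":
                ds1_parts.append(grp[grp["clin_sig"].isin(DEFINITIVE)])
            if membership in ("dataset1", "dataset2"):
                ds2_parts.append(
                    grp[grp["clin_sig"].isin(BENIGN_LIKE + PATHOGENIC_LIKE)]
                )

    empty = raw_table.iloc[0:0].assign(label=pd.Series(dtype=int))
    ds1 = pd.concat(ds1_parts, ignore_index=True) if ds1_parts else empty.copy()
    ds2 = pd.concat(ds2_parts, ignore_index=True) if ds2_parts else empty.copy()
    for ds in (ds1, ds2):
        if len(ds):
            ds["label"] = ds["clin_sig"].map(_LABEL_MAP).astype(int)

    report.dataset1_size = len(ds1)
    report.dataset2_size = len(ds2)
    if len(ds1):
        report.dataset1_benign = int((ds1["label"] == 0).sum())
        report.dataset1_pathogenic = int((ds1["label"] == 1).sum())
    if len(ds2):
        report.dataset2_benign = int((ds2["label"] == 0).sum())
        report.dataset2_pathogenic = int((ds2["label"] == 1).sum())
    return ds1, ds2, report
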