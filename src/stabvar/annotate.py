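"""Amino-acid chemistry categories and stability annotations.

The residue categorization follows a fixed five-axis scheme over the 20
canonical amino acids:

* hydropathy — hydrophobic {A,C,G,I,L,M,F,P,W,V} vs polar (the rest);
* size — small {A,C,G,S,N,D,P,T,V} vs large (the rest);
* ring/chain — aromatic {H,F,W,Y} vs aliphatic {A,I,K,L,M,P,V} (some
  residues carry neither);
* charge — positive {H,K,R} vs negative {D,E} (most residues carry
  neither).

Note two deliberate oddities kept verbatim from the source categorization:
Lys appears in the aliphatic set (its side chain is a flexible carbon chain
terminating in an amine) and Gly counts as hydrophobic.  Substitution pair
labels are directional, wild-type → mutant, because charge reversals in the
two directions associate differently with pathogenicity.
"""

from __future__ import annotations

from statistics import fmean
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import AMINO_ACIDS, PREDICTORS

__all__ = [
    "HYDROPHOBIC",
    "POLAR",
    "AROMATIC",
    "ALIPHATIC",
    "POSITIVE",
    "NEGATIVE",
    "SMALL",
    "LARGE",
    "classify_residue",
    "substitution_categories",
    "annotate_variants",
    "ensemble_ddg",
    "stability_class",
    "fraction_destabilizing",
]

HYDROPHOBIC = frozenset("ACGILMFPWV")
POLAR = frozenset("DEKRHNQSTY")
AROMATIC = frozenset("HFWY")
ALIPHATIC = frozenset("AIKLMPV")  # Lys included, per the source scheme
POSITIVE = frozenset("HKR")
NEGATIVE = frozenset("DE")
SMALL = frozenset("ACGSNDPTV")
LARGE = frozenset("RQEHILKMFWY")

_AXES = (
    ("hydrophobic", HYDROPHOBIC, "polar", POLAR),
    ("small", SMALL, "large", LARGE),
    ("aromatic", AROMATIC, "aliphatic", ALIPHATIC),
    ("positive", POSITIVE, "negative", NEGATIVE),
)


def classify_residue(aa: str) -> frozenset[str]:
    """Category labels of one residue: always a hydropathy and a size label,
    plus aromatic/aliphatic and positive/negative where applicable."""
    if aa not in set(AMINO_ACIDS):
        raise ValueError(f"non-canonical residue {aa!r}")
    labels = set()
    for name_a, set_a, name_b, set_b in _AXES:
        if aa in set_a:
            labels.add(name_a)
        elif aa in set_b:
            labels.add(name_b)
    return frozenset(labels)


def _axis_label(aa: str, set_a: frozenset, name_a: str, set_b: frozenset, name_b: str):
    if aa in set_a:
        return name_a
    if aa in set_b:
        return name_b
    return None


def substitution_categories(wt: str, mut: str) -> frozenset[str]:
    """Directional pair labels for a wt→mut substitution.

    Always yields one hydropathy pair and one size pair; an
    aromatic/aliphatic pair only when both residues carry one of those
    labels, and a charge pair only when both are charged.
    """
    if wt == mut:
        raise ValueError("wild-type and mutant residue must differ")
    for aa in (wt, mut):
        if aa not in set(AMINO_ACIDS):
            raise ValueError(f"non-canonical residue {aa!r}")
    labels = set()
    for name_a, set_a, name_b, set_b in _AXES:
        lw = _axis_label(wt, set_a, name_a, set_b, name_b)
        lm = _axis_label(mut, set_a, name_a, set_b, name_b)
        if lw is not None and lm is not None:
            labels.add(f"{lw}-{lm}")
    return frozenset(labels)


def _axis_column(residues: pd.Series, set_a, name_a, set_b, name_b) -> pd.Series:
    out = pd.Series(pd.NA, index=residues.index, dtype=object)
    out[residues.isin(set_a)] = name_a
    out[residues.isin(set_b)] = name_b
    return out


def annotate_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Add the four substitution-pair category columns to a variant table.

    New columns: cat_hydropathy, cat_size (always set), cat_aromatic,
    cat_charge (set only when both residues carry a label on that axis).
    The ``functional_class`` column, if present, is carried through
    unchanged — it is assigned by the data source, never inferred.
    """
    out = df.copy()
    col_names = ("cat_hydropathy", "cat_size", "cat_aromatic", "cat_charge")
    for col, (name_a, set_a, name_b, set_b) in zip(col_names, _AXES):
        lw = _axis_column(out["wt_aa"], set_a, name_a, set_b, name_b)
        lm = _axis_column(out["mut_aa"], set_a, name_a, set_b, name_b)
        both = lw.notna() & lm.notna()
        out[col] = pd.Series(pd.NA, index=out.index, dtype=object)
        out.loc[both, col] = lw[both] + "-" + lm[both]
    return out


def ensemble_ddg(
    variants: pd.DataFrame | pd.Series, which: Sequence[str] | Iterable[str]
) -> pd.Series | float:
    """Arithmetic mean of the selected ΔΔG predictor columns (kcal/mol)."""
    which = list(which)
    if not which:
        raise ValueError("ensemble_ddg: empty predictor selection")
    unknown = [w for w in which if w not in PREDICTORS]
    if unknown:
        raise ValueError(f"unknown predictor(s) {unknown}; expected {PREDICTORS}")
    if isinstance(variants, pd.Series):
        return fmean(float(variants[w]) for w in which)
    return variants[which].mean(axis=1)


def stability_class(ddg: float, cutoff: float) -> str:
    """'destabilizing' if ΔΔG ≤ −cutoff, 'stabilizing' if ΔΔG ≥ +cutoff,
    otherwise 'neither'.  Cutoff is a positive magnitude in kcal/mol."""
    if cutoff <= 0:
        raise ValueError("cutoff must be a positive magnitude")
    if ddg <= -cutoff:
        return "destabilizing"
    if ddg >= cutoff:
        return "stabilizing"
    return "neither"


def fraction_destabilizing(
    variants: pd.DataFrame, predictor: str | Sequence[str] = "ddg_p1"
) -> float:
    """Fraction of variants with ΔΔG < 0 (any destabilization at all).

    ``predictor`` may be one column name or a list of names, in which case
    the ensemble average is scored.  Distinct from the magnitude-cutoff
    stability classes: this is the "any destabilization" statistic.
    """
    if len(variants) == 0:
        raise ValueError("fraction_destabilizing: empty variant list")
    if isinstance(predictor, str):
        values = variants[predictor] if predictor in variants else None
        if values is None:
            raise ValueError(f"unknown predictor {predictor!r}")
    else:
        values = ensemble_ddg(variants, predictor)
    return float((np.asarray(values) < 0).mean())
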