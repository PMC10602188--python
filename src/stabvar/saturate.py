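"""In-silico saturation mutagenesis.

Every residue of a protein is substituted by the other 19 canonical amino
acids (19·L substitutions for a sequence of length L), each substitution is
scored by a pluggable ΔΔG scorer, and a substitution is called pathogenic
when its ΔΔG falls at or below a destabilization cutoff (default −1.1
kcal/mol; ΔΔG here is mutant minus wild type with negative values
destabilizing).

A scorer is any callable ``(sequence, position, wt, mut) -> float`` that is
deterministic for a fixed input and returns finite kcal/mol values.
:class:`SyntheticScorer` provides a seeded, hash-based stand-in (synthetic;
it models nothing physical) so proteome-scale bookkeeping can be exercised
without an external predictor; :class:`TableScorer` serves precomputed ΔΔG
values from a TSV join.

Rows can be streamed to TSV one substitution at a time via
:func:`scan_to_tsv`, so genome-scale runs need not hold results in memory.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .synth import AMINO_ACIDS

__all__ = [
    "DEFAULT_CUTOFF",
    "Scorer",
    "SyntheticScorer",
    "TableScorer",
    "SaturationScan",
    "enumerate_substitutions",
    "scan",
    "scan_to_tsv",
    "summarize",
]

#: ΔΔG call threshold, kcal/mol: at or below this, a substitution is
#: flagged pathogenic.
DEFAULT_CUTOFF = -1.1

Scorer = Callable[[str, int, str, str], float]

_CANONICAL = set(AMINO_ACIDS)


@dataclass(frozen=True)
class SaturationScan:
    """All 19·L substitutions of one protein with scores and calls."""

    protein_id: str
    length: int
    rows: pd.DataFrame  # columns: position, wt_aa, mut_aa, ddg, pathogenic
    cutoff: float

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def n_pathogenic(self) -> int:
        return int(self.rows["pathogenic"].sum())


class SyntheticScorer:
    """Deterministic pseudo-random ΔΔG scorer (synthetic stand-in).

    Maps each (position, wt, mut) through a keyed BLAKE2 hash onto a
    Gaussian N(mean, sd²) value, so scores look like a ΔΔG distribution but
    depend only on the seed and the substitution identity — identical
    inputs always give identical scores, across runs and platforms.
    """

    def __init__(self, seed: int = 0, mean: float = -0.9, sd: float = 1.4):
        self.seed = int(seed)
        self.mean = float(mean)
        self.sd = float(sd)

    def __call__(self, sequence: str, position: int, wt: str, mut: str) -> float:
        key = f"{self.seed}|{position}|{wt}|{mut}".encode()
        h = hashlib.blake2b(key, digest_size=8).digest()
        u = (int.from_bytes(h, "big") + 0.5) / 2**64  # in (0, 1)
        return float(self.mean + self.sd * ndtri(u))


class TableScorer:
    """Scorer backed by a precomputed ΔΔG table.

    The table needs columns protein_id, position, wt_aa, mut_aa, ddg; the
    scorer is bound to one protein id at lookup time via ``for_protein``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"protein_id", "position", "wt_aa", "mut_aa", "ddg"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"ΔΔG table missing columns {sorted(missing)}")
        self._index = table.set_index(
            ["protein_id", "position", "wt_aa", "mut_aa"]
        )["ddg"]

    def for_protein(self, protein_id: str) -> Scorer:
        def score(sequence: str, position: int, wt: str, mut: str) -> float:
            try:
                return float(self._index.loc[(protein_id, position, wt, mut)])
            except KeyError:
                raise KeyError(
                    f"no precomputed ΔΔG for {protein_id} {wt}{position}{mut}"
                ) from None

        return score


def enumerate_substitutions(sequence: str) -> list[tuple[int, str, str]]:
    """All (position, wt, mut) tuples: positions 1-based, mutants in
    alphabetical order, 19 per position."""
    if not sequence:
        raise ValueError("empty sequence")
    subs = []
    for i, wt in enumerate(sequence, start=1):
        if wt not in _CANONICAL:
            raise ValueError(f"non-canonical residue {wt!r} at position {i}")
        for mut in AMINO_ACIDS:
            if mut != wt:
                subs.append((i, wt, mut))
    return subs


def _scored_rows(
    sequence: str, scorer: Scorer, cutoff: float
) -> Iterator[tuple[int, str, str, float, int]]:
    for pos, wt, mut in enumerate_substitutions(sequence):
        ddg = float(scorer(sequence, pos, wt, mut))
        if not np.isfinite(ddg):
            raise ValueError(f"scorer returned non-finite ΔΔG for {wt}{pos}{mut}")
        yield pos, wt, mut, ddg, int(ddg <= cutoff)


def scan(
    sequence: str,
    scorer: Scorer,
    cutoff: float = DEFAULT_CUTOFF,
    protein_id: str = "protein",
) -> SaturationScan:
    """Score every substitution of one sequence and call pathogenicity.

    A substitution is flagged pathogenic iff its ΔΔG ≤ ``cutoff``.
    """
    rows = pd.DataFrame(
        _scored_rows(sequence, scorer, cutoff),
        columns=["position", "wt_aa", "mut_aa", "ddg", "pathogenic"],
    )
    return SaturationScan(
        protein_id=protein_id, length=len(sequence), rows=rows, cutoff=cutoff
    )


def scan_to_tsv(
    records: Iterable[tuple[str, str]],
    scorer_factory: Callable[[str], Scorer],
    out_path: str | Path,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """Stream scans of many proteins to one TSV; returns the summary dict.

    ``scorer_factory`` maps a protein id to its scorer, e.g.
    ``lambda pid: synthetic_scorer`` or ``table_scorer.for_protein``.
    One row is written per substitution, so memory use is O(1) in the
    number of substitutions.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    total = 0
    flagged = 0
    with open(out_path, "w") as fh:
        fh.write("protein_id\tposition\twt_aa\tmut_aa\tddg\tpathogenic\n")
        for protein_id, sequence in records:
            scorer = scorer_factory(protein_id)
            for pos, wt, mut, ddg, flag in _scored_rows(sequence, scorer, cutoff):
                fh.write(f"{protein_id}\t{pos}\t{wt}\t{mut}\t{ddg:.6g}\t{flag}\n")
                total += 1
                flagged += flag
    return {
        "total_mutations": total,
        "total_pathogenic": flagged,
        "fraction_pathogenic": flagged / total if total else 0.0,
        "cutoff": cutoff,
    }


def summarize(scans: Sequence[SaturationScan]) -> tuple[int, int, float]:
    """(total substitutions, total pathogenic calls, pathogenic fraction)
    summed over scans."""
    if not scans:
        raise ValueError("summarize: empty scan list")
    total = sum(s.n_total for s in scans)
    flagged = sum(s.n_pathogenic for s in scans)
    return total, flagged, flagged / total
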