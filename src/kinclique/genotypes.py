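"""Diploid microsatellite genotype container and GenePop I/O.

Genotypes are unordered pairs of integer allele labels (fragment-size
classes); a call may be missing.  The container is a thin wrapper over an
individuals × loci :class:`pandas.DataFrame` of ``(a, b)`` tuples /
``None``.  GenePop files (2- or 3-digit allele codes) are the interchange
format, read through Biopython's parser.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import pandas as pd
from Bio.PopGen import GenePop as _BioGenePop

__all__ = ["GenotypeTable", "read_genepop", "write_genepop"]


@dataclass
class GenotypeTable:
    """Individuals × loci diploid calls; missing allowed.

    ``calls`` cells hold an unordered tuple ``(a, b)`` of positive integer
    allele labels (stored sorted) or ``None`` for missing.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        norm = self.calls.copy()
        for col in norm.columns:
            norm[col] = [self._norm(v) for v in norm[col]]
        self.calls = norm

    @staticmethod
    def _norm(v):
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        a, b = v
        a, b = int(a), int(b)
        if a <= 0 or b <= 0:
            raise ValueError(f"allele labels must be positive, got {v}")
        return (a, b) if a <= b else (b, a)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    def get(self, individual: str, locus: str):
        return self.calls.at[individual, locus]

    def observed_alleles(self, locus: str) -> list[int]:
        alleles = set()
        for v in self.calls[locus]:
            if v is not None:
                alleles.update(v)
        return sorted(alleles)

    def n_typed(self, locus: str) -> int:
        return int(self.calls[locus].notna().sum())

    def subset(self, individuals) -> "GenotypeTable":
        return GenotypeTable(self.calls.loc[list(individuals)].copy())


def _code_width(table: GenotypeTable) -> int:
    mx = 0
    for locus in table.loci:
        alleles = table.observed_alleles(locus)
        if alleles:
            mx = max(mx, max(alleles))
    return 3 if mx > 99 else 2


def write_genepop(table: GenotypeTable, path, title: str = "kinclique genotypes") -> None:
    """Write a GenePop file (single population, digit width auto 2/3)."""
    w = _code_width(table)
    zero = "0" * w
    lines = [title]
    lines.extend(table.loci)
    lines.append("POP")
    for ind in table.individuals:
        codes = []
        for locus in table.loci:
            call = table.get(ind, locus)
            if call is None:
                codes.append(zero + zero)
            else:
                codes.append(f"{call[0]:0{w}d}{call[1]:0{w}d}")
        lines.append(f"{ind} ,  " + " ".join(codes))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file (first population) into a GenotypeTable."""
    with open(path) as fh:
        rec = _BioGenePop.read(fh)
    loci = list(rec.loci_list)
    rows: dict[str, list] = {}
    pop = rec.populations[0]
    for name, genotype in pop:
        name = name.strip().rstrip(",").strip()
        calls = []
        for g in genotype:
            if g is None or any(a is None or int(a) == 0 for a in g):
                calls.append(None)
            else:
                calls.append((int(g[0]), int(g[1])))
        rows[name] = calls
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    return GenotypeTable(frame)
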