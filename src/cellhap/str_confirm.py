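"""Fetal-origin confirmation of a candidate cell from STR genotypes.

A cell picked from maternal blood is either fetal (a circulating
trophoblast) or a maternal white blood cell.  Short-tandem-repeat
profiling settles this: alleles present in the cell and the father but
absent from the mother can only have come from the fetal genome.  A cell
showing multiple such paternal-specific alleles is scored as fetal.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

AMELOGENIN = "AMEL"

#: 15 forensic STR loci (CODIS core plus D2S1338/D19S433) and the
#: amelogenin sex marker — the 16-locus identity panel.
DEFAULT_STR_PANEL = (
    "CSF1PO", "D3S1358", "D5S818", "D7S820", "D8S1179",
    "D13S317", "D16S539", "D18S51", "D21S11", "FGA",
    "TH01", "TPOX", "vWA", "D2S1338", "D19S433",
    AMELOGENIN,
)


@dataclasses.dataclass
class StrProfile:
    """Per-locus allele calls for one individual on a declared panel.

    ``alleles`` maps locus name to a tuple of at most two integer repeat
    designations; an empty tuple marks an undetected locus.  Amelogenin
    is encoded X=0 / Y=1.
    """

    sample: str
    alleles: dict[str, tuple[int, ...]]
    panel: tuple[str, ...] = DEFAULT_STR_PANEL

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        unknown = set(self.alleles) - set(self.panel)
        if unknown:
            raise ValueError(f"loci outside the declared panel: {sorted(unknown)}")
        for locus, a in self.alleles.items():
            if len(a) > 2:
                raise ValueError(f"more than two alleles at {locus}")
        for locus in self.panel:
            self.alleles.setdefault(locus, ())

    def detected(self, locus: str) -> bool:
        return len(self.alleles.get(locus, ())) > 0

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for locus in self.panel:
            a = self.alleles[locus]
            rows.append(
                (
                    locus,
                    self.sample,
                    a[0] if len(a) > 0 else ".",
                    a[1] if len(a) > 1 else ".",
                )
            )
        pd.DataFrame(rows, columns=["locus", "sample", "allele1", "allele2"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StrProfile":
        df = pd.read_csv(path, sep="\t", dtype=str)
        samples = df["sample"].unique()
        if len(samples) != 1:
            raise ValueError("expected a single-sample STR profile")
        alleles = {}
        for row in df.itertuples(index=False):
            a = tuple(
                int(float(x)) for x in (row.allele1, row.allele2) if x not in (".", "nan")
            )
            alleles[row.locus] = a
        return cls(sample=str(samples[0]), alleles=alleles, panel=tuple(df["locus"]))


def detection_rate(cell: StrProfile) -> float:
    """Percentage of panel loci with at least one detected allele."""
    if len(cell.panel) == 0:
        raise ValueError("empty STR panel")
    detected = sum(cell.detected(locus) for locus in cell.panel)
    return 100.0 * detected / len(cell.panel)


@dataclasses.dataclass
class StrMatchReport:
    """Paternal-specific allele accounting for one candidate cell."""

    per_locus: dict[str, list[int]]
    total: int
    #: cell alleles present in neither parent (flagged, never counted)
    unexplained: dict[str, list[int]]

    def to_dict(self) -> dict:
        return {
            "paternal_specific": {k: list(v) for k, v in self.per_locus.items()},
            "total": self.total,
            "unexplained": {k: list(v) for k, v in self.unexplained.items()},
        }


def paternal_specific_alleles(
    cell: StrProfile,
    father: StrProfile,
    mother: StrProfile,
    exclude: tuple[str, ...] = (AMELOGENIN,),
) -> StrMatchReport:
    """Alleles present in cell and father but absent from the mother.

    Undetected cell loci contribute nothing.  Amelogenin is excluded
    from scoring by default (a sex marker, not a polymorphic STR).  Cell
    alleles found in neither parent are reported separately as
    unexplained, without contributing to the count.
    """
    if set(father.panel) != set(cell.panel) or set(mother.panel) != set(cell.panel):
        raise ValueError("profiles must share the same panel")
    per_locus: dict[str, list[int]] = {}
    unexplained: dict[str, list[int]] = {}
    total = 0
    for locus in cell.panel:
        if locus in exclude:
            continue
        cell_a = set(cell.alleles[locus])
        fa = set(father.alleles[locus])
        mo = set(mother.alleles[locus])
        specific = sorted(cell_a & fa - mo)
        orphan = sorted(cell_a - fa - mo)
        if specific:
            per_locus[locus] = specific
            total += len(specific)
        if orphan:
            unexplained[locus] = orphan
    return StrMatchReport(per_locus=per_locus, total=total, unexplained=unexplained)


def classify_fetal_origin(paternal_allele_count: int, threshold: int = 2) -> bool:
    """True when the cell shows at least ``threshold`` paternal-specific alleles."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return paternal_allele_count >= threshold
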