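"""Model/results interface over the haplotyping core.

``FetalHaplotypeModel`` bundles a multi-sample :class:`GenotypeTable`
(father, mother, proband, candidate fetal cell) with a disease locus
and the decision parameters; :meth:`FetalHaplotypeModel.fit` runs
informative-SNP classification, proband-anchored phasing, key-SNP
marking and flank voting, returning a :class:`FetalHaplotypeResults`
carrying the per-parent calls, the diagnostic verdict, the per-SNP
table and a ``summary()`` printout.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .haplotyping import (
    HaplotypeCall,
    Verdict,
    call_fetal_haplotype,
    classify_informative_snps,
    derive_verdict,
    mark_key_snps,
)
from .io import GenotypeTable, read_family_vcf
from .simulate import DiseaseLocus


@dataclasses.dataclass
class FetalHaplotypeModel:
    """Trio-anchored fetal haplotype model for one candidate cell.

    Parameters
    ----------
    genotypes
        Multi-sample table holding the father, mother, proband and cell.
    locus
        Disease locus descriptor (anchor position, carrier parents,
        inheritance mode, per-parent pathogenic variant positions).
    flank
        Analysis window half-width around the locus anchor (bp).
    vote_threshold, min_key_snps
        Flank decision rule: majority fraction required and minimum key
        SNPs per flank.
    key_mode
        ``"observed"`` (dropout-robust, default) or ``"trio"``.
    fetal_sex
        ``"male"``/``"female"``; inferred from the cell's ploidy when
        omitted (a hemizygous cell is male).
    """

    genotypes: GenotypeTable
    locus: DiseaseLocus
    flank: int = 2_000_000
    vote_threshold: float = 0.8
    min_key_snps: int = 1
    key_mode: str = "observed"
    fetal_sex: str | None = None
    father: str = "FATHER"
    mother: str = "MOTHER"
    proband: str = "PROBAND"
    cell: str = "CELL"

    @classmethod
    def from_vcf(
        cls,
        path: str | Path,
        locus: DiseaseLocus,
        sample_roles: dict[str, str] | None = None,
        **kwargs,
    ) -> "FetalHaplotypeModel":
        """Build the model from a multi-sample VCF.

        ``sample_roles`` maps the canonical roles (FATHER, MOTHER,
        PROBAND, CELL) to the VCF sample names when they differ.
        """
        table = read_family_vcf(path, sample_roles)
        return cls(genotypes=table, locus=locus, **kwargs)

    def fit(self) -> "FetalHaplotypeResults":
        informative = classify_informative_snps(
            self.genotypes,
            self.locus,
            self.flank,
            father=self.father,
            mother=self.mother,
            proband=self.proband,
        )
        from .haplotyping import phase_to_pathogenic  # local to keep namespace tidy

        for parent in self.locus.carrier_parents:
            informative = phase_to_pathogenic(
                informative,
                self.genotypes,
                self.locus,
                parent,
                father=self.father,
                mother=self.mother,
                proband=self.proband,
            )
        informative = mark_key_snps(
            informative, self.genotypes, cell=self.cell, mode=self.key_mode
        )
        calls = {
            parent: call_fetal_haplotype(
                informative,
                parent,
                vote_threshold=self.vote_threshold,
                min_key_snps=self.min_key_snps,
            )
            for parent in self.locus.carrier_parents
        }
        sex = self.fetal_sex
        if sex is None:
            sex = "male" if self.genotypes.sample_haploid(self.cell) else "female"
        verdict = derive_verdict(
            calls.get("father"), calls.get("mother"), self.locus, fetal_sex=sex
        )
        return FetalHaplotypeResults(
            model=self,
            informative_snps=informative,
            calls=calls,
            verdict=verdict,
            fetal_sex=sex,
        )


@dataclasses.dataclass
class FetalHaplotypeResults:
    """Fitted haplotype inheritance for one fetal cell."""

    model: FetalHaplotypeModel
    informative_snps: pd.DataFrame
    calls: dict[str, HaplotypeCall]
    verdict: Verdict
    fetal_sex: str

    # -- convenience accessors --------------------------------------------
    @property
    def paternal_call(self) -> HaplotypeCall | None:
        return self.calls.get("father")

    @property
    def maternal_call(self) -> HaplotypeCall | None:
        return self.calls.get("mother")

    @property
    def n_informative(self) -> int:
        return len(self.informative_snps)

    @property
    def n_key(self) -> int:
        return int(self.informative_snps["key"].sum()) if self.n_informative else 0

    def key_snp_positions(self) -> pd.DataFrame:
        """(chrom, pos) of the key SNPs — input to haplotypable-gene counting."""
        keyed = self.informative_snps[self.informative_snps["key"]]
        return keyed[["chrom", "pos"]].reset_index(drop=True)

    # -- export ------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "locus": self.model.locus.to_dict(),
            "fetal_sex": self.fetal_sex,
            "flank": self.model.flank,
            "vote_threshold": self.model.vote_threshold,
            "min_key_snps": self.model.min_key_snps,
            "key_mode": self.model.key_mode,
            "n_informative": self.n_informative,
            "n_key": self.n_key,
            "calls": {p: c.to_dict() for p, c in self.calls.items()},
            "verdict": self.verdict.value,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary (verdict, per-flank vote counts)."""
        locus = self.model.locus
        lines = [
            "          Fetal Haplotype Inheritance",
            "=" * 54,
            f"Gene: {locus.gene_name}   Locus: {locus.chrom}:{locus.position}",
            f"Inheritance: {locus.inheritance_mode}   Fetal sex: {self.fetal_sex}",
            f"Window: +/- {self.model.flank:,} bp   "
            f"Key mode: {self.model.key_mode}   "
            f"Vote threshold: {self.model.vote_threshold}",
            "-" * 54,
            f"Informative SNPs: {self.n_informative}   Key SNPs: {self.n_key}",
            "",
            f"{'Parent':<10}{'Haplotype':<12}{'Up (1/2)':<12}{'Down (1/2)':<12}{'Recomb'}",
        ]
        label_names = {"father": ("P1", "P2"), "mother": ("M1", "M2")}
        for parent, call in self.calls.items():
            if call.label is None:
                lab = "ambiguous"
            else:
                lab = label_names[parent][call.label - 1]
            lines.append(
                f"{parent:<10}{lab:<12}"
                f"{call.upstream_votes[0]}/{call.upstream_votes[1]:<10}"
                f"{call.downstream_votes[0]}/{call.downstream_votes[1]:<10}"
                f"{'yes' if call.recombination_flag else 'no'}"
            )
            if call.message:
                lines.append(f"{'':<10}note: {call.message}")
        lines += ["-" * 54, f"Verdict: {self.verdict.value}", "=" * 54]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Per-SNP haplotype-support track around the locus.

        Key SNPs are drawn at the haplotype they vote for (1 above, 2
        below the axis), split by parent; the locus anchor is the
        vertical line.  Returns the matplotlib figure.
        """
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            fig, ax = plt.subplots(figsize=(9, 3.2))
        else:
            fig = ax.figure
        df = self.informative_snps
        colors = {"IFF": "tab:blue", "IFM": "tab:red"}
        offsets = {"IFF": 0.08, "IFM": -0.08}
        keyed = df[df["key"] & df["hap1_allele"].notna() & df["cell_allele"].notna()]
        for origin, grp in keyed.groupby("origin"):
            vote1 = grp["cell_allele"].astype(int) == grp["hap1_allele"].astype(int)
            y = (2 - vote1.astype(int) * 1).astype(float)  # hap1 -> 1, hap2 -> 2
            ax.scatter(
                grp["pos"] / 1e6,
                y + offsets[origin],
                s=18,
                c=colors[origin],
                label=f"{origin} key SNP",
                alpha=0.8,
            )
        nonkey = df[~df["key"]]
        ax.scatter(
            nonkey["pos"] / 1e6,
            [1.5] * len(nonkey),
            s=6,
            c="0.8",
            label="non-key",
            zorder=0,
        )
        ax.axvline(self.model.locus.position / 1e6, color="k", lw=1, ls="--")
        ax.set_yticks([1, 2], ["haplotype 1", "haplotype 2"])
        ax.set_ylim(0.5, 2.5)
        ax.set_xlabel(f"{self.model.locus.chrom} position (Mb)")
        ax.set_title(
            f"{self.model.locus.gene_name}: verdict {self.verdict.value}"
        )
        ax.legend(loc="upper right", fontsize=7)
        fig.tight_layout()
        return fig
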