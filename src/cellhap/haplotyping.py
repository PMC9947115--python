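"""Trio-anchored haplotype inference for a single fetal cell.

The analysis phases each carrier parent's chromosomes against the
disease locus using the affected proband, then decides which parental
haplotype the fetal cell inherited by majority voting over "key" SNPs
in the upstream and downstream flanks.

Definitions (biallelic sites throughout):

* An *informative SNP from the father* (IFF) is a site where the father
  is heterozygous and the mother is not (homozygous, or hemizygous on
  X); *IFM* is the mirror image.  At such a site the allele the
  informative parent transmitted to a child can be read off the child's
  genotype by subtracting the other parent's obligate contribution.
* Phasing anchors at the pathogenic variant: the carrier parent's
  haplotype that the proband inherited *together with* the pathogenic
  allele is haplotype 1 (P1 / M1), the other haplotype 2.  Assuming at
  most one crossover per transmitted chromosome and none within the
  analysis window, the allele each informative SNP placed on haplotype
  1 is known.
* A *key* SNP is an informative SNP whose observed cell genotype cannot
  be explained by the competing transmission hypothesis plus a single
  allele dropout: operationally, the observation contains the allele
  that only one parental haplotype could have delivered.  Observations
  homozygous for the allele shared with the other parent are non-key
  (they are exactly what dropout of the distinguishing allele would
  produce).
* Each flank votes by majority of its key SNPs; an unambiguous call
  needs both flanks to agree with a vote fraction at or above the
  decision threshold.  Discordant flanks are flagged as a possible
  fetal recombination and the call is left ambiguous rather than
  forced.

The four fetal combinations map to the diagnostic verdict: P1/M1
affected, P1/M2 carrier (paternal), P2/M1 carrier (maternal), P2/M2
normal; for an X-linked male fetus only the maternal side exists (M1
affected, M2 normal).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Genotype, GenotypeTable
from .simulate import DiseaseLocus

IFF = "IFF"
IFM = "IFM"

_PARENT_ORIGIN = {"father": IFF, "mother": IFM}

INFORMATIVE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "origin", "other_allele",
    "proband_allele", "distance", "hap1_allele", "key", "cell_allele",
]


class PhasingError(ValueError):
    """The proband cannot anchor the requested phasing."""


def _hom_like_allele(code: int) -> int | None:
    """The single allele of a homozygous or hemizygous genotype, else None."""
    g = Genotype(code)
    if g in (Genotype.HOM_REF, Genotype.HEM_REF):
        return 0
    if g in (Genotype.HOM_ALT, Genotype.HEM_ALT):
        return 1
    return None


def _transmitted_to_diploid_child(child_code: int, other_allele: int) -> int | None:
    """Allele the informative parent gave a diploid child, or None if inconsistent.

    The other parent is obliged to transmit ``other_allele``; the child's
    genotype must contain it, and the remaining allele is the informative
    parent's transmission.
    """
    g = Genotype(child_code)
    if g == Genotype.HET:
        return 1 - other_allele
    if g == Genotype.HOM_REF:
        return 0 if other_allele == 0 else None
    if g == Genotype.HOM_ALT:
        return 1 if other_allele == 1 else None
    return None


def _transmitted_to_haploid_child(child_code: int) -> int | None:
    """Maternal allele carried by a hemizygous (male X) child."""
    g = Genotype(child_code)
    if g == Genotype.HEM_REF:
        return 0
    if g == Genotype.HEM_ALT:
        return 1
    return None


def classify_informative_snps(
    table: GenotypeTable,
    locus: DiseaseLocus,
    flank: int = 2_000_000,
    *,
    father: str = "FATHER",
    mother: str = "MOTHER",
    proband: str = "PROBAND",
) -> pd.DataFrame:
    """Classify trio sites within ``flank`` bp of the locus as IFF/IFM.

    A site qualifies when exactly one parent is heterozygous, the other
    is homozygous (or hemizygous), both are called, and the proband's
    genotype permits an unambiguous transmission inference.  The
    pathogenic variant sites themselves are excluded (they are the
    phasing anchors, not voters).  Returns a DataFrame with one row per
    informative SNP; ``distance`` is signed (negative = upstream of the
    locus anchor).
    """
    sites = table.sites
    gt_f, gt_m, gt_p = table.gt(father), table.gt(mother), table.gt(proband)
    proband_haploid = table.sample_haploid(proband)
    patho = set(locus.pathogenic_positions.values())

    pos = sites["pos"].values.astype(np.int64)
    dist = pos - int(locus.position)
    in_window = (
        (sites["chrom"].values == locus.chrom)
        & (np.abs(dist) <= flank)
        & ~np.isin(pos, list(patho))
    )

    rows: list[tuple] = []
    for i in np.flatnonzero(in_window):
        f, m, p = int(gt_f[i]), int(gt_m[i]), int(gt_p[i])
        if p == int(Genotype.MISSING):
            continue
        father_het = f == int(Genotype.HET)
        mother_het = m == int(Genotype.HET)
        if proband_haploid:
            # male X proband: only the maternal chromosome was transmitted,
            # so only IFM sites are informative and the father's genotype
            # places no constraint on the proband
            if not mother_het:
                continue
            t = _transmitted_to_haploid_child(p)
            if t is None:
                continue
            rows.append((i, IFM, -1, t))
            continue
        if father_het == mother_het:
            continue  # both het (ambiguous) or neither het (uninformative)
        if father_het:
            a = _hom_like_allele(m)
            origin = IFF
        else:
            a = _hom_like_allele(f)
            origin = IFM
        if a is None:
            continue
        t = _transmitted_to_diploid_child(p, a)
        if t is None:
            continue
        rows.append((i, origin, a, t))

    if not rows:
        return pd.DataFrame(columns=INFORMATIVE_COLUMNS)
    idx = np.asarray([r[0] for r in rows])
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"].values[idx],
            "pos": pos[idx],
            "ref": sites["ref"].values[idx],
            "alt": sites["alt"].values[idx],
            "origin": [r[1] for r in rows],
            "other_allele": np.asarray([r[2] for r in rows], dtype=np.int64),
            "proband_allele": np.asarray([r[3] for r in rows], dtype=np.int64),
            "distance": dist[idx],
        }
    )
    out["hap1_allele"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["key"] = False
    out["cell_allele"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out.reset_index(drop=True)


def proband_carries_pathogenic(
    table: GenotypeTable,
    locus: DiseaseLocus,
    parent: str,
    *,
    father: str = "FATHER",
    mother: str = "MOTHER",
    proband: str = "PROBAND",
) -> bool:
    """Whether the proband inherited ``parent``'s pathogenic (ALT) allele.

    Raises :class:`PhasingError` when the genotypes at the pathogenic
    site are missing or inconsistent with the stated carriage.
    """
    if parent not in locus.carrier_parents:
        raise PhasingError(f"{parent} is not a carrier at {locus.gene_name}")
    target = int(locus.pathogenic_positions[parent])
    idx = table.site_index().get((locus.chrom, target))
    if idx is None:
        raise PhasingError(
            f"pathogenic site {locus.chrom}:{target} absent from the genotype table"
        )
    carrier_sample = father if parent == "father" else mother
    other_sample = mother if parent == "father" else father
    carrier_gt = int(table.gt(carrier_sample)[idx])
    if carrier_gt != int(Genotype.HET):
        raise PhasingError(
            f"{parent} is not heterozygous at the pathogenic site "
            f"({Genotype(carrier_gt).name})"
        )
    p = int(table.gt(proband)[idx])
    if table.sample_haploid(proband):
        t = _transmitted_to_haploid_child(p)
    else:
        a = _hom_like_allele(int(table.gt(other_sample)[idx]))
        if a is None:
            raise PhasingError(
                "non-carrier parent is not homozygous at the pathogenic site"
            )
        t = _transmitted_to_diploid_child(p, a)
    if t is None:
        raise PhasingError(
            "proband genotype at the pathogenic site is missing or inconsistent"
        )
    return t == 1  # the pathogenic allele is the ALT allele


def phase_to_pathogenic(
    informative: pd.DataFrame,
    table: GenotypeTable,
    locus: DiseaseLocus,
    parent: str,
    *,
    father: str = "FATHER",
    mother: str = "MOTHER",
    proband: str = "PROBAND",
) -> pd.DataFrame:
    """Assign each of ``parent``'s informative SNPs an allele on haplotype 1.

    If the proband inherited the pathogenic allele, the alleles it
    received from that parent lie on haplotype 1 (the pathogenic one);
    otherwise they lie on haplotype 2 and haplotype 1 carries the
    complementary alleles.  No recombination is assumed inside the
    window (the single permitted proband crossover is taken to fall
    outside it; a crossover inside the window is undetectable with one
    proband and simply degrades the call).
    """
    carries = proband_carries_pathogenic(
        table, locus, parent, father=father, mother=mother, proband=proband
    )
    out = informative.copy()
    mask = out["origin"] == _PARENT_ORIGIN[parent]
    t = out.loc[mask, "proband_allele"].astype("Int64")
    out.loc[mask, "hap1_allele"] = t if carries else 1 - t
    out.attrs = dict(informative.attrs)
    out.attrs[f"proband_carries_{parent}"] = bool(carries)
    return out


def mark_key_snps(
    informative: pd.DataFrame,
    table: GenotypeTable,
    *,
    cell: str = "CELL",
    mode: str = "observed",
) -> pd.DataFrame:
    """Flag the informative SNPs whose cell observation is dropout-proof.

    ``mode="observed"`` (default): a site is key iff the cell's genotype
    contains the distinguishing allele (the one the other parent cannot
    supply); such an observation cannot arise from the competing
    transmission under any single-allele dropout.  Observations
    homozygous for the shared allele, and missing calls, are non-key.

    ``mode="trio"``: only missing calls are treated as dropout-affected;
    every called site is key, and a call homozygous for the shared
    allele votes for the shared-allele transmission.  This is the
    permissive trio-style alternative; it trades dropout robustness for
    vote count.

    For a hemizygous cell (male X) any non-missing call directly names
    the transmitted maternal allele and is key in both modes.
    """
    if mode not in ("observed", "trio"):
        raise ValueError("mode must be 'observed' or 'trio'")
    out = informative.copy()
    if len(out) == 0:
        return out
    index = table.site_index()
    gt_c = table.gt(cell)
    haploid = table.sample_haploid(cell)
    keys: list[bool] = []
    cell_alleles: list[object] = []
    for row in out.itertuples(index=False):
        i = index.get((row.chrom, int(row.pos)))
        code = int(gt_c[i]) if i is not None else int(Genotype.MISSING)
        if haploid:
            t = _transmitted_to_haploid_child(code)
            keys.append(t is not None)
            cell_alleles.append(t if t is not None else pd.NA)
            continue
        if code == int(Genotype.MISSING):
            keys.append(False)
            cell_alleles.append(pd.NA)
            continue
        b = 1 - int(row.other_allele)  # distinguishing allele
        contains_b = b in (
            (0, 1) if code == int(Genotype.HET)
            else (0, 0) if code == int(Genotype.HOM_REF)
            else (1, 1)
        )
        if mode == "observed":
            keys.append(contains_b)
            cell_alleles.append(b if contains_b else pd.NA)
        else:
            keys.append(True)
            cell_alleles.append(b if contains_b else int(row.other_allele))
    out["key"] = keys
    out["cell_allele"] = pd.array(cell_alleles, dtype="Int64")
    out.attrs = dict(informative.attrs)
    out.attrs["key_mode"] = mode
    return out


@dataclasses.dataclass
class HaplotypeCall:
    """Per-parent decision on which haplotype the fetal cell inherited."""

    parent: str
    label: int | None  # 1, 2, or None = ambiguous
    upstream_votes: tuple[int, int]  # (for haplotype 1, for haplotype 2)
    downstream_votes: tuple[int, int]
    recombination_flag: bool = False
    message: str = ""

    @property
    def is_ambiguous(self) -> bool:
        return self.label is None

    def to_dict(self) -> dict:
        return {
            "parent": self.parent,
            "label": self.label,
            "upstream_votes": list(self.upstream_votes),
            "downstream_votes": list(self.downstream_votes),
            "recombination_flag": self.recombination_flag,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HaplotypeCall":
        return cls(
            parent=d["parent"],
            label=d["label"],
            upstream_votes=tuple(d["upstream_votes"]),
            downstream_votes=tuple(d["downstream_votes"]),
            recombination_flag=bool(d.get("recombination_flag", False)),
            message=d.get("message", ""),
        )


def _flank_decision(
    n1: int, n2: int, vote_threshold: float, min_key_snps: int
) -> int | None:
    total = n1 + n2
    if total < max(min_key_snps, 1) or n1 == n2:
        return None
    frac = max(n1, n2) / total
    if frac < vote_threshold:
        return None
    return 1 if n1 > n2 else 2


def call_fetal_haplotype(
    informative: pd.DataFrame,
    parent: str,
    *,
    vote_threshold: float = 0.8,
    min_key_snps: int = 1,
) -> HaplotypeCall:
    """Vote the fetal haplotype of ``parent`` from phased, keyed SNPs.

    Each key SNP votes for haplotype 1 when the allele it identified in
    the cell equals that site's haplotype-1 allele, else for haplotype
    2.  Each flank (upstream / downstream of the locus anchor) decides
    by majority with vote fraction >= ``vote_threshold`` and at least
    ``min_key_snps`` votes; the call is the common flank decision.
    Discordant flank decisions raise the recombination flag and leave
    the call ambiguous.
    """
    rows = informative[
        (informative["origin"] == _PARENT_ORIGIN[parent])
        & informative["key"]
        & informative["hap1_allele"].notna()
        & informative["cell_allele"].notna()
    ]
    vote1 = rows["cell_allele"].astype(int) == rows["hap1_allele"].astype(int)
    upstream = rows["distance"].astype(int) <= 0
    u1 = int((vote1 & upstream).sum())
    u2 = int((~vote1 & upstream).sum())
    d1 = int((vote1 & ~upstream).sum())
    d2 = int((~vote1 & ~upstream).sum())
    up = _flank_decision(u1, u2, vote_threshold, min_key_snps)
    dn = _flank_decision(d1, d2, vote_threshold, min_key_snps)
    if up is None or dn is None:
        which = [name for name, dec in (("upstream", up), ("downstream", dn)) if dec is None]
        return HaplotypeCall(
            parent=parent,
            label=None,
            upstream_votes=(u1, u2),
            downstream_votes=(d1, d2),
            message=f"indecisive flank(s): {', '.join(which)}",
        )
    if up != dn:
        return HaplotypeCall(
            parent=parent,
            label=None,
            upstream_votes=(u1, u2),
            downstream_votes=(d1, d2),
            recombination_flag=True,
            message=(
                f"flank discordance (upstream -> {up}, downstream -> {dn}); "
                "possible fetal recombination near the locus"
            ),
        )
    return HaplotypeCall(
        parent=parent,
        label=up,
        upstream_votes=(u1, u2),
        downstream_votes=(d1, d2),
    )


VERDICTS = ("affected", "carrier_paternal", "carrier_maternal", "normal", "ambiguous")


@dataclasses.dataclass
class Verdict:
    """Diagnostic verdict derived from the per-parent haplotype calls."""

    value: str
    basis: dict[str, HaplotypeCall]

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "basis": {k: v.to_dict() for k, v in self.basis.items()},
        }


def derive_verdict(
    paternal: HaplotypeCall | None,
    maternal: HaplotypeCall | None,
    locus: DiseaseLocus,
    fetal_sex: str = "female",
) -> Verdict:
    """Map haplotype calls to affected / carrier / normal / ambiguous.

    Autosomal recessive with two carriers follows the P1/M1 affected,
    P1/M2 carrier-paternal, P2/M1 carrier-maternal, P2/M2 normal table.
    Autosomal dominant: inheriting any carrier parent's haplotype 1 is
    affected.  X-linked (carrier mother): a male fetus is affected by M1
    and normal with M2; a female fetus carrying M1 is a carrier.  Any
    required call that is ambiguous makes the verdict ambiguous; a
    required call that is absent raises ``ValueError``.
    """
    mode = locus.inheritance_mode
    calls: dict[str, HaplotypeCall] = {}
    required: list[str] = []
    if mode == "x_linked":
        required = ["mother"]
    else:
        required = list(locus.carrier_parents)
    provided = {"father": paternal, "mother": maternal}
    for parent in required:
        call = provided[parent]
        if call is None:
            raise ValueError(f"missing required haplotype call for {parent}")
        calls[parent] = call
    # carry non-required calls through for reporting
    for parent, call in provided.items():
        if call is not None:
            calls.setdefault(parent, call)

    if any(calls[p].is_ambiguous for p in required):
        return Verdict(value="ambiguous", basis=calls)

    if mode == "x_linked":
        m1 = calls["mother"].label == 1
        if fetal_sex == "male":
            value = "affected" if m1 else "normal"
        else:
            value = "carrier_maternal" if m1 else "normal"
        return Verdict(value=value, basis=calls)

    pat1 = "father" in required and calls["father"].label == 1
    mat1 = "mother" in required and calls["mother"].label == 1
    if mode == "autosomal_dominant":
        value = "affected" if (pat1 or mat1) else "normal"
    else:  # autosomal recessive
        if pat1 and mat1:
            value = "affected"
        elif pat1:
            value = "carrier_paternal"
        elif mat1:
            value = "carrier_maternal"
        else:
            value = "normal"
    return Verdict(value=value, basis=calls)
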