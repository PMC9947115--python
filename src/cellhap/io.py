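"""Genotype containers, the depth-based genotype caller, and VCF/BED I/O.

Every stage of the pipeline exchanges data through :class:`GenotypeTable`,
a multi-sample matrix of biallelic SNP calls with per-allele read depths,
and :class:`RegionSet`, a named collection of genomic intervals (gene
panels, exome, OMIM regions).  The genotype caller is a deliberately
simple surrogate for a reads-based pipeline: a site is callable only when
its total depth strictly exceeds ``min_depth`` (mirroring the "coverage
> 10" filter used for single-cell data), and heterozygosity requires both
alleles to reach ``min_alt_fraction`` of the site depth.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam


class Genotype(enum.IntEnum):
    """Diploid or hemizygous genotype call at a biallelic SNP."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    HEM_REF = 3
    HEM_ALT = 4


#: diploid genotype codes
DIPLOID_CODES = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
#: hemizygous genotype codes (single X in a male)
HAPLOID_CODES = (Genotype.HEM_REF, Genotype.HEM_ALT)
#: codes that count as homozygous for ADO purposes
HOM_CODES = (Genotype.HOM_REF, Genotype.HOM_ALT)
#: codes a "non-AB" (not heterozygous, informative-SNP sense) parent may carry
HOM_LIKE_CODES = (Genotype.HOM_REF, Genotype.HOM_ALT, Genotype.HEM_REF, Genotype.HEM_ALT)

_DIPLOID_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
_HAPLOID_GT_STR = {-1: ".", 3: "0", 4: "1"}


def genotype_alleles(code: int) -> tuple[int, ...]:
    """Allele indices (0=ref, 1=alt) carried by a genotype code; () if missing."""
    return {
        Genotype.MISSING: (),
        Genotype.HOM_REF: (0, 0),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1, 1),
        Genotype.HEM_REF: (0,),
        Genotype.HEM_ALT: (1,),
    }[Genotype(code)]


def call_genotypes(
    allele_depths: np.ndarray,
    *,
    min_depth: int = 10,
    min_alt_fraction: float = 0.2,
    haploid: bool = False,
) -> np.ndarray:
    """Vectorised genotype caller from (n, 2) ref/alt read counts.

    A site is missing unless its total depth is strictly greater than
    ``min_depth``.  Diploid calls are heterozygous when both alleles reach
    ``min_alt_fraction`` of the total, otherwise homozygous for the
    majority allele (ties are heterozygous, since equal halves always
    reach any fraction <= 0.5).  Hemizygous samples are called for the
    majority allele; a tie falls to the reference allele.
    """
    ad = np.asarray(allele_depths, dtype=np.int64).reshape(-1, 2)
    if (ad < 0).any():
        raise ValueError("allele depths must be non-negative")
    total = ad.sum(axis=1)
    out = np.full(ad.shape[0], int(Genotype.MISSING), dtype=np.int8)
    ok = total > min_depth
    if not ok.any():
        return out
    ref, alt = ad[ok, 0], ad[ok, 1]
    if haploid:
        out[ok] = np.where(ref >= alt, int(Genotype.HEM_REF), int(Genotype.HEM_ALT))
    else:
        t = total[ok].astype(float)
        both = (ref >= min_alt_fraction * t) & (alt >= min_alt_fraction * t)
        hom = np.where(ref >= alt, int(Genotype.HOM_REF), int(Genotype.HOM_ALT))
        out[ok] = np.where(both, int(Genotype.HET), hom)
    return out


def call_genotype(
    allele_depths: Sequence[int],
    min_depth: int = 10,
    min_alt_fraction: float = 0.2,
    haploid: bool = False,
) -> Genotype:
    """Scalar convenience wrapper around :func:`call_genotypes`."""
    code = call_genotypes(
        np.asarray(allele_depths).reshape(1, 2),
        min_depth=min_depth,
        min_alt_fraction=min_alt_fraction,
        haploid=haploid,
    )[0]
    return Genotype(int(code))


@dataclasses.dataclass
class GenotypeTable:
    """Multi-sample genotype matrix over an ordered list of biallelic SNPs.

    Attributes
    ----------
    sites : DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    genotypes : mapping sample -> (n,) int8 array of :class:`Genotype` codes.
    depths : mapping sample -> (n, 2) int array of (ref, alt) read counts.
    haploid : mapping sample -> bool, True for hemizygous samples (male X).
    n_excluded : records skipped on read (multiallelic / non-SNP).
    """

    sites: pd.DataFrame
    genotypes: dict[str, np.ndarray]
    depths: dict[str, np.ndarray]
    haploid: dict[str, bool] = dataclasses.field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        n = len(self.sites)
        for s, g in self.genotypes.items():
            if len(g) != n:
                raise ValueError(f"genotype array for {s!r} has wrong length")
            if s not in self.depths:
                raise ValueError(f"no depths for sample {s!r}")
            if np.asarray(self.depths[s]).shape != (n, 2):
                raise ValueError(f"depth array for {s!r} must be (n, 2)")
        for s in self.genotypes:
            self.haploid.setdefault(s, False)

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def gt(self, sample: str) -> np.ndarray:
        return self.genotypes[sample]

    def ad(self, sample: str) -> np.ndarray:
        return self.depths[sample]

    def total_depth(self, sample: str) -> np.ndarray:
        return np.asarray(self.depths[sample]).sum(axis=1)

    def sample_haploid(self, sample: str) -> bool:
        return bool(self.haploid.get(sample, False))

    def site_index(self) -> dict[tuple[str, int], int]:
        """Mapping (chrom, pos) -> row index."""
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.sites["chrom"], self.sites["pos"]))
        }

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            sites=self.sites.copy(),
            genotypes={s: g.copy() for s, g in self.genotypes.items()},
            depths={s: d.copy() for s, d in self.depths.items()},
            haploid=dict(self.haploid),
            n_excluded=self.n_excluded,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-site export: one row per site, genotype/depth columns per sample."""
        out = self.sites.copy()
        for s in self.samples:
            out[f"{s}_gt"] = [Genotype(int(g)).name for g in self.genotypes[s]]
            ad = np.asarray(self.depths[s])
            out[f"{s}_dp"] = ad.sum(axis=1)
            out[f"{s}_ad"] = [f"{r},{a}" for r, a in ad]
        return out

    def write_vcf(self, path: str | Path) -> None:
        """Write a minimal multi-sample VCF v4.2 with GT/DP/AD fields."""
        path = Path(path)
        samples = self.samples
        lines = [
            "##fileformat=VCFv4.2",
            "##source=cellhap",
        ]
        for chrom in pd.unique(self.sites["chrom"]):
            lines.append(f"##contig=<ID={chrom},length=400000000>")
        lines += [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        ]
        gts = {s: self.genotypes[s] for s in samples}
        ads = {s: np.asarray(self.depths[s]) for s in samples}
        for i, row in enumerate(self.sites.itertuples(index=False)):
            fields = [
                str(row.chrom), str(int(row.pos)), ".", str(row.ref), str(row.alt),
                ".", "PASS", ".", "GT:DP:AD",
            ]
            for s in samples:
                code = int(gts[s][i])
                gt_str = (_HAPLOID_GT_STR if self.haploid.get(s) else _DIPLOID_GT_STR).get(
                    code, "./."
                )
                r, a = int(ads[s][i, 0]), int(ads[s][i, 1])
                fields.append(f"{gt_str}:{r + a}:{r},{a}")
            lines.append("\t".join(fields))
        path.write_text("\n".join(lines) + "\n")


def merge_tables(a: GenotypeTable, b: GenotypeTable) -> GenotypeTable:
    """Combine the samples of two tables defined over identical site lists."""
    if len(a.sites) != len(b.sites) or not (
        (a.sites["chrom"].values == b.sites["chrom"].values).all()
        and (a.sites["pos"].values == b.sites["pos"].values).all()
    ):
        raise ValueError("tables must share an identical site list")
    overlap = set(a.samples) & set(b.samples)
    if overlap:
        raise ValueError(f"duplicate samples: {sorted(overlap)}")
    return GenotypeTable(
        sites=a.sites.copy(),
        genotypes={**{s: g.copy() for s, g in a.genotypes.items()},
                   **{s: g.copy() for s, g in b.genotypes.items()}},
        depths={**{s: d.copy() for s, d in a.depths.items()},
                **{s: d.copy() for s, d in b.depths.items()}},
        haploid={**a.haploid, **b.haploid},
        n_excluded=a.n_excluded + b.n_excluded,
    )


def read_family_vcf(
    path: str | Path,
    sample_roles: Mapping[str, str] | None = None,
) -> GenotypeTable:
    """Read a multi-sample VCF into a :class:`GenotypeTable`.

    Only biallelic single-nucleotide records are kept; multiallelic and
    indel records are skipped and counted in ``n_excluded``.  Half calls
    (e.g. ``0/.``) are treated as missing.

    Parameters
    ----------
    sample_roles
        Optional mapping from a role name (e.g. ``"FATHER"``) to the VCF
        sample name carrying that role; the returned table is keyed by
        role.  A role absent from the file raises ``ValueError``.
    """
    vf = pysam.VariantFile(str(path))
    file_samples = list(vf.header.samples)
    if sample_roles is not None:
        missing = [s for s in sample_roles.values() if s not in file_samples]
        if missing:
            raise ValueError(f"samples not in VCF: {missing}")
        columns = dict(sample_roles)  # role -> file sample
    else:
        columns = {s: s for s in file_samples}

    rows: list[tuple[str, int, str, str]] = []
    gts: dict[str, list[int]] = {r: [] for r in columns}
    ads: dict[str, list[tuple[int, int]]] = {r: [] for r in columns}
    ploidies: dict[str, set[int]] = {r: set() for r in columns}
    n_excluded = 0
    for rec in vf:
        alts = rec.alts or ()
        if (
            len(alts) != 1
            or len(rec.ref) != 1
            or len(alts[0]) != 1
            or rec.ref not in "ACGT"
            or alts[0] not in "ACGT"
        ):
            n_excluded += 1
            continue
        rows.append((rec.chrom, rec.pos, rec.ref, alts[0]))
        for role, sample in columns.items():
            sg = rec.samples[sample]
            gt = sg.get("GT") or (None,)
            ploidies[role].add(len(gt))
            called = [x for x in gt if x is not None]
            if len(gt) == 1:
                code = (
                    Genotype.MISSING
                    if not called
                    else (Genotype.HEM_ALT if called[0] else Genotype.HEM_REF)
                )
            elif len(called) < len(gt):
                code = Genotype.MISSING
            else:
                code = Genotype(sum(called))
            ad = sg.get("AD")
            if ad is None or any(x is None for x in ad):
                ad = (0, 0)
            gts[role].append(int(code))
            ads[role].append((int(ad[0]), int(ad[1])))
    vf.close()

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeTable(
        sites=sites,
        genotypes={r: np.asarray(v, dtype=np.int8) for r, v in gts.items()},
        depths={r: np.asarray(v, dtype=np.int64).reshape(len(rows), 2) for r, v in ads.items()},
        haploid={r: ploidies[r] == {1} for r in columns},
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# genomic regions


@dataclasses.dataclass
class RegionSet:
    """Named set of genomic intervals (BED convention: 0-based, half-open)."""

    name: str
    regions: pd.DataFrame  # columns: chrom, start, end, gene

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end"}
        if not req.issubset(self.regions.columns):
            raise ValueError(f"regions need columns {sorted(req)}")
        if "gene" not in self.regions.columns:
            self.regions = self.regions.assign(
                gene=[f"{self.name}_{i}" for i in range(len(self.regions))]
            )
        if (self.regions["end"] < self.regions["start"]).any():
            raise ValueError("intervals must have non-negative length")

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene"],
        )
        return cls(name=name or Path(path).stem, regions=df)

    def to_bed(self, path: str | Path) -> None:
        self.regions[["chrom", "start", "end", "gene"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @property
    def n_genes(self) -> int:
        return self.regions["gene"].nunique()

    def merged(self) -> dict[str, np.ndarray]:
        """Per-chromosome merged intervals as (k, 2) arrays."""
        return {
            chrom: _merge_intervals(grp[["start", "end"]].to_numpy())
            for chrom, grp in self.regions.groupby("chrom")
        }

    def total_length(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.merged().values())
        )


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge possibly overlapping half-open intervals; returns sorted (k, 2)."""
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _as_interval_map(regions) -> dict[str, np.ndarray]:
    if isinstance(regions, RegionSet):
        return regions.merged()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    return {c: _merge_intervals(np.asarray(v)) for c, v in by_chrom.items()}


def region_overlap(
    covered: "RegionSet | Iterable[tuple[str, int, int]]", panel: RegionSet
) -> float:
    """Fraction of the panel covered: overlapped bases / total panel bases."""
    panel_iv = panel.merged()
    total = sum((iv[:, 1] - iv[:, 0]).sum() for iv in panel_iv.values())
    if total == 0:
        raise ValueError("panel has zero total length")
    cov_iv = _as_interval_map(covered)
    inter = 0
    for chrom, piv in panel_iv.items():
        civ = cov_iv.get(chrom)
        if civ is None or len(civ) == 0:
            continue
        # clip every covered interval against every panel interval via
        # searchsorted windows; interval counts here are small
        for s, e in piv:
            lo = np.minimum(np.maximum(civ[:, 0], s), e)
            hi = np.minimum(civ[:, 1], e)
            inter += int(np.maximum(hi - lo, 0).sum())
    return float(inter) / float(total)
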