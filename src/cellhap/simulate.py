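"""Synthetic families, fetal single cells, depth tracks and STR profiles.

The generator emulates the data a cell-based noninvasive prenatal test
consumes: a nuclear family (father, mother, affected proband) genotyped
from gDNA, a candidate circulating trophoblast cell genotyped from
whole-genome-amplified single-cell DNA, and an optional reference sample
(amniotic fluid / villi surrogate) equal to the true fetal genotypes.

The family model is deliberately minimal but fully Mendelian:

* biallelic SNPs scattered over a window centred on a disease locus,
  with per-site minor-allele frequencies drawn uniformly;
* each parental chromosome is an explicit haplotype; haplotype 1 of a
  carrier parent is the one bearing the pathogenic allele;
* each meiosis transmits one parental haplotype with at most one
  crossover at a uniform breakpoint;
* the proband is constrained to be affected (it inherited the
  pathogenic haplotype from every carrier parent), which is what anchors
  the downstream phasing;
* the single cell is observed through a whole-genome-amplification
  artifact model: per-allele dropout, per-site depth sampling, and a
  genotype-level false-positive overlay.

Dropout reassigns the full site depth to the surviving allele (the WGA
reaction amplifies whatever template survived), so the probability that
a truly heterozygous, successfully called site appears homozygous is
exactly ``2d/(1+d)`` for per-allele dropout rate ``d`` — the closed form
the QC module inverts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Genotype, GenotypeTable, call_genotypes
from .str_confirm import AMELOGENIN, DEFAULT_STR_PANEL, StrProfile

INHERITANCE_MODES = ("autosomal_recessive", "autosomal_dominant", "x_linked")
MEMBERS = ("father", "mother", "proband", "fetus")


class ConfigurationError(ValueError):
    """Invalid simulation or disease-locus configuration."""


@dataclasses.dataclass
class DiseaseLocus:
    """A monogenic disease locus anchoring the haplotype analysis.

    ``position`` is the anchor coordinate splitting the window into an
    upstream and a downstream flank.  Each carrier parent has its own
    pathogenic variant site in ``pathogenic_positions`` (a compound
    heterozygous family has two distinct sites); by default a single
    carrier's variant sits at the anchor itself, and a two-carrier family
    places the paternal and maternal variants 1 kb either side of the
    anchor, since one biallelic site cannot hold a carrier-het variant
    for both parents while the other parent stays homozygous.

    The pathogenic allele is the ALT allele at the parent's variant site,
    carried on that parent's haplotype 1.
    """

    gene_name: str
    chrom: str
    position: int
    inheritance_mode: str
    carrier_parents: tuple[str, ...] = ("father", "mother")
    pathogenic_positions: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.inheritance_mode not in INHERITANCE_MODES:
            raise ConfigurationError(
                f"unknown inheritance mode {self.inheritance_mode!r}"
            )
        self.carrier_parents = tuple(self.carrier_parents)
        if not self.carrier_parents or not set(self.carrier_parents) <= {
            "father",
            "mother",
        }:
            raise ConfigurationError(
                "carrier_parents must be a non-empty subset of {'father', 'mother'}"
            )
        if self.inheritance_mode == "x_linked":
            if "father" in self.carrier_parents:
                # a hemizygous father cannot be a heterozygous carrier
                raise ConfigurationError(
                    "x_linked carrier father is out of scope (hemizygous)"
                )
        if self.pathogenic_positions is None:
            if len(self.carrier_parents) == 1:
                self.pathogenic_positions = {self.carrier_parents[0]: self.position}
            else:
                self.pathogenic_positions = {
                    "father": self.position - 1000,
                    "mother": self.position + 1000,
                }
        missing = set(self.carrier_parents) - set(self.pathogenic_positions)
        if missing:
            raise ConfigurationError(f"no pathogenic position for {sorted(missing)}")

    def to_dict(self) -> dict:
        return {
            "gene_name": self.gene_name,
            "chrom": self.chrom,
            "position": self.position,
            "inheritance_mode": self.inheritance_mode,
            "carrier_parents": list(self.carrier_parents),
            "pathogenic_positions": dict(self.pathogenic_positions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiseaseLocus":
        d = dict(d)
        if d.get("pathogenic_positions") is not None:
            d["pathogenic_positions"] = {
                k: int(v) for k, v in d["pathogenic_positions"].items()
            }
        d["carrier_parents"] = tuple(d.get("carrier_parents", ("father", "mother")))
        return cls(**d)


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic family and its single cell.

    Defaults follow the sequencing design being emulated: a ~4 Mb window
    (2 Mb per flank) around the disease gene, ~15x mean single-cell
    depth, gDNA samples at ~30x, a strict coverage > ``min_call_depth``
    caller, and per-site minor-allele frequencies uniform on
    (0.05, ``minor_allele_freq``).
    """

    n_snps: int = 600
    region_span: int = 4_000_000
    minor_allele_freq: float = 0.5
    mean_depth: float = 15.0
    ado_rate: float = 0.0
    fp_rate: float = 0.0
    min_call_depth: int = 10
    min_alt_fraction: float = 0.2
    inheritance_mode: str = "autosomal_recessive"
    fetal_sex: str = "female"
    proband_sex: str = "male"
    crossover_prob: float = 0.04
    depth_dispersion: float | None = None  # negative-binomial size; None = Poisson
    gdna_depth: float = 30.0
    seed: int = 0
    # force the fetal transmission at the disease locus (None = random draw)
    fetal_paternal_hap: int | None = None
    fetal_maternal_hap: int | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 10:
            raise ConfigurationError("n_snps must be >= 10")
        if self.region_span <= 0:
            raise ConfigurationError("region_span must be positive")
        for name in ("ado_rate", "fp_rate", "crossover_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.0 < self.minor_allele_freq <= 0.5:
            raise ConfigurationError("minor_allele_freq must be in (0, 0.5]")
        if self.inheritance_mode not in INHERITANCE_MODES:
            raise ConfigurationError(
                f"unknown inheritance mode {self.inheritance_mode!r}"
            )
        for name in ("fetal_sex", "proband_sex"):
            if getattr(self, name) not in ("male", "female"):
                raise ConfigurationError(f"{name} must be 'male' or 'female'")
        for name in ("fetal_paternal_hap", "fetal_maternal_hap"):
            v = getattr(self, name)
            if v is not None and v not in (1, 2):
                raise ConfigurationError(f"{name} must be 1, 2 or None")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


def default_locus(config: SimulationConfig) -> DiseaseLocus:
    """A representative locus for the configured inheritance mode."""
    if config.inheritance_mode == "x_linked":
        return DiseaseLocus(
            gene_name="GENE_X",
            chrom="chrX",
            position=100_000_000,
            inheritance_mode="x_linked",
            carrier_parents=("mother",),
        )
    carriers = (
        ("father", "mother")
        if config.inheritance_mode == "autosomal_recessive"
        else ("father",)
    )
    return DiseaseLocus(
        gene_name="GENE_A",
        chrom="chr7",
        position=100_000_000,
        inheritance_mode=config.inheritance_mode,
        carrier_parents=carriers,
    )


@dataclasses.dataclass
class FamilyTruth:
    """Fully known simulated family: haplotypes, meioses, and the locus.

    ``paternal_haplotypes`` / ``maternal_haplotypes`` are (2, n) 0/1
    arrays (row h-1 is haplotype h; a hemizygous father's single X is
    duplicated across both rows so transmission indexing stays uniform).
    ``proband_transmissions`` and ``fetal_transmissions`` map
    ``"paternal"``/``"maternal"`` to (n,) arrays of 1/2, or ``None``
    where no chromosome is transmitted (paternal X to a male child).
    """

    sites: pd.DataFrame
    paternal_haplotypes: np.ndarray
    maternal_haplotypes: np.ndarray
    proband_transmissions: dict[str, np.ndarray | None]
    fetal_transmissions: dict[str, np.ndarray | None]
    crossovers: dict[str, float | None]
    locus: DiseaseLocus
    config: SimulationConfig

    # -- ploidy helpers ----------------------------------------------------
    @property
    def x_linked(self) -> bool:
        return self.locus.inheritance_mode == "x_linked"

    def member_haploid(self, member: str) -> bool:
        if not self.x_linked:
            return False
        sex = {
            "father": "male",
            "mother": "female",
            "proband": self.config.proband_sex,
            "fetus": self.config.fetal_sex,
        }[member]
        return sex == "male"

    # -- derived genotypes -------------------------------------------------
    def member_alleles(self, member: str) -> np.ndarray:
        """(n, k) array of allele indices; k=1 for hemizygous members."""
        n = len(self.sites)
        idx = np.arange(n)
        if member == "father":
            if self.member_haploid("father"):
                return self.paternal_haplotypes[0][:, None]
            return self.paternal_haplotypes.T.copy()
        if member == "mother":
            return self.maternal_haplotypes.T.copy()
        trans = (
            self.proband_transmissions
            if member == "proband"
            else self.fetal_transmissions
        )
        cols = []
        if trans["paternal"] is not None:
            cols.append(self.paternal_haplotypes[trans["paternal"] - 1, idx])
        if trans["maternal"] is not None:
            cols.append(self.maternal_haplotypes[trans["maternal"] - 1, idx])
        return np.stack(cols, axis=1)

    def member_genotypes(self, member: str) -> np.ndarray:
        """(n,) array of :class:`Genotype` codes for the true genotypes."""
        alleles = self.member_alleles(member)
        if alleles.shape[1] == 1:
            return np.where(
                alleles[:, 0] == 1, int(Genotype.HEM_ALT), int(Genotype.HEM_REF)
            ).astype(np.int8)
        return alleles.sum(axis=1).astype(np.int8)

    def to_genotype_table(
        self,
        samples: Sequence[str] = ("FATHER", "MOTHER", "PROBAND"),
        include_reference: bool = True,
        rng: np.random.Generator | None = None,
    ) -> GenotypeTable:
        """Clean gDNA-style table for the family (and a REFERENCE fetal sample).

        gDNA depths are Poisson around ``gdna_depth`` but floored above the
        caller threshold, and allele depths are split deterministically in
        proportion to the true allele copies, so gDNA genotypes are exact:
        all sampling-noise modelling lives in the single cell.
        """
        if rng is None:
            rng = np.random.default_rng([max(self.config.seed, 0), 3])
        roles = {"FATHER": "father", "MOTHER": "mother", "PROBAND": "proband"}
        wanted = {s: roles[s] for s in samples}
        if include_reference:
            wanted["REFERENCE"] = "fetus"
        n = len(self.sites)
        genotypes, depths, haploid = {}, {}, {}
        for sample, member in wanted.items():
            alleles = self.member_alleles(member)
            k = alleles.shape[1]
            dp = rng.poisson(self.config.gdna_depth, size=n)
            dp = np.maximum(dp, self.config.min_call_depth + 1)
            n_ref = (alleles == 0).sum(axis=1)
            ad_ref = np.rint(dp * n_ref / k).astype(np.int64)
            depths[sample] = np.stack([ad_ref, dp - ad_ref], axis=1)
            genotypes[sample] = self.member_genotypes(member)
            haploid[sample] = k == 1
        return GenotypeTable(
            sites=self.sites.copy(),
            genotypes=genotypes,
            depths=depths,
            haploid=haploid,
        )

    def site_index_of(self, pos: int) -> int:
        hits = np.flatnonzero(self.sites["pos"].values == pos)
        if len(hits) != 1:
            raise KeyError(f"position {pos} not uniquely present")
        return int(hits[0])


def _draw_meiosis(
    rng: np.random.Generator,
    positions: np.ndarray,
    crossover_prob: float,
    force_idx: int | None = None,
    force_hap: int | None = None,
) -> tuple[np.ndarray, float | None]:
    """One meiosis: transmitted haplotype index (1/2) per site, <=1 crossover.

    If ``force_idx`` is given, the labels are flipped wholesale when
    needed so that ``trans[force_idx] == force_hap``; this conditions the
    draw without disturbing the crossover structure.
    """
    start = int(rng.integers(1, 3))
    breakpoint_ = None
    if rng.random() < crossover_prob:
        breakpoint_ = float(rng.uniform(positions[0], positions[-1]))
    trans = np.full(len(positions), start, dtype=np.int8)
    if breakpoint_ is not None:
        trans[positions > breakpoint_] = 3 - start
    if force_idx is not None and trans[force_idx] != force_hap:
        trans = (3 - trans).astype(np.int8)
    return trans, breakpoint_


def simulate_family(
    config: SimulationConfig, locus: DiseaseLocus | None = None
) -> FamilyTruth:
    """Draw a family consistent with ``config`` (and ``locus``, if given).

    The proband always inherits the pathogenic haplotype from every
    carrier parent (it is the affected child anchoring the phasing); the
    fetal meioses are free unless forced via the config.
    """
    if locus is None:
        locus = default_locus(config)
    if locus.inheritance_mode != config.inheritance_mode:
        raise ConfigurationError(
            "locus inheritance mode does not match the simulation config"
        )
    rng = np.random.default_rng([max(config.seed, 0), 0])

    half = config.region_span // 2
    lo, hi = locus.position - half, locus.position + half
    patho_pos = {p: int(locus.pathogenic_positions[p]) for p in locus.carrier_parents}
    for p, pos in patho_pos.items():
        if not lo <= pos <= hi:
            raise ConfigurationError(
                f"pathogenic position for {p} lies outside the simulated window"
            )
    pool = np.unique(rng.integers(lo, hi + 1, size=config.n_snps * 3))
    pool = pool[~np.isin(pool, list(patho_pos.values()))]
    if len(pool) < config.n_snps:
        raise ConfigurationError("region too small for the requested SNP count")
    positions = np.sort(
        np.concatenate(
            [
                rng.choice(pool, size=config.n_snps, replace=False),
                np.asarray(sorted(patho_pos.values()), dtype=np.int64),
            ]
        )
    )
    n = len(positions)

    base_pairs = np.array(["A/G", "C/T", "G/A", "T/C", "A/C", "G/T"])
    pairs = rng.choice(base_pairs, size=n)
    refs = np.array([p[0] for p in pairs])
    alts = np.array([p[2] for p in pairs])
    sites = pd.DataFrame(
        {"chrom": locus.chrom, "pos": positions.astype(np.int64), "ref": refs, "alt": alts}
    )

    maf_lo = min(0.05, config.minor_allele_freq / 2)
    mafs = rng.uniform(maf_lo, config.minor_allele_freq, size=n)
    pat = (rng.random((2, n)) < mafs).astype(np.int8)
    mat = (rng.random((2, n)) < mafs).astype(np.int8)

    father_haploid = locus.inheritance_mode == "x_linked"
    if father_haploid:
        pat[1] = pat[0]

    # plant the pathogenic variants: carrier het with ALT on haplotype 1,
    # the other parent homozygous reference
    patho_idx: dict[str, int] = {}
    for parent, pos in patho_pos.items():
        i = int(np.flatnonzero(positions == pos)[0])
        patho_idx[parent] = i
        mine, other = (pat, mat) if parent == "father" else (mat, pat)
        mine[0, i], mine[1, i] = 1, 0
        other[:, i] = 0

    proband_haploid = father_haploid and config.proband_sex == "male"
    fetal_haploid = father_haploid and config.fetal_sex == "male"

    crossovers: dict[str, float | None] = {}

    def meiosis(parent: str, child: str, force_hap: int | None) -> np.ndarray:
        force_idx = patho_idx.get(parent) if force_hap is not None else None
        if force_idx is None and force_hap is not None:
            # forcing a non-carrier parent: anchor at the site nearest the locus
            force_idx = int(np.argmin(np.abs(positions - locus.position)))
        trans, bp = _draw_meiosis(
            rng, positions, config.crossover_prob, force_idx, force_hap
        )
        crossovers[f"{child}_{parent}"] = bp
        return trans

    proband_trans: dict[str, np.ndarray | None] = {
        "paternal": None
        if proband_haploid
        else (
            np.ones(n, dtype=np.int8)
            if father_haploid
            else meiosis("father", "proband", 1 if "father" in patho_idx else None)
        ),
        "maternal": meiosis("mother", "proband", 1 if "mother" in patho_idx else None),
    }
    fetal_trans: dict[str, np.ndarray | None] = {
        "paternal": None
        if fetal_haploid
        else (
            np.ones(n, dtype=np.int8)
            if father_haploid
            else meiosis("father", "fetus", config.fetal_paternal_hap)
        ),
        "maternal": meiosis("mother", "fetus", config.fetal_maternal_hap),
    }

    return FamilyTruth(
        sites=sites,
        paternal_haplotypes=pat,
        maternal_haplotypes=mat,
        proband_transmissions=proband_trans,
        fetal_transmissions=fetal_trans,
        crossovers=crossovers,
        locus=locus,
        config=config,
    )


def _draw_site_depth(
    rng: np.random.Generator, mean: float, dispersion: float | None, n: int
) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    if dispersion is None:
        return rng.poisson(mean, size=n)
    # negative binomial with mean `mean` and size (shape) `dispersion`
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def observe_single_cell(
    truth: FamilyTruth,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    sample: str = "CELL",
) -> GenotypeTable:
    """Observe the fetus through the whole-genome-amplification artifact model.

    Per site: total depth is drawn from a Poisson (or negative-binomial)
    distribution with mean ``mean_depth``; each true allele copy drops
    independently with probability ``ado_rate``; reads are split
    binomially among surviving copies; the genotype is called with the
    strict-threshold caller; finally, with probability ``fp_rate`` a
    called genotype is replaced by a uniformly chosen different genotype
    (allele depths are left untouched — the false-positive overlay is a
    call-level error).  Sites where every copy dropped, or whose depth
    fails the caller threshold, are missing.
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng([max(config.seed, 0), 1])
    alleles = truth.member_alleles("fetus")
    n, k = alleles.shape
    haploid = k == 1

    depth = _draw_site_depth(rng, config.mean_depth, config.depth_dispersion, n)
    dropped = rng.random(alleles.shape) < config.ado_rate
    surviving = (~dropped).sum(axis=1)
    ref_copies = ((alleles == 0) & ~dropped).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_frac = np.where(surviving > 0, ref_copies / np.maximum(surviving, 1), 0.0)
    eff_depth = np.where(surviving > 0, depth, 0)
    ad_ref = rng.binomial(eff_depth, ref_frac)
    ad = np.stack([ad_ref, eff_depth - ad_ref], axis=1).astype(np.int64)

    gt = call_genotypes(
        ad,
        min_depth=config.min_call_depth,
        min_alt_fraction=config.min_alt_fraction,
        haploid=haploid,
    )

    flip = (rng.random(n) < config.fp_rate) & (gt != int(Genotype.MISSING))
    if haploid:
        u = rng.integers(0, 1, size=n)  # drawn for stream stability; flip is forced
        gt = np.where(
            flip,
            np.where(gt == int(Genotype.HEM_REF), int(Genotype.HEM_ALT), int(Genotype.HEM_REF)),
            gt,
        ).astype(np.int8)
    else:
        u = rng.integers(0, 2, size=n)
        others = np.empty((n, 2), dtype=np.int8)
        for code, pair in ((0, (1, 2)), (1, (0, 2)), (2, (0, 1))):
            mask = gt == code
            others[mask, 0], others[mask, 1] = pair
        gt = np.where(flip, others[np.arange(n), u], gt).astype(np.int8)

    return GenotypeTable(
        sites=truth.sites.copy(),
        genotypes={sample: gt},
        depths={sample: ad},
        haploid={sample: haploid},
    )


def downsample_depth(
    table: GenotypeTable,
    target_depth: float,
    *,
    source_depth: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    min_depth: int = 10,
    min_alt_fraction: float = 0.2,
) -> GenotypeTable:
    """Binomially thin read counts to an expected mean of ``target_depth``.

    Every sample is thinned with fraction ``target / source`` (source
    defaulting to that sample's realised mean depth) and its genotypes
    are re-called with the simple caller.  A thinning fraction of 1
    returns the table unchanged (original calls preserved).  Targets
    above the source depth raise ``ValueError``.
    """
    if rng is None:
        rng = np.random.default_rng([max(seed, 0), 4])
    out = table.copy()
    for sample in table.samples:
        ad = np.asarray(table.depths[sample])
        src = float(source_depth) if source_depth is not None else float(ad.sum(axis=1).mean())
        if src <= 0:
            continue
        frac = float(target_depth) / src
        if frac > 1.0 + 1e-9:
            raise ValueError(
                f"target depth {target_depth} exceeds source depth {src:.3f} "
                f"for sample {sample!r}"
            )
        if frac >= 1.0 - 1e-12:
            continue
        thinned = rng.binomial(ad, frac)
        out.depths[sample] = thinned.astype(np.int64)
        out.genotypes[sample] = call_genotypes(
            thinned,
            min_depth=min_depth,
            min_alt_fraction=min_alt_fraction,
            haploid=table.sample_haploid(sample),
        )
    return out


def simulate_str_profiles(
    truth: FamilyTruth,
    n_loci: int = 16,
    detection_rate: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[StrProfile, StrProfile, StrProfile]:
    """Simulate (father, mother, cell) STR profiles on a forensic-style panel.

    Each autosomal locus gets integer repeat alleles drawn from a common
    pool; the cell inherits one paternal and one maternal allele; each
    cell locus is independently undetected with probability
    ``1 - detection_rate`` (amplification failure / dropout).  The
    amelogenin sex marker, when the panel includes it, is encoded with
    X=0 / Y=1 and follows the configured fetal sex.
    """
    if not 1 <= n_loci:
        raise ConfigurationError("n_loci must be >= 1")
    if not 0.0 <= detection_rate <= 1.0:
        raise ConfigurationError("detection_rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng([max(truth.config.seed, 0), 2])
    if n_loci <= len(DEFAULT_STR_PANEL):
        panel = tuple(DEFAULT_STR_PANEL[:n_loci])
    else:
        panel = tuple(DEFAULT_STR_PANEL) + tuple(
            f"STR{i}" for i in range(len(DEFAULT_STR_PANEL) + 1, n_loci + 1)
        )
    father_alleles: dict[str, tuple[int, ...]] = {}
    mother_alleles: dict[str, tuple[int, ...]] = {}
    cell_alleles: dict[str, tuple[int, ...]] = {}
    for locus_name in panel:
        if locus_name == AMELOGENIN:
            fa, mo = (0, 1), (0, 0)
            cell = (0, 1) if truth.config.fetal_sex == "male" else (0, 0)
        else:
            fa = tuple(sorted(int(x) for x in rng.integers(8, 31, size=2)))
            mo = tuple(sorted(int(x) for x in rng.integers(8, 31, size=2)))
            cell = tuple(
                sorted((int(rng.choice(fa)), int(rng.choice(mo))))
            )
        father_alleles[locus_name] = fa
        mother_alleles[locus_name] = mo
        cell_alleles[locus_name] = cell if rng.random() < detection_rate else ()
    return (
        StrProfile(sample="FATHER", alleles=father_alleles, panel=panel),
        StrProfile(sample="MOTHER", alleles=mother_alleles, panel=panel),
        StrProfile(sample="CELL", alleles=cell_alleles, panel=panel),
    )
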