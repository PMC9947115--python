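"""Sequencing-quality metrics for single-cell genotype data.

Allele dropout (ADO) and the false-positive ratio (FPR) are measured
against a matched reference sample (amniotic fluid / villi, or the
simulated fetal truth):

* ``ado_ratio``  — among sites where the reference is heterozygous and
  the cell has a call, the fraction the cell reports homozygous;
* ``false_positive_ratio`` — among sites called in both samples, the
  fraction with discordant genotypes.

The denominators differ deliberately: each metric is conditioned on its
informative subset, and both denominators are reported so alternative
normalisations can be recomputed.  An ADO-induced het-to-hom change also
counts toward the FPR (any genotype difference is a discordance); the
overlap is annotated in the report.

``recover_artifact_rates`` inverts the generative closed forms: with
per-allele dropout ``d`` and genotype-error rate ``e``, discordance at
reference-homozygous sites equals ``e``, and the observed ADO ratio is
``(2d(1-e) + e) / (1+d)``, giving ``d = (ado - e) / (2 - 2e - ado)``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    Genotype,
    GenotypeTable,
    HOM_CODES,
    RegionSet,
)
from .simulate import downsample_depth


def _aligned(
    cell: GenotypeTable,
    reference: GenotypeTable,
    cell_sample: str,
    reference_sample: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype arrays of the two samples over the shared site set."""
    if len(cell.sites) == len(reference.sites) and (
        (cell.sites["pos"].values == reference.sites["pos"].values).all()
        and (cell.sites["chrom"].values == reference.sites["chrom"].values).all()
    ):
        return cell.gt(cell_sample), reference.gt(reference_sample)
    left = cell.sites.assign(_i=np.arange(len(cell.sites)))
    right = reference.sites.assign(_j=np.arange(len(reference.sites)))
    m = left.merge(right, on=["chrom", "pos"], suffixes=("", "_r"))
    return (
        cell.gt(cell_sample)[m["_i"].values],
        reference.gt(reference_sample)[m["_j"].values],
    )


def _ado_counts(gt_cell: np.ndarray, gt_ref: np.ndarray) -> tuple[int, int]:
    ref_het = gt_ref == int(Genotype.HET)
    called = gt_cell != int(Genotype.MISSING)
    den = int((ref_het & called).sum())
    num = int((ref_het & np.isin(gt_cell, [int(c) for c in HOM_CODES])).sum())
    return num, den


def ado_ratio(
    cell: GenotypeTable,
    reference: GenotypeTable,
    cell_sample: str = "CELL",
    reference_sample: str = "REFERENCE",
) -> float:
    """Fraction of reference-heterozygous, cell-called sites observed homozygous.

    Returns NaN when no reference-het site has a cell call (missing metric).
    """
    num, den = _ado_counts(*_aligned(cell, reference, cell_sample, reference_sample))
    return num / den if den else float("nan")


def _fp_counts(gt_cell: np.ndarray, gt_ref: np.ndarray) -> tuple[int, int]:
    both = (gt_cell != int(Genotype.MISSING)) & (gt_ref != int(Genotype.MISSING))
    den = int(both.sum())
    num = int((both & (gt_cell != gt_ref)).sum())
    return num, den


def false_positive_ratio(
    cell: GenotypeTable,
    reference: GenotypeTable,
    cell_sample: str = "CELL",
    reference_sample: str = "REFERENCE",
) -> float:
    """Fraction of co-called sites with discordant genotypes (NaN if none co-called)."""
    num, den = _fp_counts(*_aligned(cell, reference, cell_sample, reference_sample))
    return num / den if den else float("nan")


@dataclasses.dataclass
class ArtifactRateEstimate:
    """Inverted per-allele dropout and genotype-error rates with their inputs."""

    dropout: float
    genotype_error: float
    ado_ratio: float
    ref_hom_discordance: float
    n_ref_het_called: int
    n_ref_hom_called: int


def recover_artifact_rates(
    cell: GenotypeTable,
    reference: GenotypeTable,
    cell_sample: str = "CELL",
    reference_sample: str = "REFERENCE",
) -> ArtifactRateEstimate:
    """Estimate (dropout d, genotype-error e) from cell/reference concordance."""
    gt_cell, gt_ref = _aligned(cell, reference, cell_sample, reference_sample)
    num, den = _ado_counts(gt_cell, gt_ref)
    ado = num / den if den else float("nan")
    ref_hom = np.isin(gt_ref, [int(c) for c in HOM_CODES])
    called = gt_cell != int(Genotype.MISSING)
    hom_den = int((ref_hom & called).sum())
    hom_num = int((ref_hom & called & (gt_cell != gt_ref)).sum())
    e_hat = hom_num / hom_den if hom_den else float("nan")
    d_hat = (ado - e_hat) / (2.0 - 2.0 * e_hat - ado)
    return ArtifactRateEstimate(
        dropout=float(d_hat),
        genotype_error=float(e_hat),
        ado_ratio=float(ado),
        ref_hom_discordance=float(e_hat),
        n_ref_het_called=den,
        n_ref_hom_called=hom_den,
    )


def genome_coverage(table: GenotypeTable, sample: str = "CELL") -> float:
    """Fraction of sites with at least one read (site-level coverage surrogate)."""
    return float((table.total_depth(sample) >= 1).mean())


def _sites_in_regions(sites: pd.DataFrame, regions: RegionSet) -> np.ndarray:
    """Boolean mask over sites lying inside the region set (BED half-open)."""
    mask = np.zeros(len(sites), dtype=bool)
    pos0 = sites["pos"].values - 1  # 0-based
    for chrom, iv in regions.merged().items():
        on_chrom = sites["chrom"].values == chrom
        if not on_chrom.any() or len(iv) == 0:
            continue
        p = pos0[on_chrom]
        k = np.searchsorted(iv[:, 0], p, side="right") - 1
        inside = (k >= 0) & (p < iv[np.clip(k, 0, None), 1])
        mask[np.flatnonzero(on_chrom)[inside]] = True
    return mask


def site_panel_coverage(
    table: GenotypeTable, panel: RegionSet, sample: str = "CELL"
) -> float:
    """Fraction of in-panel sites with at least one read (NaN if no site in panel)."""
    mask = _sites_in_regions(table.sites, panel)
    if not mask.any():
        return float("nan")
    return float((table.total_depth(sample)[mask] >= 1).mean())


def covered_gene_count(
    table: GenotypeTable, genes: RegionSet, sample: str = "CELL"
) -> int:
    """Number of genes containing at least one site with >= 1 read."""
    dp = table.total_depth(sample)
    covered_sites = table.sites[dp >= 1]
    count = 0
    for row in genes.regions.itertuples(index=False):
        on = covered_sites["chrom"].values == row.chrom
        p = covered_sites["pos"].values[on] - 1
        if ((p >= row.start) & (p < row.end)).any():
            count += 1
    return count


def haplotypable_gene_count(
    genes: RegionSet,
    key_snps: "pd.DataFrame | Sequence[tuple[str, int]]",
    flank: int = 2_000_000,
) -> int:
    """Genes with at least one key SNP in each flank.

    A gene is haplotypable when the window of ``flank`` bp upstream of
    its start and the window of ``flank`` bp downstream of its end each
    contain at least one key SNP (half-open windows, the gene body
    excluded).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if isinstance(key_snps, pd.DataFrame):
        pairs = list(zip(key_snps["chrom"], key_snps["pos"]))
    else:
        pairs = list(key_snps)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in pairs:
        by_chrom.setdefault(chrom, [])
        by_chrom[chrom].append(int(pos) - 1)  # 0-based
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    count = 0
    for row in genes.regions.itertuples(index=False):
        p = by_chrom.get(row.chrom)
        if p is None:
            continue
        n_up = np.searchsorted(p, row.start) - np.searchsorted(p, row.start - flank)
        n_dn = np.searchsorted(p, row.end + flank) - np.searchsorted(p, row.end)
        if n_up >= 1 and n_dn >= 1:
            count += 1
    return count


@dataclasses.dataclass
class QcReport:
    """Aggregated sequencing-quality report for one cell."""

    ado_ratio: float
    fp_ratio: float
    genome_coverage: float
    panel_coverages: dict[str, float]
    covered_gene_counts: dict[str, int]
    haplotypable_gene_counts: dict[str, int]
    n_sites_compared: int
    n_ref_het_called: int
    #: discordances that are also ADO events (het -> hom), annotating the
    #: overlap between the two metrics
    n_ado_in_fp: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def build_qc_report(
    cell: GenotypeTable,
    reference: GenotypeTable,
    cell_sample: str = "CELL",
    reference_sample: str = "REFERENCE",
    panels: Sequence[RegionSet] = (),
    gene_sets: Sequence[RegionSet] = (),
    key_snps: pd.DataFrame | None = None,
    flank: int = 2_000_000,
) -> QcReport:
    gt_cell, gt_ref = _aligned(cell, reference, cell_sample, reference_sample)
    ado_num, ado_den = _ado_counts(gt_cell, gt_ref)
    fp_num, fp_den = _fp_counts(gt_cell, gt_ref)
    return QcReport(
        ado_ratio=ado_num / ado_den if ado_den else float("nan"),
        fp_ratio=fp_num / fp_den if fp_den else float("nan"),
        genome_coverage=genome_coverage(cell, cell_sample),
        panel_coverages={
            p.name: site_panel_coverage(cell, p, cell_sample) for p in panels
        },
        covered_gene_counts={
            g.name: covered_gene_count(cell, g, cell_sample) for g in gene_sets
        },
        haplotypable_gene_counts=(
            {}
            if key_snps is None
            else {
                g.name: haplotypable_gene_count(g, key_snps, flank) for g in gene_sets
            }
        ),
        n_sites_compared=fp_den,
        n_ref_het_called=ado_den,
        n_ado_in_fp=ado_num,
    )


def depth_gradient_analysis(
    cell: GenotypeTable,
    reference: GenotypeTable,
    depths: Sequence[float],
    *,
    source_depth: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    panels: Sequence[RegionSet] = (),
    gene_sets: Sequence[RegionSet] = (),
    min_depth: int = 0,
    min_alt_fraction: float = 0.2,
    cell_sample: str = "CELL",
    reference_sample: str = "REFERENCE",
) -> pd.DataFrame:
    """Metrics across a ladder of subsampled depths (e.g. 1X..35X).

    Thinning is nested — the 30X table is thinned from the 35X one and
    so on — so per-site read counts (hence site coverage) are exactly
    non-decreasing in target depth for a given seed.  Gradient genotypes
    are re-called with a permissive ``min_depth`` (default 0: any covered
    site is callable) so ADO/FPR remain defined at 1X.
    """
    if rng is None:
        rng = np.random.default_rng([max(seed, 0), 5])
    depths = sorted(float(d) for d in depths)
    src = (
        float(source_depth)
        if source_depth is not None
        else float(np.asarray(cell.depths[cell_sample]).sum(axis=1).mean())
    )
    if depths and depths[-1] > src * (1 + 1e-9):
        raise ValueError("max target depth exceeds the source depth")
    rows = []
    current = cell
    nominal = src
    for target in reversed(depths):
        current = downsample_depth(
            current,
            target,
            source_depth=nominal,
            rng=rng,
            min_depth=min_depth,
            min_alt_fraction=min_alt_fraction,
        )
        nominal = target
        row: dict[str, float] = {
            "depth": target,
            "genome_coverage": genome_coverage(current, cell_sample),
            "fp_ratio": false_positive_ratio(
                current, reference, cell_sample, reference_sample
            ),
            "ado_ratio": ado_ratio(
                current, reference, cell_sample, reference_sample
            ),
        }
        for p in panels:
            row[f"panel_coverage_{p.name}"] = site_panel_coverage(
                current, p, cell_sample
            )
        for g in gene_sets:
            row[f"covered_genes_{g.name}"] = covered_gene_count(
                current, g, cell_sample
            )
        rows.append(row)
    return pd.DataFrame(rows[::-1]).reset_index(drop=True)
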