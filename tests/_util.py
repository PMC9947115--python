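"""Shared helpers for building small genotype fixtures by hand."""

from __future__ import annotations

import numpy as np
import pandas as pd

from cellhap import Genotype, GenotypeTable

G = Genotype


def make_table(
    samples: dict[str, list[int]],
    pos: list[int] | None = None,
    chrom: str = "chr7",
    depth: int = 30,
    haploid: dict[str, bool] | None = None,
) -> GenotypeTable:
    """Build a GenotypeTable from genotype-code lists, fabricating depths.

    Depths are made consistent with the genotype (balanced het, one-sided
    hom, zero for missing) so re-calling at default thresholds would
    reproduce the genotypes.
    """
    n = len(next(iter(samples.values())))
    if pos is None:
        pos = list(range(1_000, 1_000 + 10 * n, 10))
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64), "ref": "A", "alt": "G"}
    )
    haploid = haploid or {}
    genotypes, depths = {}, {}
    ad_for = {
        int(G.MISSING): (0, 0),
        int(G.HOM_REF): (depth, 0),
        int(G.HET): (depth // 2, depth - depth // 2),
        int(G.HOM_ALT): (0, depth),
        int(G.HEM_REF): (depth, 0),
        int(G.HEM_ALT): (0, depth),
    }
    for s, codes in samples.items():
        genotypes[s] = np.asarray([int(c) for c in codes], dtype=np.int8)
        depths[s] = np.asarray([ad_for[int(c)] for c in codes], dtype=np.int64)
    return GenotypeTable(
        sites=sites, genotypes=genotypes, depths=depths, haploid=dict(haploid)
    )
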