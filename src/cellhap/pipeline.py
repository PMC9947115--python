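"""End-to-end reproducible runs: simulate -> confirm -> QC -> haplotype.

A run is a pure function of its :class:`RunConfig` (which embeds the
simulation seed): the same config always produces byte-identical
reports.  Every stage writes its inputs and outputs under the run
directory::

    out_dir/
      inputs/   family.vcf, str_*.tsv, locus.yaml, config.yaml
      calls/    informative_snps.tsv, haplotype_report.json
      qc/       qc_report.json, depth_gradient.tsv (optional)
      report.json
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import GenotypeTable, merge_tables
from .model import FetalHaplotypeModel
from .qc import build_qc_report, depth_gradient_analysis
from .simulate import (
    DiseaseLocus,
    FamilyTruth,
    SimulationConfig,
    default_locus,
    observe_single_cell,
    simulate_family,
    simulate_str_profiles,
)
from .str_confirm import classify_fetal_origin, detection_rate, paternal_specific_alleles


@dataclasses.dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    locus: DiseaseLocus | None = None
    flank: int = 2_000_000
    vote_threshold: float = 0.8
    min_key_snps: int = 1
    key_mode: str = "observed"
    str_n_loci: int = 16
    str_detection_rate: float = 0.9
    str_threshold: int = 2
    depth_gradients: tuple[float, ...] | None = None
    out_dir: str = "cellhap_run"

    def resolved_locus(self) -> DiseaseLocus:
        return self.locus if self.locus is not None else default_locus(self.simulation)

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "locus": self.resolved_locus().to_dict(),
            "flank": self.flank,
            "vote_threshold": self.vote_threshold,
            "min_key_snps": self.min_key_snps,
            "key_mode": self.key_mode,
            "str_n_loci": self.str_n_loci,
            "str_detection_rate": self.str_detection_rate,
            "str_threshold": self.str_threshold,
            "depth_gradients": list(self.depth_gradients)
            if self.depth_gradients
            else None,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if d.get("locus") is not None:
            d["locus"] = DiseaseLocus.from_dict(d["locus"])
        if d.get("depth_gradients") is not None:
            d["depth_gradients"] = tuple(float(x) for x in d["depth_gradients"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclasses.dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    verdict: str
    haplotype: dict
    qc: dict
    str_confirmation: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis for one simulated family and cell."""
    out = Path(config.out_dir)
    for sub in ("inputs", "calls", "qc"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    locus = config.resolved_locus()
    sim = config.simulation

    # -- stage 1: family and single-cell observation -----------------------
    truth = simulate_family(sim, locus)
    gdna = truth.to_genotype_table(include_reference=True)
    cell = observe_single_cell(truth)
    family = merge_tables(gdna, cell)
    family.write_vcf(out / "inputs" / "family.vcf")
    (out / "inputs" / "locus.yaml").write_text(yaml.safe_dump(locus.to_dict()))
    config.to_yaml(out / "inputs" / "config.yaml")

    # -- stage 2: STR fetal-origin confirmation ----------------------------
    father_p, mother_p, cell_p = simulate_str_profiles(
        truth, n_loci=config.str_n_loci, detection_rate=config.str_detection_rate
    )
    for prof, name in ((father_p, "father"), (mother_p, "mother"), (cell_p, "cell")):
        prof.to_tsv(out / "inputs" / f"str_{name}.tsv")
    match = paternal_specific_alleles(cell_p, father_p, mother_p)
    str_report = {
        "detection_rate_pct": detection_rate(cell_p),
        "paternal_specific_allele_count": match.total,
        "paternal_specific_alleles": match.to_dict()["paternal_specific"],
        "unexplained_alleles": match.to_dict()["unexplained"],
        "fetal_origin_confirmed": classify_fetal_origin(
            match.total, config.str_threshold
        ),
        "threshold": config.str_threshold,
    }

    # -- stage 3: sequencing QC --------------------------------------------
    qc_report = build_qc_report(family, family, "CELL", "REFERENCE")
    qc_report.to_json(out / "qc" / "qc_report.json")
    qc_dict = qc_report.to_dict()
    if config.depth_gradients:
        gradient = depth_gradient_analysis(
            cell,
            family,
            config.depth_gradients,
            source_depth=sim.mean_depth,
            seed=sim.seed,
            reference_sample="REFERENCE",
        )
        gradient.to_csv(out / "qc" / "depth_gradient.tsv", sep="\t", index=False)
        qc_dict["depth_gradient"] = gradient.to_dict(orient="list")

    # -- stage 4: haplotype phasing and verdict ----------------------------
    model = FetalHaplotypeModel(
        genotypes=family,
        locus=locus,
        flank=config.flank,
        vote_threshold=config.vote_threshold,
        min_key_snps=config.min_key_snps,
        key_mode=config.key_mode,
        fetal_sex=sim.fetal_sex,
    )
    results = model.fit()
    results.informative_snps.to_csv(
        out / "calls" / "informative_snps.tsv", sep="\t", index=False
    )
    results.to_json(out / "calls" / "haplotype_report.json")

    report = RunReport(
        verdict=results.verdict.value,
        haplotype=results.to_dict(),
        qc=qc_dict,
        str_confirmation=str_report,
        provenance={
            "package": "cellhap",
            "version": __version__,
            "seed": sim.seed,
            # the report is a pure function of the scientific config; the
            # output location is deliberately not part of it
            "config": {
                k: v for k, v in config.to_dict().items() if k != "out_dir"
            },
        },
    )
    report.to_json(out / "report.json")
    return report


def render_report(report: RunReport) -> str:
    """Plain-text run summary: verdict, vote counts, QC, STR confirmation."""
    hap = report.haplotype
    lines = [
        "cellhap run summary",
        "=" * 50,
        f"Verdict: {report.verdict}",
        "",
        "Haplotype calls:",
    ]
    for parent, call in hap.get("calls", {}).items():
        label = call["label"] if call["label"] is not None else "ambiguous"
        lines.append(
            f"  {parent}: haplotype {label}  "
            f"upstream {call['upstream_votes'][0]}/{call['upstream_votes'][1]}  "
            f"downstream {call['downstream_votes'][0]}/{call['downstream_votes'][1]}"
        )
        if call.get("recombination_flag"):
            lines.append("    flank discordance: possible fetal recombination")
        if call.get("message"):
            lines.append(f"    note: {call['message']}")
    lines += [
        "",
        f"Informative SNPs: {hap.get('n_informative')}  key: {hap.get('n_key')}",
        "",
        "Sequencing QC:",
        f"  ADO ratio: {_fmt(report.qc.get('ado_ratio'))}",
        f"  FP ratio:  {_fmt(report.qc.get('fp_ratio'))}",
        f"  site coverage: {_fmt(report.qc.get('genome_coverage'))}",
        "",
        "STR confirmation:",
        f"  detection rate: {report.str_confirmation.get('detection_rate_pct')}%",
        f"  paternal-specific alleles: "
        f"{report.str_confirmation.get('paternal_specific_allele_count')}",
        f"  fetal origin confirmed: "
        f"{report.str_confirmation.get('fetal_origin_confirmed')}",
    ]
    return "\n".join(lines)


def _fmt(x) -> str:
    if x is None:
        return "n/a"
    try:
        if np.isnan(x):
            return "n/a"
    except TypeError:
        return str(x)
    return f"{x:.4f}"
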