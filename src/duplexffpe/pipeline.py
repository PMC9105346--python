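"""End-to-end orchestration: filter -> group -> consensus -> merge -> call
-> population-SNP filter -> metrics, plus the file-based runner."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import io_bridge, readfilter, consensus, varcall, metrics
from .io_bridge import AlignedPairRecord, PopulationAFTable
from .metrics import ProfileConfig, SampleReport

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alignments: str = ""
    reference: str = ""
    af_table: str = ""
    af_format: Optional[str] = None
    out_dir: str = "."
    filter: readfilter.FilterConfig = field(default_factory=readfilter.FilterConfig)
    consensus: consensus.ConsensusConfig = field(default_factory=consensus.ConsensusConfig)
    snp: varcall.SnpFilterConfig = field(default_factory=varcall.SnpFilterConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)

    def validate(self) -> None:
        for name in ("alignments", "reference", "af_table"):
            value = getattr(self, name)
            if not value:
                raise ValueError(f"run config is missing required field '{name}'")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")
        self.filter.validate()
        self.consensus.validate()
        self.snp.validate()
        self.profile.validate()

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        sections = {
            "filter": readfilter.FilterConfig,
            "consensus": consensus.ConsensusConfig,
            "snp": varcall.SnpFilterConfig,
            "profile": ProfileConfig,
        }
        for key, value in raw.items():
            if key in sections:
                block = sections[key]()
                for k, v in (value or {}).items():
                    if not hasattr(block, k):
                        raise ValueError(f"unknown field '{key}.{k}' in run config")
                    setattr(block, k, v)
                setattr(cfg, key, block)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown field '{key}' in run config")
        return cfg


@dataclass
class AnalysisResult:
    report: SampleReport
    filter_report: readfilter.FilterReport
    results: list[consensus.TemplateResult]
    retained: list[varcall.VariantCall]
    removed: list[varcall.VariantCall]
    profile: pd.DataFrame


def analyze(
    pairs: Sequence[AlignedPairRecord],
    refseq: str,
    ref_name: str,
    af_table: PopulationAFTable,
    *,
    filter_config: readfilter.FilterConfig | None = None,
    consensus_config: consensus.ConsensusConfig | None = None,
    snp_config: varcall.SnpFilterConfig | None = None,
    profile_config: ProfileConfig | None = None,
) -> AnalysisResult:
    """Run the full in-memory analysis over already-loaded pair records."""
    fcfg = filter_config or readfilter.FilterConfig()
    ccfg = consensus_config or consensus.ConsensusConfig()
    scfg = snp_config or varcall.SnpFilterConfig()
    pcfg = profile_config or ProfileConfig()

    passing, freport = readfilter.filter_pairs(pairs, fcfg, refseq)
    logger.info(
        "filter: %d/%d pairs passed", freport.passed, freport.input_pairs
    )
    trimmed = readfilter.trim_all(passing, fcfg.end_trim)
    grouped = consensus.group_templates(trimmed)
    logger.info("grouped %d unique templates", len(grouped))
    results = consensus.build_duplexes(grouped, ccfg)
    duplexes = [r.duplex for r in results if r.duplex is not None]
    logger.info("built %d duplex consensuses", len(duplexes))
    calls = varcall.call_variants(duplexes, refseq, ref_name)
    retained, removed = varcall.filter_common_snps(calls, af_table, scfg)
    logger.info(
        "calls: %d total, %d retained, %d removed as common",
        len(calls), len(retained), len(removed),
    )
    profile = metrics.end_distance_profile(retained, duplexes, pcfg)
    report = metrics.build_report(
        total_read_pairs=freport.input_pairs,
        pass_fraction=freport.pass_fraction,
        results=results,
        retained=retained,
        removed=removed,
        refseq=refseq,
    )
    return AnalysisResult(report, freport, results, retained, removed, profile)


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def _write_kv_tsv(rows, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in rows:
            fh.write(f"{key}\t{value}\n")


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-based pipeline entry: reads inputs, writes every artifact.

    Outputs in ``out_dir``: report.json / report.tsv, calls.vcf, calls.tsv,
    profile.tsv, filter_report.tsv.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fasta = io_bridge.load_fasta(config.reference)
    if len(fasta) != 1:
        raise ValueError("expected a single-sequence reference FASTA")
    (ref_name, refseq), = fasta.items()
    pairs = io_bridge.load_alignments(config.alignments)
    af_table = io_bridge.load_af_table(config.af_table, config.af_format)

    result = analyze(
        pairs, refseq, ref_name, af_table,
        filter_config=config.filter,
        consensus_config=config.consensus,
        snp_config=config.snp,
        profile_config=config.profile,
    )

    _write_json(result.report.to_dict(), out / "report.json")
    _write_kv_tsv(result.report.to_rows(), out / "report.tsv")
    _write_kv_tsv(result.filter_report.to_rows(), out / "filter_report.tsv")
    varcall.write_vcf(result.retained, out / "calls.vcf", ref_name, len(refseq))
    calls_df = pd.DataFrame(
        [
            {
                "chrom": c.ref_name,
                "pos": c.pos + 1,
                "ref": c.ref,
                "alt": c.alt,
                "class": c.vclass,
                "template": f"{c.template_key[1]}-{c.template_key[2]}",
                "population_af": "" if c.af is None else c.af,
                "status": status,
            }
            for status, calls in (("retained", result.retained), ("removed_common", result.removed))
            for c in calls
        ]
    )
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
    result.profile.to_csv(out / "profile.tsv", sep="\t", index=False, na_rep="NA")
    return result
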