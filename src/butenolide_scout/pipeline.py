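"""End-to-end orchestration: calibrate -> mine -> conserve -> shift -> itc.

A single config (JSON or YAML) names the inputs for each stage; stages with
missing inputs are skipped, a failing stage is recorded without aborting the
independent stages, and the consolidated report carries a hash of the
semantic config fields so identical runs are recognizable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import conservation, itc, neighborhood, ssn, structcompare

__all__ = ["PipelineConfig", "RunReport", "load_config", "run", "ConfigError"]

logger = logging.getLogger("butenolide_scout")

VERSION = "0.1.0"


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists all violations."""


@dataclass
class PipelineConfig:
    out_dir: str = "butenolide_scout_out"
    seed: int = 0
    # ssn stage
    fasta: str | None = None
    labels: str | None = None
    ssn_threshold: float = ssn.DEFAULT_THRESHOLD
    calibrate: bool = True
    # mine stage
    genbank: list[str] = field(default_factory=list)
    domains: str | None = None
    window: int = 5
    # conserve stage
    msa: str | None = None
    ref_id: str | None = None
    pdb: str | None = None
    sites: str | None = None
    # shift stage
    apo: str | None = None
    holo: str | None = None
    chain: str | None = None
    dbd: list[tuple[int, int]] = field(default_factory=lambda: [(1, 65)])
    lbd: list[tuple[int, int]] = field(default_factory=lambda: [(66, 10000)])
    # itc stage
    isotherm: str | None = None

    def validate(self) -> None:
        problems = []
        if self.window < 1:
            problems.append("window must be >= 1")
        if self.ssn_threshold <= 0:
            problems.append("ssn_threshold must be > 0")
        for name in ("fasta", "labels", "domains", "msa", "pdb", "sites",
                     "apo", "holo", "isotherm"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name}: path {p!r} does not exist")
        for p in self.genbank:
            if not Path(p).exists():
                problems.append(f"genbank: path {p!r} does not exist")
        if problems:
            raise ConfigError("; ".join(problems))

    def semantic_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    stages: dict[str, dict]

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.dbd = [tuple(x) for x in cfg.dbd]
    cfg.lbd = [tuple(x) for x in cfg.lbd]
    return cfg


def _read_labels(path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                parts = line.split("\t")
                if len(parts) >= 2:
                    labels[parts[0]] = parts[1]
    return labels


def _read_fasta_records(path, labels: dict[str, str]) -> list[ssn.SeqRecord]:
    from Bio import SeqIO

    return [
        ssn.SeqRecord(id=r.id, sequence=str(r.seq), label=labels.get(r.id))
        for r in SeqIO.parse(str(path), "fasta")
    ]


def _stage_ssn(cfg: PipelineConfig, out: Path) -> dict:
    labels = _read_labels(cfg.labels) if cfg.labels else {}
    records = _read_fasta_records(cfg.fasta, labels)
    threshold = cfg.ssn_threshold
    chosen = None
    if cfg.calibrate and labels:
        chosen = ssn.find_exclusive_threshold(records, labels)
        if chosen is not None:
            threshold = chosen
    graph = ssn.build_ssn(records, threshold=threshold)
    ssn.write_edge_list(graph, out / "ssn_edges.tsv")
    ssn.write_components(graph, out / "ssn_components.tsv")
    comps = ssn.components(graph)
    report = ssn.exclusivity(comps, labels) if labels else None
    return {
        "n_records": len(records),
        "threshold": threshold,
        "calibrated_threshold": chosen,
        "n_components": len(comps),
        "is_exclusive": report.is_exclusive if report else None,
    }


def _stage_mine(cfg: PipelineConfig, out: Path) -> dict:
    table = neighborhood.read_domain_table(cfg.domains) if cfg.domains else None
    genomes = [neighborhood.read_genome(p, table) for p in cfg.genbank]
    rule = dataclasses.replace(neighborhood.DEFAULT_RULE, window=cfg.window)
    calls = neighborhood.scan(genomes, rule)
    frame = neighborhood.calls_to_frame(calls)
    frame.to_csv(out / "context_calls.tsv", sep="\t", index=False)
    return {
        "n_genomes": len(genomes),
        "n_receptors": len(calls),
        "n_candidates": int(frame["verdict"].sum()) if len(frame) else 0,
    }


def _stage_conserve(cfg: PipelineConfig, out: Path) -> dict:
    msa = conservation.read_msa(cfg.msa)
    profile = conservation.column_conservation(msa, ref_id=cfg.ref_id)
    profile.to_frame().to_csv(out / "conservation_profile.tsv", sep="\t", index=False)
    summary: dict = {"n_columns": msa.length, "n_sequences": len(msa.records)}
    if cfg.pdb:
        conservation.paint_structure(profile, cfg.pdb, out / "painted.pdb")
        summary["painted_pdb"] = str(out / "painted.pdb")
    if cfg.sites:
        rows = []
        with open(cfg.sites) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    num, aa = line.split("\t")[:2]
                    rows.append((int(num), aa))
        report = conservation.binding_site_report(
            profile, conservation.BindingSiteSpec(residues=rows)
        )
        report.to_csv(out / "binding_site_report.tsv", sep="\t", index=False)
        scored = report["score"].dropna()
        summary["binding_site_mean_score"] = float(scored.mean()) if len(scored) else None
    return summary


def _stage_shift(cfg: PipelineConfig, out: Path) -> dict:
    apo = structcompare.read_ca_trace(cfg.apo, chain=cfg.chain)
    holo = structcompare.read_ca_trace(cfg.holo, chain=cfg.chain)
    ranges = structcompare.DomainRanges(dbd=list(cfg.dbd), lbd=list(cfg.lbd))
    result = structcompare.domain_shift(apo, holo, ranges)
    payload = dataclasses.asdict(result)
    (out / "domain_shift.json").write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def _stage_itc(cfg: PipelineConfig, out: Path) -> dict:
    iso = itc.read_isotherm(cfg.isotherm)
    fit = itc.fit_one_site(iso, itc.PAPER_PROTOCOL)
    itc.fit_report_json(fit, out / "itc_fit.json")
    return {
        "n": fit.params.n,
        "kd_M": fit.params.kd,
        "dh_cal_per_mol": fit.params.dh,
        "dg_kcal_per_mol": fit.dg,
        "ds_cal_per_mol_K": fit.ds,
        "converged": fit.converged,
    }


_STAGES = [
    ("ssn", _stage_ssn, lambda c: c.fasta is not None),
    ("mine", _stage_mine, lambda c: bool(c.genbank)),
    ("conserve", _stage_conserve, lambda c: c.msa is not None),
    ("shift", _stage_shift, lambda c: c.apo is not None and c.holo is not None),
    ("itc", _stage_itc, lambda c: c.isotherm is not None),
]


def run(cfg: PipelineConfig) -> RunReport:
    """Execute the configured stages in order, recording per-stage outcomes.

    A stage with missing inputs is marked ``skipped``; a raising stage is
    marked ``failed`` with its error message verbatim, and independent
    stages still run.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    for name, fn, ready in _STAGES:
        t0 = time.time()
        if not ready(cfg):
            logger.info("[%s] skipped (inputs not configured)", name)
            stages[name] = {"status": "skipped"}
            continue
        try:
            summary = fn(cfg, out)
            stages[name] = {"status": "ok", "elapsed_s": round(time.time() - t0, 3), **summary}
            logger.info("[%s] ok (%.2fs)", name, time.time() - t0)
        except Exception as exc:
            stages[name] = {"status": "failed", "error": str(exc)}
            logger.error("[%s] failed: %s", name, exc)
    report = RunReport(config_hash=cfg.semantic_hash(), version=VERSION, stages=stages)
    report.to_json(out / "run_report.json")
    return report
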