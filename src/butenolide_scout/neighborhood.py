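"""Genome-neighborhood mining for putative butenolide receptors.

Butenolide receptors are TetR-family repressors that usually regulate the
biosynthesis of their own ligand, so a receptor gene flanked by the
avenolide-type biosynthetic machinery — a cytochrome P450 (PF00067) plus an
acyl-CoA dehydrogenase/oxidase (one of PF00441, PF08028, PF01756) — is a
strong candidate.  This module parses GenBank annotations (optionally
augmented by a sidecar locus->Pfam table), extracts gene-rank neighborhoods
around receptor genes, and applies the context rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneFeature",
    "GenomeRecord",
    "ContextRule",
    "NeighborhoodCall",
    "DEFAULT_RULE",
    "read_genome",
    "read_domain_table",
    "neighbors",
    "evaluate_context",
    "scan",
    "calls_to_frame",
]

RECEPTOR_FAMILY = "TetR_N"
ANCHOR_PFAMS = frozenset({"PF00067"})  # cytochrome P450
ALTERNATIVE_PFAMS = frozenset({"PF00441", "PF08028", "PF01756"})  # ACAD / ACOX


@dataclass(frozen=True)
class GeneFeature:
    """One CDS with 0-based half-open coordinates and Pfam assignments."""

    locus_tag: str
    start: int
    end: int
    strand: int
    pfam_ids: frozenset[str] = frozenset()
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.locus_tag}: {self.start}..{self.end}")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")


@dataclass
class GenomeRecord:
    id: str
    features: list[GeneFeature]

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: f.start)
        tags = [f.locus_tag for f in self.features]
        if len(set(tags)) != len(tags):
            raise ValueError(f"duplicate locus_tags in genome {self.id}")

    def feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"locus {locus_tag!r} not in genome {self.id}")


@dataclass(frozen=True)
class ContextRule:
    """Receptor surrounded by all anchor Pfams and >=1 alternative Pfam."""

    receptor_family: str = RECEPTOR_FAMILY
    anchor_set: frozenset[str] = ANCHOR_PFAMS
    alternative_set: frozenset[str] = ALTERNATIVE_PFAMS
    window: int = 5

    def __post_init__(self) -> None:
        if not self.anchor_set or not self.alternative_set:
            raise ValueError("anchor_set and alternative_set must be non-empty")
        if self.window < 1:
            raise ValueError("window must be >= 1")


DEFAULT_RULE = ContextRule()


@dataclass
class NeighborhoodCall:
    genome_id: str
    receptor_locus: str
    neighbor_loci: list[str]
    matched_anchor: set[str]
    matched_alternative: set[str]
    verdict: bool


def read_domain_table(path) -> dict[str, frozenset[str]]:
    """Sidecar TSV ``locus_tag<TAB>PFxxxxx[,PFyyyyy...]`` -> mapping."""
    table: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            locus, pfams = parts[0], parts[1]
            table[locus] = frozenset(p.strip() for p in pfams.split(",") if p.strip())
    return table


def _pfams_from_qualifiers(feat) -> set[str]:
    pfams: set[str] = set()
    for xref in feat.qualifiers.get("db_xref", []):
        if ":" in xref:
            db, acc = xref.split(":", 1)
            if db.lower() in ("pfam", "pfam_id"):
                pfams.add(acc.strip())
    for q in feat.qualifiers.get("pfam", []):
        pfams.update(p.strip() for p in q.split(",") if p.strip())
    return pfams


def read_genome(path, domain_table: Mapping[str, Iterable[str]] | None = None) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    Pfam accessions come from CDS ``db_xref``/``pfam`` qualifiers and are
    augmented or overridden by the sidecar ``domain_table``.  GenBank 1-based
    inclusive locations become 0-based half-open internally (Biopython already
    applies this convention).
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # unparseable file
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    features = []
    seen_tags = set()
    for feat in record.features:
        if feat.type != "CDS":
            continue
        tags = feat.qualifiers.get("locus_tag") or feat.qualifiers.get("gene")
        if not tags:
            continue
        tag = tags[0]
        seen_tags.add(tag)
        pfams = _pfams_from_qualifiers(feat)
        if domain_table and tag in domain_table:
            pfams |= set(domain_table[tag])
        features.append(
            GeneFeature(
                locus_tag=tag,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=int(feat.location.strand or 1),
                pfam_ids=frozenset(pfams),
                product=(feat.qualifiers.get("product") or [""])[0],
            )
        )
    if domain_table:
        missing = set(domain_table) - seen_tags
        if missing:
            warnings.warn(
                f"domain table loci not in genome {record.id}: {sorted(missing)[:5]}",
                stacklevel=2,
            )
    return GenomeRecord(id=record.id, features=features)


def neighbors(genome: GenomeRecord, locus: str, window: int = 5) -> list[GeneFeature]:
    """Up to ``window`` genes on each side of ``locus`` in gene-rank order.

    The receptor itself is excluded; the slice truncates at contig ends;
    strand is ignored.
    """
    idx = None
    for i, f in enumerate(genome.features):
        if f.locus_tag == locus:
            idx = i
            break
    if idx is None:
        raise KeyError(f"locus {locus!r} not in genome {genome.id}")
    lo = max(0, idx - window)
    return genome.features[lo:idx] + genome.features[idx + 1 : idx + 1 + window]


def evaluate_context(
    rule: ContextRule, receptor: GeneFeature, neighborhood: Sequence[GeneFeature],
    genome_id: str = "",
) -> NeighborhoodCall:
    """Apply the butenolide context rule to one receptor neighborhood.

    Verdict is true iff some neighbor carries every anchor Pfam and some
    neighbor (possibly the same gene) carries at least one alternative Pfam.
    """
    if rule.receptor_family not in receptor.pfam_ids:
        raise ValueError(
            f"receptor {receptor.locus_tag} lacks family annotation {rule.receptor_family!r}"
        )
    matched_anchor: set[str] = set()
    matched_alt: set[str] = set()
    anchor_ok = False
    for g in neighborhood:
        if rule.anchor_set <= g.pfam_ids:
            anchor_ok = True
            matched_anchor |= rule.anchor_set & g.pfam_ids
        matched_alt |= rule.alternative_set & g.pfam_ids
    return NeighborhoodCall(
        genome_id=genome_id,
        receptor_locus=receptor.locus_tag,
        neighbor_loci=[g.locus_tag for g in neighborhood],
        matched_anchor=matched_anchor,
        matched_alternative=matched_alt,
        verdict=anchor_ok and bool(matched_alt),
    )


def scan(genomes: Sequence[GenomeRecord], rule: ContextRule = DEFAULT_RULE) -> list[NeighborhoodCall]:
    """One call per receptor-family gene per genome, in deterministic order."""
    calls = []
    for genome in sorted(genomes, key=lambda g: g.id):
        receptor_loci = sorted(
            f.locus_tag for f in genome.features if rule.receptor_family in f.pfam_ids
        )
        for locus in receptor_loci:
            receptor = genome.feature(locus)
            hood = neighbors(genome, locus, window=rule.window)
            calls.append(evaluate_context(rule, receptor, hood, genome_id=genome.id))
    return calls


def calls_to_frame(calls: Sequence[NeighborhoodCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome": [c.genome_id for c in calls],
            "receptor_locus": [c.receptor_locus for c in calls],
            "verdict": [c.verdict for c in calls],
            "matched_anchor": [",".join(sorted(c.matched_anchor)) for c in calls],
            "matched_alternative": [",".join(sorted(c.matched_alternative)) for c in calls],
            "neighbor_loci": [",".join(c.neighbor_loci) for c in calls],
        }
    )
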