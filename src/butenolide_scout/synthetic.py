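"""Seeded generators for every input the pipeline consumes.

Each generator emulates one class of study input and emits a ground-truth
table, so downstream modules can be tested with parameter-recovery or
precision/recall assertions without any external data:

* receptor families with controlled within/between-family identity
  (substitution-only mutation from a common ancestor, so the output is
  trivially alignable and doubles as an MSA);
* annotated genomes with planted receptor+P450+dehydrogenase operons and
  decoy contexts that each violate exactly one clause of the context rule;
* two-domain Ca structures differing by a planted hinge rotation;
* MSAs with per-column conservation targets;
* the palindromization utility for pseudopalindromic operator half-sites.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from Bio import SeqIO
from scipy.optimize import brentq

from .conservation import LN20, Msa
from .neighborhood import (
    ALTERNATIVE_PFAMS,
    ANCHOR_PFAMS,
    RECEPTOR_FAMILY,
    GeneFeature,
    GenomeRecord,
)
from .ssn import SeqRecord
from .structcompare import CaTrace

__all__ = [
    "FamilySpec",
    "GenomePlan",
    "make_families",
    "make_genomes",
    "write_genome_files",
    "make_two_domain",
    "make_msa",
    "palindromize",
    "pairwise_identity",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# receptor families


@dataclass(frozen=True)
class FamilySpec:
    n_families: int = 3
    members_per_family: int = 5
    length: int = 200
    within_identity: float = 0.9
    between_identity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.between_identity < self.within_identity <= 1.0):
            raise ValueError("need 0 < between_identity < within_identity <= 1")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching positions over the shorter length."""
    n = min(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x == y) / n


def _mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability p to a different residue."""
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < p:
            choices = AMINO_ACIDS.replace(chars[i], "")
            chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _divergence_for_identity(target: float) -> float:
    """Per-branch substitution rate so two independently mutated copies of
    one ancestor show the target identity.

    Both positions unmutated with probability (1-p)^2; otherwise residues
    coincide by chance with probability ~1/20.
    """
    u = (target - 0.05) / 0.95  # (1-p)^2
    u = min(max(u, 0.0), 1.0)
    return 1.0 - math.sqrt(u)


def make_families(spec: FamilySpec) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Labeled receptor families mutated from a common ancestor.

    Returns the records plus a truth table (id, family, generation targets).
    Realized pairwise identities land within ~5% of the targets for
    lengths around 200.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=spec.length))
    p_between = _divergence_for_identity(spec.between_identity)
    p_within = _divergence_for_identity(spec.within_identity)
    records, rows = [], []
    for fam in range(spec.n_families):
        family = f"family{fam + 1}"
        founder = _mutate(ancestor, p_between, rng)
        for mem in range(spec.members_per_family):
            seq = _mutate(founder, p_within, rng)
            rid = f"{family}_m{mem + 1}"
            records.append(SeqRecord(id=rid, sequence=seq, label=family))
            rows.append((rid, family, spec.within_identity, spec.between_identity))
    truth = pd.DataFrame(
        rows, columns=["id", "family", "within_identity_target", "between_identity_target"]
    )
    return records, truth


def write_families_fasta(records: list[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# genomes with planted operons


@dataclass(frozen=True)
class GenomePlan:
    n_true_operons: int = 3
    n_anchor_only: int = 1
    n_alternative_only: int = 1
    n_no_receptor: int = 1
    n_scrambled: int = 1
    gap_range: tuple[int, int] = (50, 300)  # intergenic bp
    gene_length: int = 900
    window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_true_operons, self.n_anchor_only, self.n_alternative_only,
            self.n_no_receptor, self.n_scrambled,
        )
        if any(c < 0 for c in counts):
            raise ValueError("cassette counts must be >= 0")


def _cassette_genes(kind: str, rng: np.random.Generator, window: int) -> list[tuple[frozenset[str], str, bool | None]]:
    """Gene list for one cassette: (pfams, role, intended verdict on receptor).

    Each decoy violates exactly one clause of the context rule.
    """
    p450 = frozenset(ANCHOR_PFAMS)
    acad = frozenset({sorted(ALTERNATIVE_PFAMS)[rng.integers(len(ALTERNATIVE_PFAMS))]})
    receptor = frozenset({RECEPTOR_FAMILY})
    nothing = frozenset()
    if kind == "true":
        genes = [(p450, "p450", None), (receptor, "receptor", True), (acad, "acad", None)]
    elif kind == "anchor_only":
        genes = [(p450, "p450", None), (receptor, "receptor", False)]
    elif kind == "alternative_only":
        genes = [(receptor, "receptor", False), (acad, "acad", None)]
    elif kind == "no_receptor":
        genes = [(p450, "p450", None), (acad, "acad", None)]
    elif kind == "scrambled":
        # partners pushed beyond the rule window by filler genes
        genes = [(receptor, "receptor", False)]
        genes += [(nothing, "filler", None)] * window
        genes += [(p450, "p450", None), (acad, "acad", None)]
    else:
        raise ValueError(f"unknown cassette kind {kind!r}")
    return genes


def make_genomes(plan: GenomePlan) -> tuple[GenomeRecord, dict[str, frozenset[str]], pd.DataFrame]:
    """One synthetic genome with planted true operons and decoy cassettes.

    Returns the genome record, the locus->Pfam domain table, and a truth
    table listing every planted receptor with its intended verdict.
    Cassettes are shuffled and padded with filler genes so neighborhoods
    never bleed into each other at the rule window.
    """
    rng = np.random.default_rng(plan.seed)
    kinds = (
        ["true"] * plan.n_true_operons
        + ["anchor_only"] * plan.n_anchor_only
        + ["alternative_only"] * plan.n_alternative_only
        + ["no_receptor"] * plan.n_no_receptor
        + ["scrambled"] * plan.n_scrambled
    )
    rng.shuffle(kinds)
    genome_id = f"synth_genome_{plan.seed}"
    features: list[GeneFeature] = []
    domain_table: dict[str, frozenset[str]] = {}
    truth_rows = []
    pos = int(rng.integers(*plan.gap_range))
    counter = 0

    def add_gene(pfams: frozenset[str], product: str) -> str:
        nonlocal pos, counter
        counter += 1
        tag = f"SG{plan.seed}_{counter:04d}"
        length = plan.gene_length + int(rng.integers(-200, 201))
        strand = 1 if rng.random() < 0.5 else -1
        features.append(
            GeneFeature(
                locus_tag=tag, start=pos, end=pos + length,
                strand=strand, pfam_ids=pfams, product=product,
            )
        )
        if pfams:
            domain_table[tag] = pfams
        pos += length + int(rng.integers(*plan.gap_range))
        return tag

    for i, kind in enumerate(kinds):
        if i > 0:
            for _ in range(plan.window + 1):  # insulating filler genes
                add_gene(frozenset(), "hypothetical protein")
        for pfams, role, verdict in _cassette_genes(kind, rng, plan.window):
            tag = add_gene(pfams, role)
            if role == "receptor":
                truth_rows.append((genome_id, tag, kind, verdict))
    truth = pd.DataFrame(
        truth_rows, columns=["genome", "receptor_locus", "cassette", "intended_verdict"]
    )
    return GenomeRecord(id=genome_id, features=features), domain_table, truth


def write_genome_files(
    genome: GenomeRecord,
    domain_table: dict[str, frozenset[str]],
    out_dir,
    seed: int = 0,
) -> tuple[Path, Path]:
    """Write the genome as a GenBank flat file plus the sidecar domain TSV.

    The nucleotide sequence is random filler — only the feature table
    carries information for the miner.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    total = max(f.end for f in genome.features) + 100
    seq = "".join(DNA[i] for i in rng.integers(4, size=total))
    record = BioSeqRecord(Seq(seq), id=genome.id, name=genome.id[:16],
                          description="synthetic genome with planted operons")
    record.annotations["molecule_type"] = "DNA"
    for f in genome.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=f.strand),
                type="CDS",
                qualifiers={"locus_tag": [f.locus_tag], "product": [f.product]},
            )
        )
    gbk = out_dir / f"{genome.id}.gbk"
    SeqIO.write([record], str(gbk), "genbank")
    tsv = out_dir / f"{genome.id}.domains.tsv"
    with open(tsv, "w") as fh:
        for tag in sorted(domain_table):
            fh.write(f"{tag}\t{','.join(sorted(domain_table[tag]))}\n")
    return gbk, tsv


# ---------------------------------------------------------------------------
# two-domain structures with a planted hinge rotation


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def make_two_domain(
    angle: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_dbd: int = 65,
    n_total: int = 220,
) -> tuple[CaTrace, CaTrace, dict]:
    """Apo/holo Ca trace pair differing by a planted DBD hinge rotation.

    The apo trace has a compact DBD cluster (residues 1..n_dbd) and an LBD
    cluster (n_dbd+1..n_total).  The holo trace is a copy with the DBD
    rotated by ``angle`` degrees about a random axis through the hinge point
    (the centroid of the boundary residue pair), plus optional Gaussian
    coordinate noise.
    """
    if not (0.0 <= angle <= 180.0):
        raise ValueError("angle must lie in [0, 180] degrees")
    rng = np.random.default_rng(seed)
    # jittered helical-ish walks keep clusters compact but non-degenerate
    dbd = np.cumsum(rng.normal(0.0, 1.5, size=(n_dbd, 3)), axis=0)
    lbd = np.cumsum(rng.normal(0.0, 1.5, size=(n_total - n_dbd, 3)), axis=0)
    lbd += np.array([25.0, 0.0, 0.0]) - lbd[0] + dbd[-1]
    apo_coords = np.vstack([dbd, lbd])

    hinge = (apo_coords[n_dbd - 1] + apo_coords[n_dbd]) / 2.0
    axis = rng.normal(size=3)
    holo_coords = apo_coords.copy()
    if angle != 0.0:  # keep the zero-angle copy bit-identical
        R = _rotation_about_axis(axis, angle)
        holo_coords[:n_dbd] = (apo_coords[:n_dbd] - hinge) @ R.T + hinge
    if noise_sd > 0:
        holo_coords = holo_coords + rng.normal(0.0, noise_sd, size=holo_coords.shape)

    def as_trace(coords: np.ndarray, chain: str) -> CaTrace:
        return CaTrace(
            chain_id=chain,
            residues=[(i + 1, "ALA", tuple(coords[i])) for i in range(len(coords))],
        )

    truth = {"angle": angle, "noise_sd": noise_sd, "n_dbd": n_dbd, "n_total": n_total}
    return as_trace(apo_coords, "A"), as_trace(holo_coords, "B"), truth


# ---------------------------------------------------------------------------
# MSAs with target per-column conservation


def _majority_probability(target: float) -> float:
    """Majority-residue probability whose 20-letter mixture entropy yields
    the requested conservation score ``1 - H/ln20``."""
    if target >= 1.0:
        return 1.0
    if target <= 0.0:
        return 0.05

    def h(p: float) -> float:
        rest = (1.0 - p) / 19.0
        out = -p * math.log(p)
        if rest > 0:
            out -= 19.0 * rest * math.log(rest)
        return out

    want = (1.0 - target) * LN20
    # h(p) decreases from ln20 at p=1/20 to 0 at p=1
    return brentq(lambda p: h(p) - want, 0.05, 1.0 - 1e-12)


def make_msa(targets, n_seqs: int = 200, seed: int = 0) -> tuple[Msa, pd.DataFrame]:
    """Gap-free MSA whose columns hit the requested conservation targets.

    Per column, a majority residue is drawn with the probability that makes
    the expected entropy-based score equal the target; the remaining mass is
    uniform over the other 19 residues.
    """
    targets = list(targets)
    if any(not (0.0 <= t <= 1.0) for t in targets):
        raise ValueError("targets must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    columns = []
    rows_truth = []
    for ci, t in enumerate(targets):
        p = _majority_probability(t)
        maj = AMINO_ACIDS[rng.integers(20)]
        others = AMINO_ACIDS.replace(maj, "")
        col = [
            maj if rng.random() < p else others[rng.integers(19)]
            for _ in range(n_seqs)
        ]
        columns.append(col)
        rows_truth.append((ci + 1, t, p, maj))
    records = [
        (f"seq{i + 1}", "".join(columns[c][i] for c in range(len(targets))))
        for i in range(n_seqs)
    ]
    truth = pd.DataFrame(rows_truth, columns=["column", "target_score", "majority_p", "majority_aa"])
    return Msa(records=records), truth


# ---------------------------------------------------------------------------
# operator palindromization


def palindromize(half_site: str) -> str:
    """Half-site concatenated with its reverse complement.

    Turns a pseudopalindromic operator half into a perfect palindrome — the
    output is its own reverse complement, suitable for symmetric
    protein-DNA co-crystallization constructs.
    """
    site = half_site.upper()
    bad = set(site) - set(DNA)
    if bad or not site:
        raise ValueError(f"half-site must be non-empty over ACGT, got {half_site!r}")
    return site + site.translate(COMPLEMENT)[::-1]
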