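"""Sequence similarity networks with family-exclusivity threshold calibration.

A sequence similarity network (SSN) represents each protein as a node and
draws an undirected edge between two proteins when their pairwise local
alignment is more significant than an E-value cutoff.  For hormone-receptor
families, the cutoff can be calibrated so that characterized receptors of
distinct ligand classes (gamma-butyrolactone, butenolide, methylenomycin
furan, ...) never share a connected component — "mutually exclusive
co-localization".  This module scores pairs (BLOSUM62, affine gaps 11/1),
converts raw scores to bit scores with gapped Karlin-Altschul statistics,
builds the network, and scans a descending threshold grid for the most
permissive exclusive cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SeqRecord",
    "PairScore",
    "SSNGraph",
    "ExclusivityReport",
    "align_pair",
    "evalue",
    "bit_score",
    "build_ssn",
    "components",
    "exclusivity",
    "find_exclusive_threshold",
    "default_threshold_grid",
    "write_edge_list",
    "write_components",
    "DEFAULT_THRESHOLD",
]

# Amino-acid alphabet accepted in input sequences; X = unknown residue.
VALID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# Gapped Karlin-Altschul constants for BLOSUM62 with gap open 11 / extend 1,
# as used by protein search tools for bit-score conversion.
KA_LAMBDA = 0.267
KA_K = 0.041

#: Shipped default E-value cutoff for receptor-family mining.
DEFAULT_THRESHOLD = 1e-70


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence with an identifier and optional family label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")
        bad = set(self.sequence.upper()) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence for {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairScore:
    """Local-alignment score between two sequences, with significance."""

    query_id: str
    target_id: str
    raw_score: float
    bit_score: float
    e_value: float


@dataclass
class SSNGraph:
    """Undirected similarity network thresholded at a fixed E-value."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["e_value"]) for u, v, d in self.graph.edges(data=True)]


@dataclass
class ExclusivityReport:
    threshold: float
    n_components: int
    impure_components: int
    is_exclusive: bool


_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner(mode="local")
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def bit_score(raw_score: float) -> float:
    """Convert a raw BLOSUM62 alignment score to bits.

    Uses the standard gapped Karlin-Altschul form
    ``S' = (lambda*S - ln K) / ln 2``.
    """
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue(bit: float, m: int, n: int) -> float:
    """Expected number of chance hits: ``E = m * n * 2**(-bit)``.

    ``m`` is the query length, ``n`` the effective database length.
    """
    if m < 1 or n < 1:
        raise ValueError(f"lengths must be >= 1, got m={m}, n={n}")
    if not math.isfinite(bit):
        raise ValueError("bit score must be finite")
    # 2**(-bit) underflows double precision near bit ~ 1074; go through logs
    # and clamp to the smallest subnormal so E stays strictly positive.
    log_e = math.log(m) + math.log(n) - bit * math.log(2.0)
    e = math.exp(log_e)
    return e if e > 0.0 else 5e-324


def align_pair(a: SeqRecord, b: SeqRecord, db_size: int | None = None) -> PairScore:
    """Score a pair of sequences by local alignment (BLOSUM62, gaps 11/1).

    The E-value uses the query length of the lexicographically smaller id so
    that the result is symmetric in ``(a, b)``.  ``db_size`` defaults to
    ``len(a) + len(b)`` when the pair is scored outside an all-vs-all set.
    """
    raw = float(_get_aligner().score(a.sequence.upper(), b.sequence.upper()))
    bits = bit_score(raw)
    first, second = (a, b) if a.id <= b.id else (b, a)
    n = db_size if db_size is not None else len(a) + len(b)
    return PairScore(
        query_id=a.id,
        target_id=b.id,
        raw_score=raw,
        bit_score=bits,
        e_value=evalue(bits, len(first), n),
    )


def _all_pair_scores(records: Sequence[SeqRecord]) -> list[PairScore]:
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input")
    db_size = sum(len(r) for r in records)
    scores = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            scores.append(align_pair(records[i], records[j], db_size=db_size))
    return scores


def build_ssn(
    records: Sequence[SeqRecord],
    threshold: float = DEFAULT_THRESHOLD,
    pair_scores: Iterable[PairScore] | None = None,
) -> SSNGraph:
    """All-vs-all similarity network with edges at ``e_value <= threshold``.

    ``pair_scores`` allows reusing precomputed scores (threshold calibration
    re-thresholds the same alignments many times).
    """
    if not records:
        raise ValueError("need at least one record")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if pair_scores is None:
        pair_scores = _all_pair_scores(records)
    g = nx.Graph()
    for r in records:
        g.add_node(r.id, label=r.label)
    for ps in pair_scores:
        if ps.query_id != ps.target_id and ps.e_value <= threshold:
            g.add_edge(ps.query_id, ps.target_id, e_value=ps.e_value, bit_score=ps.bit_score)
    return SSNGraph(graph=g, threshold=threshold)


def components(ssn: SSNGraph) -> list[set[str]]:
    """Connected components of the network, sorted for determinism."""
    comps = [set(c) for c in nx.connected_components(ssn.graph)]
    return sorted(comps, key=lambda c: min(c))


def exclusivity(partition: Sequence[set[str]], labels: Mapping[str, str]) -> ExclusivityReport:
    """Check whether no component mixes two distinct family labels.

    Unlabeled ids are ignored.  A label occupying several pure components is
    still exclusive; only mixed (impure) components break exclusivity.
    """
    all_ids = set().union(*partition) if partition else set()
    unknown = set(labels) - all_ids
    if unknown:
        raise ValueError(f"label map references unknown ids: {sorted(unknown)[:5]}")
    impure = 0
    for comp in partition:
        comp_labels = {labels[i] for i in comp if i in labels}
        if len(comp_labels) >= 2:
            impure += 1
    return ExclusivityReport(
        threshold=math.nan,
        n_components=len(partition),
        impure_components=impure,
        is_exclusive=impure == 0,
    )


def default_threshold_grid() -> list[float]:
    """Descending decade grid 1e-10 ... 1e-120."""
    return [10.0 ** (-k) for k in range(10, 121, 10)]


def find_exclusive_threshold(
    records: Sequence[SeqRecord],
    labels: Mapping[str, str] | None = None,
    grid: Sequence[float] | None = None,
) -> float | None:
    """Most permissive grid threshold giving mutually exclusive co-localization.

    The grid is scanned from permissive (large E) to strict; the first
    threshold whose network is exclusive is returned, or ``None`` if even the
    strictest grid value mixes families.  Deterministic for fixed inputs.
    """
    if labels is None:
        labels = {r.id: r.label for r in records if r.label is not None}
    if grid is None:
        grid = default_threshold_grid()
    grid = sorted(grid, reverse=True)
    scores = _all_pair_scores(records)
    for t in grid:
        ssn = build_ssn(records, threshold=t, pair_scores=scores)
        report = exclusivity(components(ssn), labels)
        if report.is_exclusive:
            return t
    return None


def write_edge_list(ssn: SSNGraph, path) -> None:
    """Edge list TSV (source, target, e_value, bit_score) for Cytoscape import."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\te_value\tbit_score\n")
        for u, v, d in sorted(ssn.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['e_value']:.6g}\t{d['bit_score']:.2f}\n")


def write_components(ssn: SSNGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcomponent\tlabel\n")
        for ci, comp in enumerate(components(ssn)):
            for node in sorted(comp):
                label = ssn.graph.nodes[node].get("label") or ""
                fh.write(f"{node}\t{ci}\t{label}\n")
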