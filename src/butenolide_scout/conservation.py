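"""Per-column conservation scoring and mapping onto a reference structure.

Conservation of each alignment column is scored by gap-penalized normalized
Shannon entropy::

    score = (1 - H / ln 20) * (1 - gap_fraction)

where H is the entropy of the amino-acid frequencies in the column (gaps
excluded from H).  Scores lie in [0, 1]: 1 for a fully conserved gap-free
column, 0 for a uniformly random or all-gap column.  Scores are mapped
through a reference record onto structure residue numbers and can be painted
into the B-factor field of a PDB file (score x 100; unmapped residues get a
-1 sentinel), the standard trick for coloring structures by an external
per-residue quantity.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import gemmi
import pandas as pd
from Bio import AlignIO

__all__ = [
    "Msa",
    "ConservationProfile",
    "BindingSiteSpec",
    "read_msa",
    "column_conservation",
    "paint_structure",
    "binding_site_report",
]

LN20 = math.log(20.0)
UNMAPPED_BFACTOR = -1.0


@dataclass
class Msa:
    """Aligned records: list of (id, gapped sequence), all equal length."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs >= 2 records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in length")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def record(self, ref_id: str) -> str:
        for rid, seq in self.records:
            if rid == ref_id:
                return seq
        raise KeyError(f"record {ref_id!r} not in alignment")


@dataclass
class ConservationProfile:
    scores: list[float]
    gap_fraction: list[float]
    ref_map: list[int | None]  # column -> 1-based reference residue number
    majority: list[str | None]
    ref_id: str

    def score_by_refpos(self) -> dict[int, float]:
        return {
            pos: s for pos, s in zip(self.ref_map, self.scores) if pos is not None
        }

    def majority_by_refpos(self) -> dict[int, str | None]:
        return {
            pos: aa for pos, aa in zip(self.ref_map, self.majority) if pos is not None
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": range(1, len(self.scores) + 1),
                "refpos": [p if p is not None else "" for p in self.ref_map],
                "score": self.scores,
                "gap_fraction": self.gap_fraction,
            }
        )


@dataclass
class BindingSiteSpec:
    """Residues expected at the ligand-binding site, e.g. (64, 'Q')."""

    residues: list[tuple[int, str]]

    def __post_init__(self) -> None:
        nums = [n for n, _ in self.residues]
        if any(n <= 0 for n in nums) or len(set(nums)) != len(nums):
            raise ValueError("residue numbers must be positive and unique")


def read_msa(path) -> Msa:
    aln = AlignIO.read(str(path), "fasta")
    return Msa(records=[(r.id, str(r.seq).upper()) for r in aln])


def column_conservation(msa: Msa, ref_id: str | None = None) -> ConservationProfile:
    """Score every column and build the reference residue-number map.

    The reference record defaults to the first in the alignment; columns
    where the reference has a gap map to ``None``.
    """
    if ref_id is None:
        ref_id = msa.records[0][0]
    ref_seq = msa.record(ref_id)
    n = len(msa.records)
    scores, gapfracs, ref_map, majority = [], [], [], []
    refpos = 0
    for col in range(msa.length):
        column = [seq[col] for _, seq in msa.records]
        gaps = sum(1 for c in column if c == "-")
        residues = [c for c in column if c != "-"]
        gap_fraction = gaps / n
        if not residues:
            score, maj = 0.0, None  # all-gap column
        else:
            counts = Counter(residues)
            total = len(residues)
            h = -sum((k / total) * math.log(k / total) for k in counts.values())
            score = (1.0 - h / LN20) * (1.0 - gap_fraction)
            maj = counts.most_common(1)[0][0]
        scores.append(max(0.0, min(1.0, score)))
        gapfracs.append(gap_fraction)
        majority.append(maj)
        if ref_seq[col] != "-":
            refpos += 1
            ref_map.append(refpos)
        else:
            ref_map.append(None)
    return ConservationProfile(
        scores=scores, gap_fraction=gapfracs, ref_map=ref_map,
        majority=majority, ref_id=ref_id,
    )


def paint_structure(
    profile: ConservationProfile,
    structure: gemmi.Structure | str,
    out_path=None,
    offset: int = 0,
) -> gemmi.Structure:
    """Write conservation scores into the B-factor column of a structure.

    Residues whose (structure number + offset) matches a mapped reference
    position get ``score * 100``; others get the -1 sentinel.  Mapping is by
    residue-number identity — no re-alignment.
    """
    if isinstance(structure, (str,)) or hasattr(structure, "__fspath__"):
        structure = gemmi.read_structure(str(structure))
    by_pos = profile.score_by_refpos()
    n_hit = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                pos = residue.seqid.num + offset
                if pos in by_pos:
                    b = by_pos[pos] * 100.0
                    n_hit += 1
                else:
                    b = UNMAPPED_BFACTOR
                for atom in residue:
                    atom.b_iso = b
    if n_hit == 0:
        raise ValueError("no residues in common between profile and structure")
    if out_path is not None:
        structure.setup_entities()
        structure.write_pdb(str(out_path))
    return structure


def binding_site_report(profile: ConservationProfile, spec: BindingSiteSpec) -> pd.DataFrame:
    """Tabulate conservation at nominated binding-site residues.

    Flags residues whose majority amino acid differs from the expectation;
    residues outside the mapped reference range get a warning row with a
    missing score.
    """
    scores = profile.score_by_refpos()
    majorities = profile.majority_by_refpos()
    rows = []
    for resnum, expected in spec.residues:
        if resnum not in scores:
            warnings.warn(f"binding-site residue {resnum} not mapped in profile", stacklevel=2)
            rows.append((resnum, expected, None, None, False))
            continue
        maj = majorities[resnum]
        rows.append((resnum, expected, scores[resnum], maj, maj == expected))
    return pd.DataFrame(
        rows, columns=["residue", "expected_aa", "score", "majority_aa", "matches_expected"]
    )
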