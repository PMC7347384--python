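"""Rigid superposition and quantification of the hormone-induced DBD shift.

TetR-family receptors are two-domain proteins: a DNA-binding domain (DBD,
helices a1-a4) and a ligand-binding domain (LBD, helices a5-a13).  Hormone
binding re-orients the DBD relative to the LBD.  The shift is quantified by
(1) pairing apo and holo Ca atoms by residue number, (2) superposing the
holo structure onto the apo structure using LBD pairs only, and (3) fitting
the residual rigid rotation that maps the apo DBD onto the LBD-aligned holo
DBD; the angle of that rotation is the reported domain shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "CaTrace",
    "Superposition",
    "DomainRanges",
    "DomainShiftResult",
    "read_ca_trace",
    "write_ca_trace",
    "kabsch",
    "rotation_angle",
    "domain_shift",
]


@dataclass
class CaTrace:
    """Ordered Ca coordinates of one chain: (resnum, aa, xyz)."""

    chain_id: str
    residues: list[tuple[int, str, tuple[float, float, float]]]

    def __post_init__(self) -> None:
        nums = [n for n, _, _ in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        coords = np.array([xyz for _, _, xyz in self.residues], dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    def coords(self) -> np.ndarray:
        return np.array([xyz for _, _, xyz in self.residues], dtype=float)

    def numbers(self) -> list[int]:
        return [n for n, _, _ in self.residues]

    def subset(self, resnums) -> "CaTrace":
        wanted = set(resnums)
        return CaTrace(
            chain_id=self.chain_id,
            residues=[r for r in self.residues if r[0] in wanted],
        )


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DomainRanges:
    """Residue-number intervals of the two domains, e.g. dbd=[(1, 65)]."""

    dbd: list[tuple[int, int]]
    lbd: list[tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.dbd + self.lbd)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("domain intervals overlap")

    @staticmethod
    def _members(intervals, nums):
        return [n for n in nums if any(a <= n <= b for a, b in intervals)]

    def dbd_members(self, nums):
        return self._members(self.dbd, nums)

    def lbd_members(self, nums):
        return self._members(self.lbd, nums)


# Default AvaR1-like split: DBD = N-terminal ~65 residues, LBD = the rest.
DEFAULT_RANGES = DomainRanges(dbd=[(1, 65)], lbd=[(66, 10000)])


@dataclass
class DomainShiftResult:
    angle: float  # degrees
    rmsd_lbd: float  # after LBD fit
    rmsd_dbd: float  # DBD residual before the domain fit
    n_pairs: int


def read_ca_trace(path, chain: str | None = None) -> CaTrace:
    """Ca trace of one chain from a PDB file; first altloc kept."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"no chains in {path}")
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = next((c for c in model if c.name == chain), None)
        if ch is None:
            raise ValueError(f"chain {chain!r} absent from {path}")
    residues = []
    for res in ch:
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                ca = atom
                break
        if ca is None:
            continue  # residue without a Ca (het, incomplete) — skipped
        residues.append((res.seqid.num, res.name, (ca.pos.x, ca.pos.y, ca.pos.z)))
    return CaTrace(chain_id=ch.name, residues=residues)


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_ca_trace(trace: CaTrace, path) -> None:
    """Write a Ca-only PDB file (ATOM records at standard precision)."""
    with open(path, "w") as fh:
        for i, (num, aa, (x, y, z)) in enumerate(trace.residues, start=1):
            name3 = aa if len(aa) == 3 else _AA3.get(aa, "UNK")
            fh.write(
                f"ATOM  {i:5d}  CA  {name3:>3s} {trace.chain_id:1s}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C\n"
            )
        fh.write("END\n")


def kabsch(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares rigid transform of Q onto P (proper rotation enforced).

    Returns the rotation R and translation t minimizing ``|R q + t - p|``
    over the paired points, with the RMSD at the optimum.  The sign of the
    smallest singular direction is flipped when the raw SVD solution is a
    reflection.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need matching Nx3 coordinate arrays with N >= 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10:  # rank < 2: collinear or coincident points
        raise ValueError("degenerate geometry: points are (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = Q0 @ R.T - P0
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle in degrees: ``arccos((trace - 1)/2)``, in [0, 180]."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or abs(np.linalg.det(R) - 1) > 1e-6:
        raise ValueError("not a proper rotation matrix")
    c = (np.trace(R) - 1.0) / 2.0
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def domain_shift(
    apo: CaTrace, holo: CaTrace, ranges: DomainRanges = DEFAULT_RANGES
) -> DomainShiftResult:
    """Angle of the DBD rotation between two conformations.

    Residues are paired by number; the holo trace is superposed on the apo
    trace using LBD pairs; the rigid rotation mapping the apo DBD onto the
    LBD-aligned holo DBD is then fitted and its angle reported.
    """
    shared = sorted(set(apo.numbers()) & set(holo.numbers()))
    lbd_nums = ranges.lbd_members(shared)
    dbd_nums = ranges.dbd_members(shared)
    if len(lbd_nums) < 3 or len(dbd_nums) < 3:
        raise ValueError(
            f"insufficient shared residues: {len(lbd_nums)} LBD, {len(dbd_nums)} DBD"
        )
    apo_lbd = apo.subset(lbd_nums).coords()
    holo_lbd = holo.subset(lbd_nums).coords()
    lbd_fit = kabsch(apo_lbd, holo_lbd)

    apo_dbd = apo.subset(dbd_nums).coords()
    holo_dbd_aligned = lbd_fit.apply(holo.subset(dbd_nums).coords())
    rmsd_dbd = float(np.sqrt(((holo_dbd_aligned - apo_dbd) ** 2).sum(axis=1).mean()))
    dbd_fit = kabsch(holo_dbd_aligned, apo_dbd)
    return DomainShiftResult(
        angle=rotation_angle(dbd_fit.rotation),
        rmsd_lbd=lbd_fit.rmsd,
        rmsd_dbd=rmsd_dbd,
        n_pairs=len(lbd_nums) + len(dbd_nums),
    )
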