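"""Residue-pair labels for a complex from its 3-D structure.

Positive labels are produced in two stages: seed pairs from a heavy-atom
contact criterion (default < 5 A), then expansion to residues flanking
each seed by up to +/-2 sequence positions whose representative-atom
distance stays within a 10 A cap. Everything else on the M x N grid is a
negative.

Indices are 1-based sequence positions matching the feature matrices;
residues missing from the structure simply never appear in labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class Residue:
    """One residue: 1-based sequence index, 3-letter-or-1-letter name, atoms."""

    index: int
    name: str
    atoms: tuple[tuple[str, tuple[float, float, float]], ...]  # (atom name, xyz)
    elements: tuple[str, ...]

    def heavy_coords(self) -> np.ndarray:
        coords = [
            xyz
            for (_, xyz), el in zip(self.atoms, self.elements)
            if el not in HYDROGEN_ELEMENTS
        ]
        if not coords:
            raise ValueError(f"residue {self.index} has no heavy-atom coordinates")
        return np.asarray(coords, dtype=float)

    def representative_coord(self, mode: str = "CB") -> np.ndarray:
        """Representative atom: CB (CA fallback, e.g. glycine), CA, or centroid."""
        by_name = {name: np.asarray(xyz, float) for name, xyz in self.atoms}
        if mode == "CB":
            for name in ("CB", "CA"):
                if name in by_name:
                    return by_name[name]
        elif mode == "CA":
            if "CA" in by_name:
                return by_name["CA"]
        elif mode == "centroid":
            return self.heavy_coords().mean(axis=0)
        else:
            raise ValueError(f"unknown representative-atom mode {mode!r}")
        return self.heavy_coords().mean(axis=0)


@dataclass(frozen=True)
class StructurePair:
    """Two chains of one complex, each an ordered residue list."""

    chainA: tuple[Residue, ...]
    chainB: tuple[Residue, ...]

    def __post_init__(self) -> None:
        for label, chain in (("A", self.chainA), ("B", self.chainB)):
            if not chain:
                raise ValueError(f"chain {label} is empty")
            idx = [r.index for r in chain]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"chain {label}: residue indices not strictly increasing")
            for r in chain:
                coords = np.array([xyz for _, xyz in r.atoms], dtype=float)
                if coords.size == 0:
                    raise ValueError(f"chain {label} residue {r.index} has no coordinates")
                if not np.isfinite(coords).all():
                    raise ValueError(f"chain {label} residue {r.index} has non-finite coordinates")


@dataclass(frozen=True)
class PairLabelSet:
    """Positive/negative labels over the M x N residue-pair grid."""

    M: int
    N: int
    positives: frozenset[tuple[int, int]]
    provenance: str = "seed"  # "seed" | "expanded"

    def __post_init__(self) -> None:
        for i, j in self.positives:
            if not (1 <= i <= self.M and 1 <= j <= self.N):
                raise ValueError(f"pair ({i}, {j}) outside 1..{self.M} x 1..{self.N}")

    def negatives(self) -> frozenset[tuple[int, int]]:
        """Complement of the positives on the full grid."""
        full = {
            (i, j) for i in range(1, self.M + 1) for j in range(1, self.N + 1)
        }
        return frozenset(full - self.positives)

    def as_matrix(self) -> np.ndarray:
        out = np.zeros((self.M, self.N), dtype=int)
        for i, j in self.positives:
            out[i - 1, j - 1] = 1
        return out


def read_structure_pair(
    path: str | Path, chain_a: str, chain_b: str
) -> StructurePair:
    """Load two chains from a PDB file (first model, standard residues only)."""
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    model = next(iter(parser.get_structure("complex", str(path))))
    chains = {}
    for cid in (chain_a, chain_b):
        if cid not in model:
            raise ValueError(f"chain {cid!r} not found in {path}")
        residues = []
        for res in model[cid]:
            if not is_aa(res, standard=False):
                continue
            atoms = tuple(
                (atom.get_name(), tuple(map(float, atom.coord))) for atom in res
            )
            elements = tuple(atom.element.strip().upper() or atom.get_name()[0] for atom in res)
            residues.append(
                Residue(
                    index=res.id[1],
                    name=res.get_resname(),
                    atoms=atoms,
                    elements=elements,
                )
            )
        chains[cid] = tuple(residues)
    return StructurePair(chainA=chains[chain_a], chainB=chains[chain_b])


def _chain_lengths(s: StructurePair) -> tuple[int, int]:
    return s.chainA[-1].index, s.chainB[-1].index


def seed_interface_pairs(
    s: StructurePair, heavy_atom_cutoff: float = 5.0
) -> PairLabelSet:
    """Residue pairs with any heavy-atom distance below the cutoff."""
    coords_a, owner_a = [], []
    for res in s.chainA:
        hc = res.heavy_coords()
        coords_a.append(hc)
        owner_a.extend([res.index] * len(hc))
    coords_b, owner_b = [], []
    for res in s.chainB:
        hc = res.heavy_coords()
        coords_b.append(hc)
        owner_b.extend([res.index] * len(hc))
    pts_a = np.vstack(coords_a)
    pts_b = np.vstack(coords_b)
    tree_a = cKDTree(pts_a)
    tree_b = cKDTree(pts_b)
    pairs = set()
    for ia, neighbors in enumerate(
        tree_a.query_ball_tree(tree_b, r=heavy_atom_cutoff)
    ):
        for ib in neighbors:
            # query_ball_tree includes distance == r; the criterion is strict
            if np.linalg.norm(pts_a[ia] - pts_b[ib]) < heavy_atom_cutoff:
                pairs.add((owner_a[ia], owner_b[ib]))
    m, n = _chain_lengths(s)
    return PairLabelSet(M=m, N=n, positives=frozenset(pairs), provenance="seed")


def expand_labels(
    seeds: PairLabelSet,
    s: StructurePair,
    flank: int = 2,
    cap: float = 10.0,
    representative: str = "CB",
) -> PairLabelSet:
    """Grow each seed to its +/-flank neighborhood under a distance cap.

    A flanking pair (i', j') with |i'-i| <= flank and |j'-j| <= flank is
    kept iff the representative-atom distance (default CB, CA for glycine)
    is <= cap and both residues are present in the structure.
    """
    rep_a = {
        r.index: r.representative_coord(representative) for r in s.chainA
    }
    rep_b = {
        r.index: r.representative_coord(representative) for r in s.chainB
    }
    out = set()
    for i, j in seeds.positives:
        for di in range(-flank, flank + 1):
            for dj in range(-flank, flank + 1):
                ii, jj = i + di, j + dj
                if not (1 <= ii <= seeds.M and 1 <= jj <= seeds.N):
                    continue
                if ii not in rep_a or jj not in rep_b:
                    continue
                dist = float(np.linalg.norm(rep_a[ii] - rep_b[jj]))
                if dist <= cap:
                    out.add((ii, jj))
    return PairLabelSet(
        M=seeds.M, N=seeds.N, positives=frozenset(out), provenance="expanded"
    )


def negatives(labels: PairLabelSet) -> frozenset[tuple[int, int]]:
    """All grid pairs not labeled positive; |pos| + |neg| = M * N."""
    return labels.negatives()


def write_labels_tsv(labels: PairLabelSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tlabel\tprovenance\n")
        pos = labels.positives
        for i in range(1, labels.M + 1):
            for j in range(1, labels.N + 1):
                lab = 1 if (i, j) in pos else 0
                fh.write(f"{i}\t{j}\t{lab}\t{labels.provenance if lab else '.'}\n")


def read_labels_tsv(path: str | Path) -> PairLabelSet:
    pos = set()
    m = n = 0
    provenance = "seed"
    for ln in Path(path).read_text().strip().splitlines():
        if ln.startswith("i\t"):
            continue
        i, j, lab, prov = ln.split("\t")
        i, j = int(i), int(j)
        m, n = max(m, i), max(n, j)
        if lab == "1":
            pos.add((i, j))
            provenance = prov
    return PairLabelSet(M=m, N=n, positives=frozenset(pos), provenance=provenance)
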