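"""Seed-deterministic synthetic fixtures for every pipeline stage.

Generates idealized two-chain complexes with an exactly planted interface,
matching per-residue annotations, and concatenated alignments carrying
planted inter-column covariation, so the full pipeline is testable without
external data. Geometry is deliberately schematic: residues are CA/CB
pseudo-atom pairs on a line, chains far apart except at planted contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ALL_FEATURES, ResidueAnnotations
from .labeling import PairLabelSet, Residue, StructurePair
from .msa import AMINO_ACIDS, ConcatenatedAlignment

#: Spacing between consecutive residues along a chain (A).
RESIDUE_SPACING = 8.0

#: y-offset separating the chains away from planted contacts (A).
FAR_OFFSET = 60.0

#: y-distance of a planted contact (under the 5 A seed criterion).
CONTACT_DISTANCE = 3.0

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Parameters of one synthetic complex + alignment fixture."""

    M: int
    N: int
    n_interface: int
    coupling: float = 0.9
    n_sequences: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.M, self.N, self.n_interface, self.n_sequences) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_interface > min(self.M, self.N):
            raise ValueError("n_interface cannot exceed the shorter chain")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [0, 1]")


def _make_residue(index: int, letter: str, base: np.ndarray) -> Residue:
    ca = tuple(float(v) for v in base)
    cb = tuple(float(v) for v in base + np.array([0.0, 0.0, 1.5]))
    return Residue(
        index=index,
        name=THREE_LETTER[letter],
        atoms=(("CA", ca), ("CB", cb)),
        elements=("C", "C"),
    )


def _ssp_runs(length: int, rng: np.random.Generator) -> tuple[str, ...]:
    out: list[str] = []
    while len(out) < length:
        out.extend([rng.choice(["H", "E", "C"])] * int(rng.integers(3, 9)))
    return tuple(out[:length])


def gen_complex(
    spec: SyntheticComplexSpec,
) -> tuple[StructurePair, ResidueAnnotations, ResidueAnnotations, PairLabelSet, str, str]:
    """Build a toy complex whose seed interface is exactly the planted pairs.

    Returns ``(structure, annotations_A, annotations_B, truth, seqA, seqB)``.
    Planted pairs sit at 3 A (seed-positive); every other inter-chain
    residue pair is at least 8 A apart. A designated subset of
    non-interface residues is buried (RSA exactly 0); remaining RSA values
    are drawn from (0, 1]; secondary structure is assigned in runs.
    """
    rng = np.random.default_rng(spec.seed)
    seq_a = "".join(rng.choice(list(AMINO_ACIDS), size=spec.M))
    seq_b = "".join(rng.choice(list(AMINO_ACIDS), size=spec.N))

    planted_i = rng.choice(np.arange(1, spec.M + 1), size=spec.n_interface, replace=False)
    planted_j = rng.choice(np.arange(1, spec.N + 1), size=spec.n_interface, replace=False)
    truth_pairs = frozenset(
        (int(i), int(j)) for i, j in zip(np.sort(planted_i), np.sort(planted_j))
    )
    j_to_i = {j: i for i, j in truth_pairs}

    chain_a = tuple(
        _make_residue(i, seq_a[i - 1], np.array([(i - 1) * RESIDUE_SPACING, 0.0, 0.0]))
        for i in range(1, spec.M + 1)
    )
    chain_b_res = []
    for j in range(1, spec.N + 1):
        if j in j_to_i:
            base = np.array(
                [(j_to_i[j] - 1) * RESIDUE_SPACING, CONTACT_DISTANCE, 0.0]
            )
        else:
            base = np.array([(j - 1) * RESIDUE_SPACING, FAR_OFFSET, 0.0])
        chain_b_res.append(_make_residue(j, seq_b[j - 1], base))
    structure = StructurePair(chainA=chain_a, chainB=tuple(chain_b_res))

    interface_a = {i for i, _ in truth_pairs}
    interface_b = {j for _, j in truth_pairs}

    def annotations(length: int, interface: set[int]) -> ResidueAnnotations:
        rsa = rng.uniform(0.05, 1.0, size=length)
        surface_pool = [k for k in range(1, length + 1) if k not in interface]
        n_buried = max(1, length // 5)
        buried = rng.choice(surface_pool, size=min(n_buried, len(surface_pool)), replace=False)
        for k in buried:
            rsa[k - 1] = 0.0
        return ResidueAnnotations(rsa=rsa, ssp=_ssp_runs(length, rng))

    ann_a = annotations(spec.M, interface_a)
    ann_b = annotations(spec.N, interface_b)
    truth = PairLabelSet(M=spec.M, N=spec.N, positives=truth_pairs, provenance="seed")
    return structure, ann_a, ann_b, truth, seq_a, seq_b


def gen_coupled_msa(
    spec: SyntheticComplexSpec, truth: PairLabelSet
) -> ConcatenatedAlignment:
    """Concatenated alignment with covariation planted at the truth pairs.

    Background columns are i.i.d. uniform over the 20 residues. For each
    truth pair (i, j), each sequence's residue at protein-B column j is,
    with probability ``coupling``, the image of its protein-A column-i
    residue under a fixed random bijection of the residue alphabet.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n, width = spec.n_sequences, spec.M + spec.N
    letters = np.array(list(AMINO_ACIDS))
    mat = rng.integers(0, 20, size=(n, width))
    for i, j in sorted(truth.positives):
        if not (1 <= i <= spec.M and 1 <= j <= spec.N):
            raise ValueError(f"truth pair ({i}, {j}) outside the chain lengths")
        bijection = rng.permutation(20)
        coupled = rng.random(n) < spec.coupling
        col_b = spec.M + j - 1
        mat[coupled, col_b] = bijection[mat[coupled, i - 1]]
    rows = tuple(
        (f"sp{k:05d}", "".join(letters[mat[k]])) for k in range(n)
    )
    return ConcatenatedAlignment(rows=rows, lenA=spec.M, lenB=spec.N, name="synthetic")


def gen_separable_table(
    n_pos: int = 200,
    n_neg: int = 1000,
    shift: float = 0.4,
    seed: int = 0,
    informative: tuple[str, ...] = ALL_FEATURES,
    complex_id: str = "synth",
) -> pd.DataFrame:
    """Training table with positives drawn from a shifted feature distribution.

    Negatives are N(0.3, 0.1) per feature, positives N(0.3 + shift, 0.1)
    on the ``informative`` features (all 18 by default), clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    rows = n_pos + n_neg
    data: dict = {
        "complex_id": complex_id,
        "i": np.arange(1, rows + 1),
        "j": np.ones(rows, dtype=int),
    }
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    for f in ALL_FEATURES:
        vals = rng.normal(0.3, 0.1, size=rows)
        if f in informative:
            vals[: n_pos] += shift
        data[f] = np.clip(vals, 0.0, 1.0)
    data["label"] = labels
    return pd.DataFrame(data)


def write_pdb(structure: StructurePair, path: str | Path, chain_ids=("A", "B")) -> None:
    """Write the two chains as a minimal standard PDB file."""
    serial = 1
    with open(path, "w") as fh:
        for cid, chain in zip(chain_ids, (structure.chainA, structure.chainB)):
            for res in chain:
                for (atom_name, (x, y, z)), element in zip(res.atoms, res.elements):
                    fh.write(
                        f"ATOM  {serial:5d} {atom_name:^4s}{res.name:>4s} {cid}"
                        f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n"
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")
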