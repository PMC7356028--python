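"""Pairwise residue feature matrices for an interacting protein pair.

Nine base features are assembled on the M x N residue-pair grid (M residues
of protein A by N of protein B), each min-max scaled to [0, 1]:

===== =======================================================
CMI   co-evolution score (from :mod:`pairiface.coevolution`)
CCM   charge compatibility (20x20 table lookup)
HCM   hydropathy compatibility (20x20 table lookup)
SCM   size compatibility (20x20 table lookup)
RSA   product of per-residue relative solvent accessibilities
SSP   rank of the unordered secondary-structure class pair
CP    inter-residue contact potential
CPE   contact potential variant for exposed residues
CPB   contact potential variant for buried residues
===== =======================================================

The published 20x20 compatibility and contact-potential tables are not
bundled; :func:`default_tables` derives surrogate tables from standard
scalar scales (formal charge class, Kyte-Doolittle hydropathy, residue
volume) so the pipeline and its tests are self-contained. Externally
curated tables can be loaded from 20x20 TSV files with
:func:`read_property_table` and substituted anywhere.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .msa import AMINO_ACIDS

#: Canonical base feature order.
BASE_FEATURES = ("CMI", "CCM", "HCM", "SCM", "RSA", "SSP", "CP", "CPE", "CPB")

#: Canonical 18-feature order: base features then their environment derivatives.
ALL_FEATURES = BASE_FEATURES + tuple("E" + f for f in BASE_FEATURES)

#: 3-class secondary structure codes: H = helix, E = sheet, C = loop/coil.
SSP_CLASSES = ("H", "E", "C")

#: The 6 unordered secondary-structure class pairs.
SSP_PAIRS = (
    frozenset({"H"}),
    frozenset({"H", "E"}),
    frozenset({"H", "C"}),
    frozenset({"E"}),
    frozenset({"E", "C"}),
    frozenset({"C"}),
)

# Kyte-Doolittle hydropathy index.
HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

# Formal side-chain charge class at physiological pH (His counted half).
CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5})

# Residue volumes in cubic angstroms (Zamyatnin).
VOLUME = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
    "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
    "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
    "W": 227.8, "Y": 193.6,
}


@dataclass(frozen=True)
class PropertyTable:
    """A symmetric 20x20 residue-pair property table."""

    name: str
    values: np.ndarray  # indexed by AMINO_ACIDS order

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ValueError(f"table {self.name!r} must be 20x20, got {v.shape}")
        if not np.allclose(v, v.T):
            raise ValueError(f"table {self.name!r} is not symmetric")
        object.__setattr__(self, "values", v)

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.values[AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)])
        except ValueError as exc:
            raise KeyError(f"residue {exc} not in table {self.name!r}") from exc


def _table_from_rule(name: str, rule) -> PropertyTable:
    vals = np.array(
        [[rule(a, b) for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
    )
    return PropertyTable(name=name, values=vals)


def default_tables() -> dict[str, PropertyTable]:
    """Surrogate 20x20 tables derived from scalar residue scales.

    Compatibility rules (documented stand-ins for the unpublished curated
    tables; higher = more compatible / more favorable):

    - CCM: ``-charge(a) * charge(b)`` — opposite charges compatible.
    - HCM: ``-|hydropathy(a) - hydropathy(b)|`` — like hydropathies pair.
    - SCM: ``-|volume(a) - volume(b)|`` — similar volumes pack evenly.
    - CP:  ``-(hydropathy(a) + hydropathy(b)) / 2`` — hydrophobic pairs
      have low (favorable) contact energy.
    - CPE: ``CP/2 + charge(a)*charge(b)`` — exposed contacts weaken the
      hydrophobic term and add electrostatics.
    - CPB: ``1.5*CP - 0.2*|hydropathy(a) - hydropathy(b)|`` — buried
      contacts amplify the hydrophobic term and penalize mismatch.
    """
    h, q, v = HYDROPATHY, CHARGE, VOLUME
    cp = lambda a, b: -(h[a] + h[b]) / 2.0  # noqa: E731
    return {
        "CCM": _table_from_rule("CCM", lambda a, b: -q[a] * q[b]),
        "HCM": _table_from_rule("HCM", lambda a, b: -abs(h[a] - h[b])),
        "SCM": _table_from_rule("SCM", lambda a, b: -abs(v[a] - v[b])),
        "CP": _table_from_rule("CP", cp),
        "CPE": _table_from_rule("CPE", lambda a, b: cp(a, b) / 2.0 + q[a] * q[b]),
        "CPB": _table_from_rule(
            "CPB", lambda a, b: 1.5 * cp(a, b) - 0.2 * abs(h[a] - h[b])
        ),
    }


def read_property_table(path: str | Path, name: str | None = None) -> PropertyTable:
    """Read a 20x20 TSV with residue-letter header row and column."""
    path = Path(path)
    lines = [ln.split("\t") for ln in path.read_text().splitlines() if ln]
    header = [c.strip() for c in lines[0][1:]]
    if sorted(header) != sorted(AMINO_ACIDS):
        raise ValueError(f"{path}: header must list the 20 standard residues")
    vals = np.zeros((20, 20))
    for row in lines[1:]:
        a = row[0].strip()
        for col_letter, cell in zip(header, row[1:]):
            vals[AMINO_ACIDS.index(a), AMINO_ACIDS.index(col_letter)] = float(cell)
    return PropertyTable(name=name or path.stem, values=vals)


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, a in enumerate(AMINO_ACIDS):
            fh.write(a + "\t" + "\t".join(format(x, ".6g") for x in table.values[i]) + "\n")


@dataclass(frozen=True)
class SspRankTable:
    """Rank values for the 6 unordered secondary-structure class pairs.

    Ranks are distinct integers 1..6; the scaled value used in feature
    matrices is ``rank / 6``.
    """

    ranks: Mapping[frozenset, int]

    def __post_init__(self) -> None:
        if set(self.ranks) != set(SSP_PAIRS):
            raise ValueError("rank table must cover exactly the 6 class pairs")
        if sorted(self.ranks.values()) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("ranks must be the distinct integers 1..6")

    def scaled(self, class_a: str, class_b: str) -> float:
        key = frozenset({class_a, class_b})
        if key not in self.ranks:
            raise KeyError(f"unknown secondary-structure class pair {class_a}-{class_b}")
        return self.ranks[key] / 6.0


#: Documented stand-in ordering for feature-only runs (helix-helix pairs
#: treated as most frequent at interfaces, sheet-sheet as least).
DEFAULT_SSP_RANKS = SspRankTable(
    ranks={
        frozenset({"H"}): 6,
        frozenset({"H", "C"}): 5,
        frozenset({"C"}): 4,
        frozenset({"H", "E"}): 3,
        frozenset({"E", "C"}): 2,
        frozenset({"E"}): 1,
    }
)


def ranks_from_occurrence(
    sspA: Sequence[str], sspB: Sequence[str], positive_pairs: Sequence[tuple[int, int]]
) -> SspRankTable:
    """Learn the rank table from class-pair occurrence among positive pairs.

    The most frequent unordered class pair among the labeled positive
    residue pairs receives rank 6, the least frequent rank 1. Ties and
    unobserved pairs are broken by the canonical pair order so the result
    is deterministic.
    """
    counts: Counter = Counter()
    for i, j in positive_pairs:
        counts[frozenset({sspA[i - 1], sspB[j - 1]})] += 1
    order = sorted(
        SSP_PAIRS, key=lambda p: (counts.get(p, 0), -SSP_PAIRS.index(p))
    )
    return SspRankTable(ranks={pair: rank for rank, pair in enumerate(order, start=1)})


@dataclass(frozen=True)
class ResidueAnnotations:
    """Per-residue relative solvent accessibility and secondary structure."""

    rsa: np.ndarray
    ssp: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.rsa, dtype=float)
        if r.ndim != 1 or len(r) != len(self.ssp):
            raise ValueError("rsa and ssp must be 1-D and equal length")
        if r.size and (r.min() < 0 or r.max() > 1):
            raise ValueError("rsa values must lie in [0, 1]")
        bad = set(self.ssp) - set(SSP_CLASSES)
        if bad:
            raise ValueError(f"unknown secondary-structure class(es) {sorted(bad)}")
        object.__setattr__(self, "rsa", r)
        object.__setattr__(self, "ssp", tuple(self.ssp))

    def __len__(self) -> int:
        return len(self.ssp)


def read_annotations(path: str | Path) -> ResidueAnnotations:
    """Read a TSV with columns index (1-based), aa, rsa, ssp (H/E/C)."""
    rsa, ssp = [], []
    expected = 1
    for ln in Path(path).read_text().strip().splitlines():
        if ln.startswith("index") or not ln.strip():
            continue
        idx, _aa, r, s = ln.split("\t")
        if int(idx) != expected:
            raise ValueError(f"{path}: expected residue index {expected}, got {idx}")
        expected += 1
        rsa.append(float(r))
        ssp.append(s.strip())
    return ResidueAnnotations(rsa=np.array(rsa), ssp=tuple(ssp))


def write_annotations(
    ann: ResidueAnnotations, seq: str, path: str | Path
) -> None:
    if len(seq) != len(ann):
        raise ValueError("sequence length does not match annotations")
    with open(path, "w") as fh:
        fh.write("index\taa\trsa\tssp\n")
        for i, (aa, r, s) in enumerate(zip(seq, ann.rsa, ann.ssp), start=1):
            fh.write(f"{i}\t{aa}\t{r:.6g}\t{s}\n")


@dataclass(frozen=True)
class FeatureStack:
    """Named set of equally shaped M x N feature matrices."""

    matrices: dict[str, np.ndarray]
    feature_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.matrices) != set(self.feature_order):
            raise ValueError("matrices and feature_order disagree")
        shapes = {m.shape for m in self.matrices.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent matrix shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.matrices.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrices[name]

    def __contains__(self, name: str) -> bool:
        return name in self.matrices

    def as_table(self) -> np.ndarray:
        """Row-major flattening to an (M*N, n_features) design matrix."""
        return np.column_stack(
            [self.matrices[f].ravel() for f in self.feature_order]
        )


def pairwise_from_table(seqA: str, seqB: str, table: PropertyTable) -> np.ndarray:
    """out[i, j] = table[seqA[i]][seqB[j]] for gap-free standard sequences."""
    idx = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    for label, seq in (("A", seqA), ("B", seqB)):
        for pos, aa in enumerate(seq, start=1):
            if aa not in idx:
                raise KeyError(
                    f"residue {aa!r} at position {pos} of protein {label} "
                    f"missing from table {table.name!r}"
                )
    ia = np.array([idx[a] for a in seqA])
    ib = np.array([idx[b] for b in seqB])
    return table.values[np.ix_(ia, ib)]


def rsa_pair(rsaA: np.ndarray, rsaB: np.ndarray) -> np.ndarray:
    """Outer product of per-residue accessibilities: out[i,j] = a[i] * b[j]."""
    a = np.asarray(rsaA, dtype=float)
    b = np.asarray(rsaB, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("RSA values must be non-negative")
    return np.outer(a, b)


def ssp_pair(
    sspA: Sequence[str], sspB: Sequence[str], ranks: SspRankTable = DEFAULT_SSP_RANKS
) -> np.ndarray:
    """out[i, j] = scaled rank of the unordered class pair {sspA[i], sspB[j]}."""
    lut = np.zeros((len(SSP_CLASSES), len(SSP_CLASSES)))
    for x, ca in enumerate(SSP_CLASSES):
        for y, cb in enumerate(SSP_CLASSES):
            lut[x, y] = ranks.scaled(ca, cb)
    cls_idx = {c: k for k, c in enumerate(SSP_CLASSES)}
    try:
        ia = np.array([cls_idx[c] for c in sspA])
        ib = np.array([cls_idx[c] for c in sspB])
    except KeyError as exc:
        raise KeyError(f"unknown secondary-structure class {exc}") from exc
    return lut[np.ix_(ia, ib)]


def minmax_scale(matrix: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant matrix maps to all zeros."""
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("cannot scale an empty matrix")
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def build_base_stack(
    seqA: str,
    seqB: str,
    cmi_values: np.ndarray,
    annA: ResidueAnnotations,
    annB: ResidueAnnotations,
    tables: Mapping[str, PropertyTable] | None = None,
    ranks: SspRankTable = DEFAULT_SSP_RANKS,
    scale: bool = True,
) -> FeatureStack:
    """Assemble the 9 base matrices in canonical order, each scaled to [0,1].

    Raises a ``ValueError`` naming the offending input on any dimension
    mismatch against ``(M, N) = (len(seqA), len(seqB))``.
    """
    tables = tables or default_tables()
    m, n = len(seqA), len(seqB)
    cmi_values = np.asarray(cmi_values, dtype=float)
    checks = {
        "cmi": cmi_values.shape == (m, n),
        "annotations A": len(annA) == m,
        "annotations B": len(annB) == n,
    }
    for what, ok in checks.items():
        if not ok:
            raise ValueError(f"dimension mismatch: {what} does not fit ({m}, {n})")

    mats = {
        "CMI": cmi_values,
        "CCM": pairwise_from_table(seqA, seqB, tables["CCM"]),
        "HCM": pairwise_from_table(seqA, seqB, tables["HCM"]),
        "SCM": pairwise_from_table(seqA, seqB, tables["SCM"]),
        "RSA": rsa_pair(annA.rsa, annB.rsa),
        "SSP": ssp_pair(annA.ssp, annB.ssp, ranks),
        "CP": pairwise_from_table(seqA, seqB, tables["CP"]),
        "CPE": pairwise_from_table(seqA, seqB, tables["CPE"]),
        "CPB": pairwise_from_table(seqA, seqB, tables["CPB"]),
    }
    if scale:
        mats = {k: minmax_scale(v) for k, v in mats.items()}
    return FeatureStack(matrices=mats, feature_order=BASE_FEATURES)


def read_stack_tsv(path: str | Path) -> FeatureStack:
    """Read a long-format stack TSV written by :func:`write_stack_tsv`."""
    cells: dict[str, dict[tuple[int, int], float]] = {}
    order: list[str] = []
    m = n = 0
    for ln in Path(path).read_text().strip().splitlines():
        if ln.startswith("i\t"):
            continue
        i, j, name, value = ln.split("\t")
        i, j = int(i), int(j)
        m, n = max(m, i), max(n, j)
        if name not in cells:
            cells[name] = {}
            order.append(name)
        cells[name][(i, j)] = float(value)
    mats = {}
    for name, entries in cells.items():
        mat = np.zeros((m, n))
        for (i, j), v in entries.items():
            mat[i - 1, j - 1] = v
        mats[name] = mat
    return FeatureStack(matrices=mats, feature_order=tuple(order))


def write_stack_tsv(stack: FeatureStack, path: str | Path) -> None:
    """Long-format TSV: i, j, feature, value (1-based indices)."""
    m, n = stack.shape
    with open(path, "w") as fh:
        fh.write("i\tj\tfeature\tvalue\n")
        for name in stack.feature_order:
            mat = stack[name]
            for i in range(m):
                for j in range(n):
                    fh.write(f"{i + 1}\t{j + 1}\t{name}\t{mat[i, j]:.10g}\n")
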