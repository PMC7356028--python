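"""Network-analysis post-filter for classifier predictions.

Four pruning stages, each of which only removes predicted pairs:

1. intra-protein contact networks from intra-mode co-evolution (top
   fraction of candidates at sequence separation >= 5);
2. a residual bipartite network after deleting buried residues (RSA = 0)
   and residues engaged in strong intra-protein contacts;
3. unitary window-sum scoring that keeps only clustered predictions
   (score cutoff 2 for a 3x3 window, 6 for 5x5, strict inequality);
4. a stretch filter requiring surviving pairs to sit in runs of >= 3
   consecutive residues on both chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate

from .coevolution import CoevolutionMatrix

#: Window-sum cutoff per kernel size (pairs must score strictly above).
SCORE_CUTOFFS = {3: 2, 5: 6}


def n_unordered_pairs(length: int) -> int:
    """Unordered residue pairs of one chain before separation filtering."""
    return length * (length - 1) // 2


def intra_candidates(length: int, min_sep: int = 5) -> list[tuple[int, int]]:
    """Unordered 1-based residue pairs with sequence separation >= min_sep."""
    return [
        (i, ip)
        for i, ip in combinations(range(1, length + 1), 2)
        if ip - i >= min_sep
    ]


@dataclass(frozen=True)
class IntraNetwork:
    """Top co-evolving intra-protein pairs and the residues they touch."""

    edges: frozenset[tuple[int, int]]  # unordered, 1-based, i < i'
    nodes: frozenset[int]
    n_candidates_unfiltered: int  # all unordered pairs, before separation filter
    n_candidates: int  # pairs surviving the separation filter


def intra_network(
    cmi: CoevolutionMatrix,
    min_sep: int = 5,
    top_frac: float = 0.05,
    mode: str = "count",
) -> IntraNetwork:
    """Extract the strongest intra-protein co-evolution contacts.

    Candidates are unordered residue pairs at sequence separation
    >= ``min_sep``. ``mode="count"`` keeps the top ``top_frac`` fraction of
    candidates by score (descending, deterministic tie-break);
    ``mode="value"`` keeps candidates whose score exceeds 95% of the
    candidate score range.
    """
    if cmi.mode != "intra":
        raise ValueError("intra_network requires an intra-mode co-evolution matrix")
    length = cmi.shape[0]
    n_unfiltered = n_unordered_pairs(length)
    candidates = intra_candidates(length, min_sep)
    if not candidates:
        warnings.warn(
            f"chain of length {length} has no pairs at separation >= {min_sep}",
            stacklevel=2,
        )
        return IntraNetwork(frozenset(), frozenset(), n_unfiltered, 0)

    scored = [(cmi.values[i - 1, ip - 1], i, ip) for i, ip in candidates]
    if mode == "count":
        k = max(1, math.ceil(top_frac * len(candidates)))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        kept = scored[:k]
    elif mode == "value":
        values = [s for s, _, _ in scored]
        lo, hi = min(values), max(values)
        threshold = lo + (1.0 - top_frac) * (hi - lo)
        kept = [t for t in scored if t[0] > threshold] if hi > lo else []
    else:
        raise ValueError(f"unknown top-fraction mode {mode!r}")
    edges = frozenset((i, ip) for _, i, ip in kept)
    nodes = frozenset(i for e in edges for i in e)
    return IntraNetwork(edges, nodes, n_unfiltered, len(candidates))


def residual_network(
    pred: np.ndarray,
    rsaA: np.ndarray,
    rsaB: np.ndarray,
    intraA_nodes: frozenset[int] | set[int] = frozenset(),
    intraB_nodes: frozenset[int] | set[int] = frozenset(),
) -> np.ndarray:
    """Remove buried residues and intra-network residues from predictions.

    Row i (1-based) is zeroed when ``rsaA[i-1] == 0`` or i is in
    ``intraA_nodes``; columns likewise for protein B. Surviving 1-cells
    are always a subset of the input's.
    """
    out = np.asarray(pred).astype(int).copy()
    m, n = out.shape
    rsaA = np.asarray(rsaA, dtype=float)
    rsaB = np.asarray(rsaB, dtype=float)
    if len(rsaA) != m or len(rsaB) != n:
        raise ValueError("RSA vector lengths do not match the prediction grid")
    drop_rows = (rsaA == 0) | np.isin(np.arange(1, m + 1), list(intraA_nodes))
    drop_cols = (rsaB == 0) | np.isin(np.arange(1, n + 1), list(intraB_nodes))
    out[drop_rows, :] = 0
    out[:, drop_cols] = 0
    return out


@dataclass(frozen=True)
class ScoredPairs:
    """Predicted pairs surviving window-sum scoring."""

    entries: tuple[tuple[int, int, int, float], ...]  # (i, j, score, probability)
    kernel_size: int
    cutoff: int

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset((i, j) for i, j, _, _ in self.entries)


def window_sums(pred: np.ndarray, kernel_size: int) -> np.ndarray:
    """Zero-padded window sum of a binary matrix (unitary kernel)."""
    unitary = np.ones((kernel_size, kernel_size))
    return correlate(
        np.asarray(pred, dtype=float), unitary, mode="constant", cval=0.0
    ).round().astype(int)


def convolution_score(
    pred: np.ndarray,
    kernel_size: int = 5,
    prob: np.ndarray | None = None,
    cutoff: int | None = None,
) -> ScoredPairs:
    """Keep predicted pairs whose neighborhood is densely predicted.

    Each 1-cell is scored by the number of 1s in the ``kernel_size`` x
    ``kernel_size`` window centered on it (zero padding at borders) and
    retained iff the score strictly exceeds the cutoff (2 for 3x3, 6 for
    5x5 unless overridden).
    """
    if kernel_size not in SCORE_CUTOFFS:
        raise ValueError(
            f"kernel size must be one of {sorted(SCORE_CUTOFFS)}, got {kernel_size}"
        )
    cutoff = SCORE_CUTOFFS[kernel_size] if cutoff is None else cutoff
    pred = np.asarray(pred).astype(int)
    scores = window_sums(pred, kernel_size)
    entries = []
    for i, j in zip(*np.nonzero(pred)):
        if scores[i, j] > cutoff:
            p = float(prob[i, j]) if prob is not None else float("nan")
            entries.append((int(i) + 1, int(j) + 1, int(scores[i, j]), p))
    entries.sort()
    return ScoredPairs(entries=tuple(entries), kernel_size=kernel_size, cutoff=cutoff)


def _qualifying_positions(positions: set[int], run_length: int) -> set[int]:
    """Members of maximal consecutive runs of length >= run_length."""
    good: set[int] = set()
    for p in sorted(positions):
        if p - 1 in positions:
            continue  # not a run start
        q = p
        while q + 1 in positions:
            q += 1
        if q - p + 1 >= run_length:
            good.update(range(p, q + 1))
    return good


def stretch_filter(pairs: ScoredPairs, run_length: int = 3) -> ScoredPairs:
    """Keep pairs lying in >= run_length consecutive residues on both chains.

    A pair (i, j) survives iff i belongs to a run of >= ``run_length``
    consecutive protein-A residues covered by the retained pairs, and j to
    such a run on protein B.
    """
    a_positions = {i for i, _, _, _ in pairs.entries}
    b_positions = {j for _, j, _, _ in pairs.entries}
    good_a = _qualifying_positions(a_positions, run_length)
    good_b = _qualifying_positions(b_positions, run_length)
    kept = tuple(
        e for e in pairs.entries if e[0] in good_a and e[1] in good_b
    )
    return ScoredPairs(entries=kept, kernel_size=pairs.kernel_size, cutoff=pairs.cutoff)


def write_scored_pairs(
    pairs: ScoredPairs,
    path: str | Path,
    seqA: str | None = None,
    seqB: str | None = None,
    stretch_pairs: frozenset[tuple[int, int]] | None = None,
) -> None:
    """Final output TSV: i, j, residues, probability, score, passed_stretch."""
    with open(path, "w") as fh:
        fh.write("i\tj\taa_i\taa_j\tprobability\tscore\tpassed_stretch\n")
        for i, j, score, p in pairs.entries:
            aa_i = seqA[i - 1] if seqA else "."
            aa_j = seqB[j - 1] if seqB else "."
            passed = (
                int((i, j) in stretch_pairs) if stretch_pairs is not None else "."
            )
            fh.write(f"{i}\t{j}\t{aa_i}\t{aa_j}\t{p:.4g}\t{score}\t{passed}\n")


def write_edge_list(edges, path: str | Path) -> None:
    """Plain two-column edge list."""
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")
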