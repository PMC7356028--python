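"""Perturbation-based co-evolution scores between alignment columns.

For every column pair (i of protein A, j of protein B) the concatenated
alignment is repeatedly subset on the 20 possible conditioning residues at
column i; the frequency shift each condition induces at column j is scored
with a conditional log-likelihood ratio, and the 20 condition scores are
combined into one matrix entry.

Two combination modes are provided:

``weighted`` (default)
    Each condition is weighted by the (smoothed) frequency of its
    conditioning residue. The sum then equals, exactly, the mutual
    information of the smoothed 21x21 joint frequency table of the two
    columns, which gives the statistic an independent closed-form oracle
    and guarantees non-negativity.

``unweighted``
    Each observed condition contributes with weight 1 (a plain sum over
    conditions).

Rows whose conditioning column holds a gap are excluded from the base set
of a column pair: gaps are never conditions, but they remain a legitimate
21st outcome symbol at the response column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .msa import AMINO_ACIDS, N_SYMBOLS, EncodedAlignment

#: Default per-cell pseudocount added during frequency smoothing.
DEFAULT_PSEUDOCOUNT = 1.0 / N_SYMBOLS


@dataclass(frozen=True)
class CoevolutionMatrix:
    """Co-evolution scores, rows = protein-A columns, cols = protein-B columns."""

    values: np.ndarray
    mode: str  # "inter" | "intra"
    pseudocount: float
    weighting: str = "weighted"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("co-evolution matrix must be 2-D")
        if self.mode not in ("inter", "intra"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "intra" and v.shape[0] != v.shape[1]:
            raise ValueError("intra-mode matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def candidate_conditions(enc: EncodedAlignment, col: int) -> list[int]:
    """The conditioning subsets evaluated for one protein-A column.

    One condition per standard residue type; the gap symbol is never a
    condition. Conditions whose subset is empty are still candidates (they
    contribute 0 to the score).
    """
    if not 0 <= col < enc.width:
        raise IndexError(f"column {col} out of range")
    return [code + 1 for code in range(len(AMINO_ACIDS))]


def column_frequencies(
    enc: EncodedAlignment,
    col: int,
    subset: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Smoothed symbol frequencies of one column over the 21-symbol alphabet.

    ``pseudocount`` is added to each of the 21 symbol counts before
    renormalizing. ``subset`` restricts to a boolean mask or index array of
    rows; an empty subset is an error (callers skip empty conditions).
    """
    column = enc.matrix[:, col]
    if subset is not None:
        column = column[np.asarray(subset)]
    if column.size == 0:
        raise ValueError("empty row subset")
    counts = np.bincount(column, minlength=N_SYMBOLS).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def _mi_from_counts(
    counts: np.ndarray,
    pseudocount: float,
    weighting: str,
    log_base: float | None,
) -> np.ndarray:
    """Score a stack of 21x21xP joint count tables (P response columns).

    Smoothing adds ``pseudocount`` to every cell of rows whose conditioning
    symbol occurs at least once; unobserved conditions receive no smoothing
    mass so that they contribute exactly 0.
    """
    n_obs_per_a = counts.sum(axis=1)  # (21, P); constant across P
    observed = n_obs_per_a[:, 0] > 0  # conditioning symbols present
    k = int(observed.sum())
    n = counts[:, :, 0].sum()
    if n == 0 or k == 0:
        return np.zeros(counts.shape[2])

    smoothed = counts.astype(float)
    smoothed[observed] += pseudocount
    z = n + N_SYMBOLS * k * pseudocount
    q = smoothed / z  # joint (a, b, j)
    qa = q.sum(axis=1, keepdims=True)  # (21, 1, P)
    qb = q.sum(axis=0, keepdims=True)  # (1, 21, P)

    positive = q > 0  # zero cells contribute 0 (only arise with pseudocount 0)
    log_ratio = np.zeros_like(q)
    ratio = np.ones_like(q)
    np.divide(q, np.broadcast_to(qa * qb, q.shape), out=ratio, where=positive)
    np.log(ratio, out=log_ratio, where=positive)
    if weighting == "weighted":
        terms = q * log_ratio
    elif weighting == "unweighted":
        cond = np.zeros_like(q)  # p(b | a)
        np.divide(q, np.broadcast_to(qa, q.shape), out=cond, where=positive)
        terms = cond * log_ratio
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    scores = terms.sum(axis=(0, 1))
    if log_base is not None:
        scores = scores / np.log(log_base)
    return scores


def cmi_matrix(
    enc: EncodedAlignment,
    boundary: int,
    *,
    weighting: str = "weighted",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float | None = None,
    mode: str = "inter",
) -> CoevolutionMatrix:
    """Co-evolution matrix between protein-A columns and protein-B columns.

    Parameters
    ----------
    enc
        Encoded concatenated alignment.
    boundary
        Index of the first protein-B column; columns ``< boundary`` belong
        to protein A.
    weighting
        ``"weighted"`` (condition weight = smoothed conditioning-residue
        frequency; equals joint-table mutual information) or
        ``"unweighted"`` (each observed condition weighted 1).
    pseudocount
        Per-cell smoothing count (0 disables smoothing).
    log_base
        Logarithm base for the scores; natural log when ``None``.

    Returns
    -------
    CoevolutionMatrix
        Shape ``(boundary, width - boundary)``. All-gap columns yield zero
        rows/columns with a warning.
    """
    if enc.n_sequences < 2:
        raise ValueError("co-evolution needs at least 2 sequences")
    if not 0 < boundary < enc.width:
        raise ValueError(f"boundary {boundary} must split the columns")
    mat = enc.matrix
    n_seq, width = mat.shape
    len_a, len_b = boundary, width - boundary
    out = np.zeros((len_a, len_b))

    b_block = np.ascontiguousarray(mat[:, boundary:])
    all_gap_b = (b_block == 0).all(axis=0)
    if all_gap_b.any():
        warnings.warn(
            f"{int(all_gap_b.sum())} all-gap protein-B column(s); scores set to 0",
            stacklevel=2,
        )

    col_offsets = np.arange(len_b) * N_SYMBOLS
    for i in range(len_a):
        cond_col = mat[:, i]
        base = cond_col != 0
        if not base.any():
            warnings.warn(
                f"all-gap protein-A column {i}; scores set to 0", stacklevel=2
            )
            continue
        a_codes = cond_col[base].astype(np.int64)
        sub = b_block[base]
        # joint counts (a, b, j) via one flat bincount
        flat = (
            a_codes[:, None] * (N_SYMBOLS * len_b)
            + sub.astype(np.int64) * len_b
            + np.arange(len_b)[None, :]
        )
        counts = np.bincount(
            flat.ravel(), minlength=N_SYMBOLS * N_SYMBOLS * len_b
        ).reshape(N_SYMBOLS, N_SYMBOLS, len_b)
        out[i] = _mi_from_counts(counts, pseudocount, weighting, log_base)

    out[:, all_gap_b] = 0.0
    return CoevolutionMatrix(
        values=out, mode=mode, pseudocount=pseudocount, weighting=weighting
    )


def intra_cmi(
    enc: EncodedAlignment,
    *,
    weighting: str = "weighted",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float | None = None,
) -> CoevolutionMatrix:
    """Co-evolution of a protein with itself (square matrix, mode "intra").

    Equivalent to :func:`cmi_matrix` on the alignment concatenated with
    itself. Diagonal entries are reported but are self-pairs, never
    contacts; downstream consumers must ignore them.
    """
    doubled = EncodedAlignment(np.hstack([enc.matrix, enc.matrix]))
    return cmi_matrix(
        doubled,
        boundary=enc.width,
        weighting=weighting,
        pseudocount=pseudocount,
        log_base=log_base,
        mode="intra",
    )


def write_matrix_tsv(cmi: CoevolutionMatrix, path) -> None:
    """Wide TSV: 1-based protein-A residue rows, protein-B residue columns."""
    m, n = cmi.shape
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(str(j + 1) for j in range(n)) + "\n")
        for i in range(m):
            fh.write(
                str(i + 1)
                + "\t"
                + "\t".join(format(v, ".10g") for v in cmi.values[i])
                + "\n"
            )


def write_long_tsv(cmi: CoevolutionMatrix, path) -> None:
    """Long TSV with columns i, j, score (1-based indices)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        m, n = cmi.shape
        for i in range(m):
            for j in range(n):
                fh.write(f"{i + 1}\t{j + 1}\t{cmi.values[i, j]:.10g}\n")
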