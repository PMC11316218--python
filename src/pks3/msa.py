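"""Multiple sequence alignment: in-house progressive aligner and import.

The built-in aligner is a deliberately simple progressive scheme — k-mer
guide distances, a neighbor-joining guide tree, and profile-profile Gotoh
alignment with sum-of-pairs substitution scores — adequate for the
synthetic families the pipeline is tested on. For publication-grade runs
an externally computed alignment (e.g. MUSCLE) can be supplied through
:func:`import_alignment` instead; both routes yield the same
:class:`MultipleAlignment` object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices

from .errors import AlignmentError, DuplicateIdError, EmptyInputError
from .io import SequenceRecord

GAP = "-"


@dataclass
class MultipleAlignment:
    """An ordered set of equal-length gapped rows."""

    rows: list[tuple[str, str]]  # (id, gapped residues)

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyInputError("alignment has no rows")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment rows (lengths {sorted(lengths)})")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("duplicate ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def degapped(self, seq_id: str) -> str:
        for i, row in self.rows:
            if i == seq_id:
                return row.replace(GAP, "")
        raise KeyError(seq_id)

    @property
    def gap_free_column_count(self) -> int:
        return sum(
            1
            for c in range(self.length)
            if all(row[c] != GAP for _, row in self.rows)
        )

    def subsample_columns(self, columns: Sequence[int]) -> "MultipleAlignment":
        """New alignment from the given column indices (0-based, repeats allowed)."""
        out = []
        for seq_id, row in self.rows:
            out.append((seq_id, "".join(row[c] for c in columns)))
        return MultipleAlignment(rows=out)


def kmer_distance(a: SequenceRecord, b: SequenceRecord, k: int = 3) -> float:
    """Fractional k-mer distance: 1 - |shared k-mers| / min(|k-mers|).

    Distinct k-mer sets are compared; identical sequences give 0, sequences
    with disjoint k-mer sets give 1. Symmetric.
    """
    if len(a.residues) < k or len(b.residues) < k:
        raise AlignmentError(f"sequence shorter than k={k}")
    ka = {a.residues[i : i + k] for i in range(len(a.residues) - k + 1)}
    kb = {b.residues[i : i + k] for i in range(len(b.residues) - k + 1)}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def blosum_substitution(matrix_name: str = "BLOSUM62") -> Callable[[str, str], float]:
    """Residue-pair substitution score function backed by a named matrix."""
    mat = substitution_matrices.load(matrix_name)
    alphabet = mat.alphabet

    def sub(x: str, y: str) -> float:
        if x not in alphabet or y not in alphabet:
            return 0.0
        return float(mat[x, y])

    return sub


@dataclass(frozen=True)
class MsaScoring:
    """Profile-alignment scoring: substitution function plus affine gaps."""

    substitution: Callable[[str, str], float]
    gap_open: float = 11.0
    gap_extend: float = 1.0


def default_msa_scoring() -> MsaScoring:
    return MsaScoring(substitution=blosum_substitution())


def _pair_score_matrix(
    prof_a: list[str], prof_b: list[str], sub
) -> np.ndarray:
    """pair[i, j] = mean substitution score of column i of A vs column j of B,
    averaged over residue pairs with no gap on either side (0 if none)."""
    symbols = sorted({c for row in prof_a + prof_b for c in row} - {GAP})
    sym_index = {c: k for k, c in enumerate(symbols)}
    score = np.array([[sub(x, y) for y in symbols] for x in symbols])

    def counts(prof: list[str]) -> np.ndarray:
        length = len(prof[0])
        out = np.zeros((length, len(symbols)))
        for row in prof:
            for c, ch in enumerate(row):
                if ch != GAP:
                    out[c, sym_index[ch]] += 1
        return out

    ca, cb = counts(prof_a), counts(prof_b)
    num = ca @ score @ cb.T
    denom = np.outer(ca.sum(axis=1), cb.sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pair = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    return pair


def _profile_align(
    prof_a: list[str], prof_b: list[str], scoring: MsaScoring
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (Gotoh, affine gaps).

    Deterministic: ties are broken in the fixed state order
    match > gap-in-B (consume A) > gap-in-A (consume B).
    """
    n, m = len(prof_a[0]), len(prof_b[0])
    go, ge = scoring.gap_open, scoring.gap_extend
    pair = _pair_score_matrix(prof_a, prof_b, scoring.substitution)
    neg = -1e30

    mm = np.full((n + 1, m + 1), neg)   # state 0: columns matched
    ix = np.full((n + 1, m + 1), neg)   # state 1: gap in B, consuming A
    iy = np.full((n + 1, m + 1), neg)   # state 2: gap in A, consuming B
    mm[0, 0] = 0.0
    jr = np.arange(m + 1)
    iy[0, 1:] = -go - (jr[1:] - 1) * ge
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.full((n + 1, m + 1), 2, dtype=np.int8)
    ptr_y[0, 1] = 0

    for i in range(1, n + 1):
        pm, px, py = mm[i - 1], ix[i - 1], iy[i - 1]
        diag = np.stack([pm[:-1], px[:-1], py[:-1]])
        ptr_m[i, 1:] = diag.argmax(axis=0)
        mm[i, 1:] = diag.max(axis=0) + pair[i - 1, :]
        up = np.stack([pm - go, px - ge, py - go])
        ptr_x[i, :] = up.argmax(axis=0)
        ix[i, :] = up.max(axis=0)
        # left-moving state: running-max recurrence along the row
        base = np.maximum(mm[i, :] - go, ix[i, :] - go)
        open_from_x = (ix[i, :] - go) > (mm[i, :] - go)
        t = base[:-1] + ge * jr[1:]
        c = np.maximum.accumulate(np.concatenate(([iy[i, 0]], t)))
        iy[i, :] = c - ge * jr
        opened = iy[i, 1:] <= base[:-1] + 1e-9
        ptr_y[i, 1:] = np.where(opened, np.where(open_from_x[:-1], 1, 0), 2)

    final = (mm[n, m], ix[n, m], iy[n, m])
    state = int(np.argmax(final))
    i, j = n, m
    ops: list[int] = []
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        ops.append(state)
        if state == 0:
            prev = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            prev = int(ptr_x[i, j])
            i -= 1
        else:
            prev = int(ptr_y[i, j])
            j -= 1
        state = prev
    ops.reverse()

    out_a = ["" for _ in prof_a]
    out_b = ["" for _ in prof_b]
    ia = ib = 0
    for op in ops:
        if op in (0, 1):
            for r, row in enumerate(prof_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(prof_a)):
                out_a[r] += GAP
        if op in (0, 2):
            for r, row in enumerate(prof_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(prof_b)):
                out_b[r] += GAP
    return out_a, out_b


def _merge_order(records: Sequence[SequenceRecord], k: int) -> list:
    """Postorder merge plan from a midpoint-rooted NJ guide tree.

    Returns a nested-tuple topology over record indices.
    """
    from .phylo import DistanceMatrix, nj_tree  # late import: phylo is downstream

    n = len(records)
    if n == 2:
        return (0, 1)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kmer_distance(records[i], records[j], k=k)
    dm = DistanceMatrix(ids=[r.id for r in records], matrix=mat)
    tree = nj_tree(dm)
    index = {r.id: i for i, r in enumerate(records)}

    def plan(node):
        if node.is_leaf():
            return index[node.taxon.label]
        parts = [plan(c) for c in node.child_nodes()]
        if node.taxon is not None:  # degenerate guide trees can label internals
            parts.append(index[node.taxon.label])
        merged = parts[0]
        for part in parts[1:]:
            merged = (merged, part)
        return merged

    return plan(tree.seed_node)


def progressive_align(
    records: Sequence[SequenceRecord],
    scoring: MsaScoring | None = None,
    k: int = 3,
) -> MultipleAlignment:
    """Progressive MSA over a k-mer/NJ guide tree.

    Deterministic for a fixed input order and scoring. Requires >= 2 records.
    """
    if len(records) < 2:
        raise AlignmentError("progressive alignment needs at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("duplicate sequence ids")
    scoring = scoring or default_msa_scoring()
    plan = _merge_order(records, k)

    def build(node) -> tuple[list[int], list[str]]:
        if isinstance(node, int):
            return [node], [records[node].residues]
        (la, pa), (lb, pb) = build(node[0]), build(node[1])
        aligned_a, aligned_b = _profile_align(pa, pb, scoring)
        return la + lb, aligned_a + aligned_b

    order, profile = build(plan)
    by_index = dict(zip(order, profile))
    rows = [(records[i].id, by_index[i]) for i in range(len(records))]
    return MultipleAlignment(rows=rows)


def import_alignment(path: str | Path) -> MultipleAlignment:
    """Read and validate an aligned-FASTA file (e.g. a MUSCLE alignment)."""
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentError(f"cannot read alignment {path}: {exc}") from exc
    rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    if not rows:
        raise EmptyInputError(f"no rows in alignment {path}")
    return MultipleAlignment(rows=rows)


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in msa.rows:
            fh.write(f">{seq_id}\n{row}\n")


def from_records(records: Sequence[SequenceRecord]) -> MultipleAlignment:
    """Treat already-aligned or equal-length records as an alignment."""
    return MultipleAlignment(rows=[(r.id, r.residues) for r in records])
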