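"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the alignment oracle
enumerates every gapped global alignment as a lattice path and scores it
directly; the rotation-grid oracle evaluates the superposition residual
under a large sample of rotations.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def alignment_paths(la: int, lb: int) -> tuple[tuple[str, ...], ...]:
    """All global alignment paths for sequence lengths (la, lb).

    A path is a tuple of moves: 'D' aligns a residue pair, 'U' puts a
    gap in the second sequence, 'L' in the first.
    """
    if la == 0 and lb == 0:
        return ((),)
    out = []
    if la > 0 and lb > 0:
        out += [("D",) + p for p in alignment_paths(la - 1, lb - 1)]
    if la > 0:
        out += [("U",) + p for p in alignment_paths(la - 1, lb)]
    if lb > 0:
        out += [("L",) + p for p in alignment_paths(la, lb - 1)]
    return tuple(out)


def gap_cost_of_path(path: tuple[str, ...], gap_open: float,
                     gap_extend: float) -> float:
    """Total affine gap penalty of a path (each maximal U- or L-run is one gap)."""
    cost, run = 0.0, None
    for mv in path:
        if mv == "D":
            run = None
        elif mv == run:
            cost += gap_extend
        else:
            cost += gap_open
            run = mv
    return cost


def brute_force_align_score(a: str, b: str, S: dict,
                            gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score by exhaustive path enumeration."""
    best = -np.inf
    for path in alignment_paths(len(a), len(b)):
        i = j = 0
        score = -gap_cost_of_path(path, gap_open, gap_extend)
        for mv in path:
            if mv == "D":
                score += S[(a[i], b[j])]
                i += 1
                j += 1
            elif mv == "U":
                i += 1
            else:
                j += 1
        best = max(best, score)
    return best


def brute_force_scores_all_pairs(alphabet: str, la: int, lb: int, S: dict,
                                 gap_open: float, gap_extend: float
                                 ) -> np.ndarray:
    """Optimal scores for every sequence pair of lengths (la, lb).

    Returns an array of shape (k**la, k**lb) indexed by base-k digit
    encoding of the sequences.  Vectorized over pairs so the full
    length-<=4 enumeration stays fast.
    """
    k = len(alphabet)
    Sm = np.array([[S[(x, y)] for y in alphabet] for x in alphabet])
    A = _all_seqs(k, la)    # (k**la, la) integer codes
    B = _all_seqs(k, lb)
    best = np.full((len(A), len(B)), -np.inf)
    for path in alignment_paths(la, lb):
        gap = gap_cost_of_path(path, gap_open, gap_extend)
        M = np.full((len(A), len(B)), -gap)
        i = j = 0
        for mv in path:
            if mv == "D":
                M = M + Sm[A[:, i][:, None], B[:, j][None, :]]
                i += 1
                j += 1
            elif mv == "U":
                i += 1
            else:
                j += 1
        np.maximum(best, M, out=best)
    return best


def _all_seqs(k: int, length: int) -> np.ndarray:
    if length == 0:
        return np.zeros((1, 0), dtype=int)
    grids = np.meshgrid(*([np.arange(k)] * length), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def decode_seq(code_row: np.ndarray, alphabet: str) -> str:
    return "".join(alphabet[c] for c in code_row)


def rotation_grid_min_rmsd(P: np.ndarray, Q: np.ndarray,
                           rotations: np.ndarray) -> float:
    """Minimum r.m.s.d. of R·P + t onto Q over a fixed rotation sample.

    For each rotation the optimal translation aligns the centroids, so the
    residual is computed on centered clouds directly.
    """
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    moved = np.einsum("rij,nj->rni", rotations, Pc)
    d2 = np.sum((moved - Qc[None]) ** 2, axis=(1, 2)) / len(P)
    return float(np.sqrt(d2.min()))
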