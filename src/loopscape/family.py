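"""Sequence-level loop comparison across glycoside-hydrolase homologs.

A pairwise Needleman–Wunsch aligner with affine gaps maps the reference
loop spans onto homolog sequences; loop length, charge, motif match and
column conservation are then tabulated.  The task is strictly pairwise
(reference → target), so no multiple-sequence-alignment engine is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .loop_analysis import CHARGE_1
from .structure_io import RegionSpec

__all__ = [
    "AlignmentResult", "LoopTableRow", "MotifResult",
    "global_align", "map_loops", "motif_scan", "conservation_profile",
    "loop_table", "read_fasta", "write_fasta", "blosum62",
]

ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

GAP = "-"
# traceback states
_M, _IX, _IY = 0, 1, 2  # match/mismatch, gap in b (consume a), gap in a (consume b)
NEG = -1e30


@lru_cache(maxsize=1)
def blosum62():
    """BLOSUM62 as a plain dict[(aa, aa)] -> float (from Biopython's tables)."""
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    alpha = m.alphabet
    return {(a, b): float(m[a, b]) for a in alpha for b in alpha}


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")


@dataclass
class LoopTableRow:
    species_tag: str
    loop: str
    start: int          # mapped author number on the target (0 if unmappable)
    end: int
    length: int         # non-gap target positions under the loop columns
    net_charge: int
    mappable: bool = True


@dataclass
class MotifResult:
    tag: str
    matched: bool
    position: int               # 0-based window offset of best match (-1 if none fits)
    mismatches: list[int]       # pattern positions (0-based) violated at best window
    reason: str = ""


def _check_seq(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise ConfigurationError(
            f"{label}: illegal sequence characters {sorted(bad)}")
    return seq


def global_align(a: str, b: str, matrix: dict | None = None,
                 gap_open: float = 10.0, gap_extend: float = 0.5
                 ) -> AlignmentResult:
    """Optimal global alignment with affine gap penalties (Gotoh).

    A gap of length k costs ``gap_open + (k-1) * gap_extend``.  Traceback
    ties are broken deterministically: diagonal over up (gap in b) over
    left (gap in a).
    """
    if not (gap_open >= gap_extend >= 0):
        raise ConfigurationError("need gap_open >= gap_extend >= 0")
    a, b = _check_seq(a, "sequence a"), _check_seq(b, "sequence b")
    S = matrix if matrix is not None else blosum62()
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        k = max(n, m)
        cost = 0.0 if k == 0 else -(gap_open + (k - 1) * gap_extend)
        return AlignmentResult(a or GAP * m, b or GAP * n, cost,
                               0.0 if k else 100.0)

    # three-state DP; M[i][j] = best ending in aligned pair (a_i, b_j)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b: a_i over '-'
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a: '-' over b_j
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Ixi, Ixi1 = Ix[i], Ix[i - 1]
        Iyi, Iyi1 = Iy[i], Iy[i - 1]
        for j in range(1, m + 1):
            s = S[(ai, b[j - 1])]
            Mi[j] = s + max(Mi1[j - 1], Ixi1[j - 1], Iyi1[j - 1])
            Ixi[j] = max(Mi1[j] - gap_open, Ixi1[j] - gap_extend,
                         Iyi1[j] - gap_open)
            Iyi[j] = max(Mi[j - 1] - gap_open, Iyi[j - 1] - gap_extend,
                         Ixi[j - 1] - gap_open)

    # traceback with the declared tie-break: diagonal > up > left
    i, j = n, m
    finals = (M[n][m], Ix[n][m], Iy[n][m])
    score = max(finals)
    state = finals.index(score)  # index order == preference order M, Ix, Iy
    out_a, out_b = [], []
    while i > 0 or j > 0:
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = (M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            target = M[i][j] - S[(a[i - 1], b[j - 1])]
            state = _pick(prev, target)
            i, j = i - 1, j - 1
        elif state == _IX:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            prev = (M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend,
                    Iy[i - 1][j] - gap_open)
            state = _pick(prev, Ix[i][j])
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            prev = (M[i][j - 1] - gap_open, Ix[i][j - 1] - gap_open,
                    Iy[i][j - 1] - gap_extend)
            # preference among predecessors of Iy is still M > Ix > Iy,
            # but prev tuple here is ordered (M, Ix(via open), Iy(extend));
            # map index 1->Ix, 2->Iy is NOT the tuple order -- reorder:
            prev = (prev[0], prev[1], prev[2])
            state = _pick_iy(prev, Iy[i][j])
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = _IY
        elif j == 0:
            state = _IX
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    ident = sum(1 for x, y in zip(aligned_a, aligned_b)
                if x == y and x != GAP)
    cols = sum(1 for x, y in zip(aligned_a, aligned_b)
               if not (x == GAP and y == GAP))
    return AlignmentResult(aligned_a, aligned_b, float(score),
                           100.0 * ident / cols if cols else 100.0)


def _pick(prev: tuple, target: float, tol: float = 1e-9) -> int:
    for k in (_M, _IX, _IY):
        if abs(prev[k] - target) <= tol:
            return k
    return int(np.argmax(prev))


def _pick_iy(prev: tuple, target: float, tol: float = 1e-9) -> int:
    for k in (_M, _IX, _IY):
        if abs(prev[k] - target) <= tol:
            return k
    return int(np.argmax(prev))


def map_loops(reference_seq: str, reference_loops: list[RegionSpec],
              target_seq: str, aln: AlignmentResult | None = None,
              ref_start: int = 1, target_start: int = 1,
              species_tag: str = "target", **align_kwargs) -> list[LoopTableRow]:
    """Project reference loop spans through an alignment onto a target.

    Each loop's aligned column interval is mapped onto the target sequence;
    the target loop length counts the non-gap target positions in that
    interval.  A loop falling entirely into a target gap gets length 0 and
    is flagged unmappable.  ``ref_start``/``target_start`` give the author
    number of each sequence's first residue.
    """
    reference_seq = _check_seq(reference_seq, "reference")
    target_seq = _check_seq(target_seq, "target")
    if aln is None:
        aln = global_align(reference_seq, target_seq, **align_kwargs)
    if aln.aligned_a.replace(GAP, "") != reference_seq:
        raise ConfigurationError("alignment does not match the reference sequence")
    if aln.aligned_b.replace(GAP, "") != target_seq:
        raise ConfigurationError("alignment does not match the target sequence")

    # column index of each reference position (0-based)
    col_of_ref: list[int] = []
    for col, ch in enumerate(aln.aligned_a):
        if ch != GAP:
            col_of_ref.append(col)
    # target author number at each column (None on gaps)
    tnum_at_col: list[int | None] = []
    t = target_start - 1
    for ch in aln.aligned_b:
        if ch == GAP:
            tnum_at_col.append(None)
        else:
            t += 1
            tnum_at_col.append(t)

    rows = []
    for rg in reference_loops:
        i0, i1 = rg.start - ref_start, rg.end - ref_start
        if i0 < 0 or i1 >= len(reference_seq):
            raise ConfigurationError(
                f"loop {rg.name} ({rg.start}-{rg.end}) outside the reference "
                f"numbering {ref_start}-{ref_start + len(reference_seq) - 1}")
        cols = range(col_of_ref[i0], col_of_ref[i1] + 1)
        tnums = [tnum_at_col[c] for c in cols if tnum_at_col[c] is not None]
        sub = "".join(aln.aligned_b[c] for c in cols
                      if aln.aligned_b[c] != GAP)
        if not tnums:
            rows.append(LoopTableRow(species_tag, rg.name, 0, 0, 0, 0,
                                     mappable=False))
            continue
        charge = sum(CHARGE_1.get(c, 0) for c in sub)
        rows.append(LoopTableRow(species_tag, rg.name, tnums[0], tnums[-1],
                                 len(tnums), charge))
    return rows


def loop_table(rows: list[LoopTableRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def motif_scan(seqs: dict[str, str] | list[tuple[str, str]],
               pattern: str) -> list[MotifResult]:
    """Match a positional pattern (fixed letters + 'x' wildcards) in each sequence.

    The pattern is slid over the sequence; a sequence matches if some window
    satisfies every fixed position.  For non-matching sequences the window
    with the fewest violations (leftmost on ties) is reported together with
    the violated pattern positions.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    pat = pattern.strip()
    fixed = [(k, c.upper()) for k, c in enumerate(pat) if c.lower() != "x"]
    if not fixed:
        raise ConfigurationError("pattern has no fixed positions")
    out = []
    for tag, seq in items:
        seq = _check_seq(seq, tag)
        if len(pat) > len(seq):
            out.append(MotifResult(tag, False, -1, [],
                                   reason="pattern longer than sequence"))
            continue
        best_mis, best_off = None, -1
        for off in range(len(seq) - len(pat) + 1):
            mis = [k for k, c in fixed if seq[off + k] != c]
            if best_mis is None or len(mis) < len(best_mis):
                best_mis, best_off = mis, off
            if not mis:
                break
        out.append(MotifResult(tag, not best_mis, best_off, best_mis or []))
    return out


def n_fixed_positions(pattern: str) -> int:
    """Number of fixed (conserved) positions in a motif pattern."""
    return sum(1 for c in pattern.strip() if c.lower() != "x")


def conservation_profile(aligned_seqs: list[str]) -> np.ndarray:
    """Per-column fraction of the most common non-gap residue."""
    if not aligned_seqs:
        raise ConfigurationError("empty sequence set")
    lengths = {len(s) for s in aligned_seqs}
    if len(lengths) != 1:
        raise ConfigurationError("aligned sequences must share one length")
    n = len(aligned_seqs)
    L = lengths.pop()
    out = np.zeros(L)
    for j in range(L):
        counts: dict[str, int] = {}
        for s in aligned_seqs:
            c = s[j].upper()
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        out[j] = max(counts.values()) / n if counts else 0.0
    return out


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    recs = [SeqRecord(Seq(s), id=tag, description="") for tag, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")
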