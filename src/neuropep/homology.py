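"""Local alignment homology screening.

A desk-scale surrogate for a translated BLAST screen: query peptides or
precursors are aligned against six-frame-translated ORF proteins with full
Smith-Waterman dynamic programming (Gotoh affine-gap recurrences, BLOSUM62,
gap open 11 / extend 1 by default; a gap of length k costs open + k*extend).
No heuristic seeding and no e-value statistics — screening is by raw score
with a permissive default threshold, mirroring a recall-oriented search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Align import substitution_matrices

NEG_INF = float("-inf")

_blosum62 = None


def blosum62():
    global _blosum62
    if _blosum62 is None:
        _blosum62 = substitution_matrices.load("BLOSUM62")
    return _blosum62


@dataclass
class AlignmentHit:
    """An optimal local alignment.  Coordinates are 1-based inclusive; a score-0
    result is the empty hit (all coordinates 0, empty aligned strings)."""

    query_id: str
    target_id: str
    score: int
    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0
    q_aln: str = ""
    t_aln: str = ""

    @property
    def empty(self) -> bool:
        return self.score <= 0


def rescore(hit: AlignmentHit, matrix=None, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Recompute the score of an alignment from its aligned strings (invariant check)."""
    matrix = matrix if matrix is not None else blosum62()
    score = 0.0
    in_gap = False
    for qc, tc in zip(hit.q_aln, hit.t_aln):
        if qc == "-" or tc == "-":
            score -= gap_extend + (gap_open if not in_gap else 0)
            in_gap = True
        else:
            score += matrix[qc, tc]
            in_gap = False
    return int(score)


def _check_residues(seq: str, matrix, label: str) -> None:
    alphabet = set(matrix.alphabet)
    for c in seq:
        if c not in alphabet:
            raise ValueError(f"unknown residue {c!r} in {label}: not covered by the matrix")


def smith_waterman(
    query: str,
    target: str,
    matrix=None,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit:
    """Optimal local alignment of ``query`` against ``target``.

    Deterministic: among co-optimal end cells the alignment with the smallest
    target start, then smallest query start, then shortest length is reported;
    traceback prefers substitutions over gap closure over gap extension.
    """
    if not query or not target:
        raise ValueError("both sequences must be non-empty")
    matrix = matrix if matrix is not None else blosum62()
    _check_residues(query, matrix, "query")
    _check_residues(target, matrix, "target")
    m, n = len(query), len(target)
    go, ge = gap_open, gap_extend
    open_cost = go + ge

    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in query (consumes target)
    F = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in target (consumes query)
    best = 0.0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] - open_cost, Ei[j - 1] - ge)
            f = max(Hi1[j] - open_cost, Fi1[j] - ge)
            h = max(0.0, Hi1[j - 1] + matrix[qi, target[j - 1]], e, f)
            Ei[j], Fi[j] = e, f
            Hi[j] = h
            if h > best:
                best = h
    if best <= 0:
        return AlignmentHit(query_id, target_id, 0)

    candidates = []
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if H[i][j] == best:
                aln = _traceback(query, target, matrix, open_cost, ge, H, E, F, i, j)
                candidates.append(aln)
    # (t_start, q_start, alignment length) tie-break
    qa, ta, qs, ts = min(candidates, key=lambda a: (a[3], a[2], len(a[0])))
    q_end = qs + len(qa.replace("-", "")) - 1
    t_end = ts + len(ta.replace("-", "")) - 1
    return AlignmentHit(query_id, target_id, int(best), qs, q_end, ts, t_end, qa, ta)


def _traceback(q, t, matrix, open_cost, ge, H, E, F, i, j):
    qa: list[str] = []
    ta: list[str] = []
    state = "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            if i > 0 and j > 0 and h == H[i - 1][j - 1] + matrix[q[i - 1], t[j - 1]]:
                qa.append(q[i - 1])
                ta.append(t[j - 1])
                i -= 1
                j -= 1
            elif h == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in target, consume query residue
            f = F[i][j]
            qa.append(q[i - 1])
            ta.append("-")
            if f == H[i - 1][j] - open_cost:
                state = "H"
            i -= 1
        else:  # state == "E": gap in query, consume target residue
            e = E[i][j]
            qa.append("-")
            ta.append(t[j - 1])
            if e == H[i][j - 1] - open_cost:
                state = "H"
            j -= 1
    return "".join(reversed(qa)), "".join(reversed(ta)), i + 1, j + 1


def screen(
    queries: Iterable,
    orfs: Sequence,
    min_score: int = 30,
    top_k: int = 10,
    matrix=None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> pd.DataFrame:
    """Align every query against every ORF and return the ranked hit table.

    ``queries`` and ``orfs`` are objects with ``.id`` and a protein sequence
    (``.seq`` or ``.protein``) or ``(id, seq)`` pairs.  Per query, hits with
    score >= ``min_score`` are sorted by (score desc, target id, target start)
    and truncated to ``top_k``.  Stable, deterministic, and invariant to the
    input ORF order.
    """
    if min_score < 0 or top_k < 1:
        raise ValueError("thresholds must be non-negative and top_k >= 1")

    def unpack(rec):
        if hasattr(rec, "id"):
            seq = getattr(rec, "protein", None) or getattr(rec, "seq")
            return rec.id, seq
        return rec

    targets = [unpack(o) for o in orfs]
    rows = []
    for qrec in queries:
        qid, qseq = unpack(qrec)
        hits = []
        for tid, tseq in targets:
            hit = smith_waterman(
                qseq, tseq, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend,
                query_id=qid, target_id=tid,
            )
            if not hit.empty and hit.score >= min_score:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.score, h.target_id, h.t_start))
        for h in hits[:top_k]:
            rows.append(
                {
                    "query_id": h.query_id, "target_id": h.target_id, "score": h.score,
                    "q_start": h.q_start, "q_end": h.q_end,
                    "t_start": h.t_start, "t_end": h.t_end,
                    "q_aln": h.q_aln, "t_aln": h.t_aln,
                }
            )
    columns = [
        "query_id", "target_id", "score", "q_start", "q_end", "t_start", "t_end",
        "q_aln", "t_aln",
    ]
    return pd.DataFrame(rows, columns=columns)
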