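"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's search code paths: the off-target
oracle slides a window over every position of both strands; the SSR oracle
enumerates maximal tandem runs with regular expressions; the alignment
oracle is a plain affine-gap dynamic program.
"""

from __future__ import annotations

import operator
import re

from crispec.sequence import IUPAC, revcomp

# ---------------------------------------------------------------- off-targets


def brute_force_offtargets(
    genome: str, spacer: str, max_mm: int, pam_pattern: str = "NRG"
) -> set[tuple[int, str, int]]:
    """{(start, strand, n_mismatch)} by scanning every window on both strands."""
    hits: set[tuple[int, str, int]] = set()
    L, plen, n = len(spacer), len(pam_pattern), len(genome)
    for strand, seq in (("+", genome), ("-", revcomp(genome))):
        for i in range(n - L - plen + 1):
            pam = seq[i + L : i + L + plen]
            if not all(b in IUPAC[p] for p, b in zip(pam_pattern, pam)):
                continue
            mm = sum(map(operator.ne, spacer, seq[i : i + L]))
            if mm <= max_mm:
                start = i if strand == "+" else n - (i + L + plen)
                hits.add((start, strand, mm))
    return hits


# ----------------------------------------------------------------------- SSRs


def brute_force_perfect_ssrs(
    seq: str, min_repeats: dict[int, int]
) -> list[tuple[int, int, str, int]]:
    """All maximal complete-unit tandem runs meeting thresholds, then the
    same longest-wins/leftmost/shortest-unit overlap resolution.

    Enumeration is regex-based: ``(unit)\\1{k-1,}`` matches are maximal and
    leftmost by regex semantics.  Returns (start, end, unit, count).
    """
    candidates: list[tuple[int, int, str, int]] = []
    for ul, min_count in sorted(min_repeats.items()):
        pat = re.compile(r"([ACGT]{%d})\1{%d,}" % (ul, min_count - 1))
        pos = 0
        while True:
            m = pat.search(seq, pos)
            if not m:
                break
            unit = m.group(1)
            if _primitive(unit):
                count = (m.end() - m.start()) // ul
                candidates.append((m.start(), m.start() + count * ul, unit, count))
                pos = m.start() + 1  # allow overlapping starts at other phases
            else:
                pos = m.start() + 1
        # regex with backtracking from each start would be quadratic; the
        # search above already yields leftmost-maximal runs per unit length.
    # overlap resolution: longest span wins, ties leftmost, then shorter unit
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], len(c[2])))
    chosen: list[tuple[int, int, str, int]] = []
    for s, e, unit, count in candidates:
        if any(s < ce and e > cs for cs, ce, _, _ in chosen):
            continue
        chosen.append((s, e, unit, count))
    chosen.sort()
    return chosen


def _primitive(unit: str) -> bool:
    return all(
        not (len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p))
        for p in range(1, len(unit))
    )


# ------------------------------------------------------------------ alignment


def affine_semiglobal_score(
    ref: str,
    read: str,
    match: float = 2,
    mismatch: float = -3,
    gap_open: float = -8,
    gap_extend: float = -1,
) -> float:
    """Optimal semi-global affine-gap score (free end gaps) by Gotoh DP.

    ``gap_open`` is the score of the first gapped position, ``gap_extend``
    of each subsequent one, matching the aligner configuration.
    """
    n, m = len(ref), len(read)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (deletion)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free end gaps
        M[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = 0.0
        M[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    # free end gaps: best over last row/column
    best = max(M[n][m], X[n][m], Y[n][m])
    for i in range(n + 1):
        best = max(best, M[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j])
    return best
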