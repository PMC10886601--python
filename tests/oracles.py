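"""Independent brute-force oracles used by the tests.

These deliberately re-derive results with the most literal algorithm
available (full-matrix DP, per-column counting, all-pairs union-find,
exhaustive window enumeration) and share no code with the package
implementations they check.
"""

from __future__ import annotations

from collections import Counter


def sw_score_oracle(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -5,
    gap_extend: int = -1,
) -> int:
    """Optimal local alignment score by the full Gotoh recurrence.

    A gap of length L costs ``gap_open + (L-1) * gap_extend``; characters
    outside A/C/G/T (e.g. N) never match.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            paired = (
                match
                if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT")
                else mismatch
            )
            H[i][j] = max(0.0, H[i - 1][j - 1] + paired, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def consensus_oracle(rows: list[str], threshold: float = 0.5) -> str:
    """Per-column counting consensus following the 50% majority rule."""
    if not rows:
        raise ValueError("no rows")
    out = []
    n = len(rows)
    for col in range(len(rows[0])):
        chars = [r[col] for r in rows]
        if chars.count("-") / n >= threshold:
            continue
        counts = Counter(c for c in chars if c != "-")
        top = max(counts.values())
        winners = sorted(
            (c for c, k in counts.items() if k == top),
            key=lambda c: ("ACGTN".index(c) if c in "ACGTN" else 99, c),
        )
        winner = winners[0]
        nongap = n - chars.count("-")
        out.append(winner if counts[winner] / nongap >= threshold else "N")
    return "".join(out)


def partition_oracle(n: int, linked) -> list[frozenset[int]]:
    """Connected components over the pairwise predicate ``linked(i, j)``."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if linked(i, j):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def ppt_oracle(
    internal: str,
    window: int = 10,
    min_purine_frac: float = 0.8,
    max_gap_to_ltr: int = 5,
):
    """Exhaustive PPT search mirroring the stated rule.

    For each admissible end position (right-most first), test the
    ``window``-nt window; if it qualifies, extend the start leftward one
    base at a time while the purine fraction of the whole interval holds.
    """
    n = len(internal)
    if n < window:
        return None

    def frac(s, e):
        seg = internal[s:e]
        return sum(1 for c in seg if c in "AG") / len(seg)

    for gap in range(max_gap_to_ltr + 1):
        e = n - gap
        if e < window:
            return None
        s = e - window
        if frac(s, e) < min_purine_frac:
            continue
        while s > 0 and frac(s - 1, e) >= min_purine_frac:
            s -= 1
        return (s, e)
    return None
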