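"""Independent reference implementations used only by the test suite.

Each oracle is written from the mathematical definition, with none of the
shortcuts the package uses (no recurrence-track seeding, no two-pass
wraparound rows, no edlib), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from typing import List, Tuple


def oracle_tandem_score(region: str, motif: str, match: int = 2,
                        mismatch: int = 3, indel: int = 5) -> int:
    """Best global score of ``region`` against unbounded tandem copies of
    ``motif``, by plain Needleman-Wunsch against an explicit long tandem
    reference with free leading/trailing reference gaps."""
    n, m = len(region), len(motif)
    reps = (n + 2 * m) // m + 2
    ref = motif * reps
    R = len(ref)
    NEG = -(10 ** 9)
    # dp[i][j]: best score aligning region[:i] to ref[:j], start free in ref
    prev = [0] * (R + 1)
    for i in range(1, n + 1):
        cur = [NEG] * (R + 1)
        cur[0] = prev[0] - indel
        for j in range(1, R + 1):
            sub = match if region[i - 1] == ref[j - 1] else -mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] - indel, cur[j - 1] - indel)
        prev = cur
    return max(prev)  # end free in ref


def oracle_edit_distance(a: str, b: str) -> int:
    """Textbook unit-cost edit distance."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[lb]


def oracle_perfect_tandems(seq: str) -> List[Tuple[int, int, int]]:
    """All maximal perfect tandem repeats of ``seq`` as (start, end, period),
    with at least two full copies, by exhaustive check of every candidate
    triple; records whose period is a multiple of a same-span record's
    period are pruned (the redundancy rule the finder applies)."""
    n = len(seq)
    found = []
    for period in range(1, n // 2 + 1):
        for start in range(0, n - 2 * period + 1):
            # must repeat with this period for at least 2*period bases
            if any(seq[i] != seq[i + period] for i in range(start, start + period)):
                continue
            end = start + 2 * period
            while end < n and seq[end] == seq[end - period]:
                end += 1
            # maximality to the left
            if start > 0 and seq[start - 1] == seq[start - 1 + period]:
                continue
            # skip non-leftmost starts of the same run
            if any(
                (s, e) == (start, end) for s, e, p in found if p == period
            ):
                continue
            if "N" in seq[start:end]:
                continue
            found.append((start, end, period))
    # redundancy pruning on identical spans
    pruned = []
    for s, e, p in found:
        if any(
            s2 == s and e2 == e and p2 < p and p % p2 == 0 for s2, e2, p2 in found
        ):
            continue
        pruned.append((s, e, p))
    return sorted(pruned)
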