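"""Independent oracles used to verify the implementation.

These deliberately take different computational routes from the package:
a textbook rolling-row Smith-Waterman DP (scores only, no direction
matrix), an exhaustive recursion over all gapped alignments of all
substring pairs, and a four-term argmax re-derivation of the single-cell
rule. They are written against the recurrence definition, not against the
package's code.
"""

from functools import lru_cache


def sw_max_score(q: str, s: str, match: int, mismatch: int, gap: int) -> int:
    """Textbook Smith-Waterman maximum local score, rolling rows."""
    prev = [0] * (len(q) + 1)
    best = 0
    for i in range(1, len(s) + 1):
        cur = [0] * (len(q) + 1)
        for j in range(1, len(q) + 1):
            diag = prev[j - 1] + (match if q[j - 1] == s[i - 1] else mismatch)
            up = prev[j] - gap
            left = cur[j - 1] - gap
            cur[j] = max(0, diag, up, left)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def exhaustive_local_score(
    q: str, s: str, match: int, mismatch: int, gap: int
) -> int:
    """Best score over every gapped alignment of every substring pair.

    Enumerates all (q-substring, s-substring) pairs and, for each, the best
    end-to-end gapped alignment by recursion over the last emitted column.
    Intended for tiny sequences (lengths <= 6).
    """

    @lru_cache(maxsize=None)
    def best_global(a: str, b: str) -> int:
        if not a and not b:
            return 0
        options = []
        if a and b:
            options.append(
                best_global(a[:-1], b[:-1])
                + (match if a[-1] == b[-1] else mismatch)
            )
        if a:
            options.append(best_global(a[:-1], b) - gap)
        if b:
            options.append(best_global(a, b[:-1]) - gap)
        return max(options)

    best = 0
    for i0 in range(len(q) + 1):
        for i1 in range(i0, len(q) + 1):
            for j0 in range(len(s) + 1):
                for j1 in range(j0, len(s) + 1):
                    score = best_global(q[i0:i1], s[j0:j1])
                    if score > best:
                        best = score
    return best


def cell_argmax(x: int, y: int, v: int, sub: int, gamma: int):
    """Four-term argmax of the cell recurrence with the adopted tie rules:
    diagonal wins any tie; a vertical/horizontal tie goes horizontal."""
    cd, cy, cv = x + sub, y - gamma, v - gamma
    best = max(0, cd, cy, cv)
    if best <= 0:
        return 0, 0
    if cd == best:
        return best, 2
    if cy == best and cv == best:
        return best, 3
    if cy == best:
        return best, 1
    return best, 3
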