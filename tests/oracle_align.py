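"""Independent brute-force alignment oracle.

Enumerates every global alignment as a lattice path of M/X/Y moves
(match, gap-in-subject, gap-in-query) and scores it directly: matrix
scores for M columns, and each maximal run of k equal gap moves costs
gap_open + k * gap_extend.  Completely independent of the dynamic
program it is used to check.
"""

from functools import lru_cache

from orpscan.align import AlignmentParams, encode


@lru_cache(maxsize=None)
def _paths(la: int, lb: int) -> tuple[str, ...]:
    if la == 0 and lb == 0:
        return ("",)
    out = []
    if la > 0 and lb > 0:
        out += [p + "M" for p in _paths(la - 1, lb - 1)]
    if la > 0:
        out += [p + "X" for p in _paths(la - 1, lb)]
    if lb > 0:
        out += [p + "Y" for p in _paths(la, lb - 1)]
    return tuple(out)


def brute_force_score(a: str, b: str, params: AlignmentParams) -> float:
    ea, eb = encode(a), encode(b)
    best = None
    for path in _paths(len(a), len(b)):
        i = j = 0
        score = 0.0
        run = ""
        for op in path:
            if op == "M":
                score += params.matrix[ea[i], eb[j]]
                i += 1
                j += 1
            else:
                if op != run:
                    score -= params.gap_open
                score -= params.gap_extend
                if op == "X":
                    i += 1
                else:
                    j += 1
            run = op if op != "M" else ""
        if best is None or score > best:
            best = score
    return best
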