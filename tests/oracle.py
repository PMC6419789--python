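"""Independent brute-force oracle: exhaustive enumeration of assignments."""

import math

from lewisopt.molgraph import positions
from lewisopt.scoring import ElectronAssignment, assignment_score


def enumerate_complete(p):
    """Yield every complete counts tuple for the multiset ``p``."""
    caps = [p.mult(pos) for pos in p.order]
    suffix = [0] * (len(caps) + 1)
    for i in range(len(caps) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + caps[i]

    def rec(i, left, acc):
        if i == len(caps):
            if left == 0:
                yield tuple(acc)
            return
        lo = max(0, left - suffix[i + 1])
        for n in range(lo, min(caps[i], left) + 1):
            acc.append(n)
            yield from rec(i + 1, left - n, acc)
            acc.pop()

    yield from rec(0, p.e_t, [])


def brute_minimum(g, table, pair_mode=True, fixed=None, p=None):
    """(min score, list of arg-min counts tuples) by exhaustive search."""
    if p is None:
        p = positions(g, pair_mode=pair_mode)
    best = math.inf
    argmins = []
    for counts in enumerate_complete(p):
        s = assignment_score(g, ElectronAssignment(p, counts, fixed), table)
        if s < best:
            best, argmins = s, [counts]
        elif s == best and math.isfinite(s):
            argmins.append(counts)
    return best, argmins
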