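"""Independent brute-force oracles used by the tests.

These re-derive duplex and fold energies by exhaustive enumeration of
all admissible pairings/structures under the same published energy
rules, written without reference to the package's dynamic programs.
"""

from itertools import combinations

ALLOWED = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
GC = {("C", "G"), ("G", "C")}
AU = {("A", "U"), ("U", "A")}
WOBBLE = {("G", "U"), ("U", "G")}
LOOP = 4.0


def stack_energy(p1, p2):
    if p1 in WOBBLE or p2 in WOBBLE:
        return -0.5
    if p1 in GC and p2 in GC:
        return -3.0
    if p1 in AU and p2 in AU:
        return -1.0
    return -2.0


def brute_duplex(x: str, y: str):
    """Min energy over antiparallel non-crossing inter-strand pairings.

    Returns (mfe, paired_count); energy 0 reports 0 pairs.
    """
    n, m = len(x), len(y)
    best_e, best_c = 0.0, 0
    for k in range(1, min(n, m) + 1):
        for xs in combinations(range(n), k):
            for ys in combinations(range(m), k):
                pairs = list(zip(xs, reversed(ys)))
                if any((x[i], y[j]) not in ALLOWED for i, j in pairs):
                    continue
                e = 0.0
                for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
                    if i2 == i1 + 1 and j2 == j1 - 1:
                        e += stack_energy((x[i1], y[j1]), (x[i2], y[j2]))
                    else:
                        e += LOOP
                if e < best_e - 1e-9 or (abs(e - best_e) <= 1e-9 and k > best_c):
                    best_e, best_c = e, k
    if best_e > -1e-9:
        return 0.0, 0
    return best_e, best_c


def _matchings(seq, i, max_j):
    """All non-crossing pair sets on seq[i..max_j] with span >= 5 per pair."""
    if i > max_j:
        yield []
        return
    # i unpaired
    for rest in _matchings(seq, i + 1, max_j):
        yield rest
    # i paired with j
    for j in range(i + 4, max_j + 1):
        if (seq[i], seq[j]) not in ALLOWED:
            continue
        for inner in _matchings(seq, i + 1, j - 1):
            for outer in _matchings(seq, j + 1, max_j):
                yield [(i, j)] + inner + outer


def structure_energy(seq, pairs):
    """Energy of one structure, or None if a hairpin is too tight.

    Each pair either stacks on its immediate inner neighbour, closes a
    hairpin (>= 3 unpaired inside), or closes a loop event (+4).
    """
    pairs = sorted(pairs)
    e = 0.0
    for i, j in pairs:
        inside = [(a, b) for a, b in pairs if i < a and b < j]
        outermost = [
            (a, b)
            for a, b in inside
            if not any(c < a and b < d for c, d in inside)
        ]
        if not outermost:
            if j - i - 1 < 3:
                return None
            continue
        if outermost == [(i + 1, j - 1)]:
            e += stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
        else:
            e += LOOP
    return e


def brute_fold(seq: str, blocked=()):
    """Min fold energy by structure enumeration (windows <= ~14 nt)."""
    best = 0.0
    blocked = set(blocked)
    for pairs in _matchings(seq, 0, len(seq) - 1):
        if any(i in blocked or j in blocked for i, j in pairs):
            continue
        e = structure_energy(seq, pairs)
        if e is not None and e < best:
            best = e
    return best
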