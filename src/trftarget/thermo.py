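"""Duplex stability and target-site accessibility features.

The pipeline needs three thermodynamic quantities per candidate site:
the minimum free energy (MFE) of the tRF:mRNA inter-molecular duplex,
the number of tRF bases paired in that duplex, and the accessibility of
the site within the local mRNA secondary structure (exposed nucleotides
and the energy to open the site).

These are computed under a small bundled stacking model chosen so that
every value is exactly reproducible by exhaustive enumeration in tests:
energy accrues only from stacked adjacent base pairs, every internal
loop / bulge / multibranch event costs a flat penalty, and hairpin loops
need at least 3 unpaired bases.  A full nearest-neighbor backend
(ViennaRNA's RNAfold/RNAduplex command-line programs) can be swapped in
for production parity; it changes the numbers but not the contracts
consumed downstream (mfe <= 0, exposed counts bounded, opening energy
>= 0).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .seq import Interval

#: canonical pair codes, used to index stacking tables
PAIRS = ("AU", "UA", "CG", "GC", "GU", "UG")
_BASE = {"A": 0, "C": 1, "G": 2, "U": 3}

# 4x4 base -> pair code, -1 where no pair is allowed
_PAIR_CODE = -np.ones((4, 4), dtype=np.int64)
for _k, _p in enumerate(PAIRS):
    _PAIR_CODE[_BASE[_p[0]], _BASE[_p[1]]] = _k

# pair class: 0 = wobble (GU/UG), 1 = A:U, 2 = G:C
_PAIR_CLASS = np.array([1, 1, 2, 2, 0, 0], dtype=np.int64)


def _default_stack_table() -> np.ndarray:
    """Bundled stack energies (kcal/mol) by the classes of the two pairs.

    G:C on G:C stacks are strongest (-3.0), stacks mixing G:C with A:U
    are -2.0, A:U on A:U -1.0, and anything touching a G:U wobble -0.5.
    """
    table = np.zeros((6, 6))
    for a in range(6):
        for b in range(6):
            ca, cb = _PAIR_CLASS[a], _PAIR_CLASS[b]
            if ca == 0 or cb == 0:
                e = -0.5
            elif ca == 2 and cb == 2:
                e = -3.0
            elif ca == 1 and cb == 1:
                e = -1.0
            else:
                e = -2.0
            table[a, b] = e
    return table


@dataclass(frozen=True)
class EnergyModel:
    """Stacking energies, loop penalty and hairpin constraint.

    ``stack[p, q]`` is the energy of pair with code ``q`` stacked on pair
    ``p`` (codes index :data:`PAIRS`); all stack energies must be <= 0
    and the loop penalty >= 0.
    """

    stack: np.ndarray = field(default_factory=_default_stack_table)
    loop_penalty: float = 4.0
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if np.any(self.stack > 0):
            raise ValueError("stack energies must be <= 0")
        if self.loop_penalty < 0:
            raise ValueError("loop penalty must be >= 0")

    @classmethod
    def from_tsv(cls, path, loop_penalty: float = 4.0) -> "EnergyModel":
        """Override the stack table from a TSV of (pair1, pair2, kcal/mol)."""
        table = _default_stack_table()
        idx = {p: i for i, p in enumerate(PAIRS)}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                p1, p2, e = line.split("\t")
                table[idx[p1], idx[p2]] = float(e)
        return cls(stack=table, loop_penalty=loop_penalty)


@dataclass(frozen=True)
class DuplexResult:
    mfe: float
    paired_count: int
    pairing_map: tuple[tuple[int, int], ...]  # (trf_pos, target_pos), 0-based


@dataclass(frozen=True)
class AccessibilityResult:
    exposed_at_site: int
    exposed_flanks: int
    opening_energy: float


def _encode(s: str) -> np.ndarray:
    return np.array([_BASE.get(c, -1) for c in s], dtype=np.int64)


# ---------------------------------------------------------------------------
# inter-molecular duplex


def duplex_mfe(trf: str, target: str, model: EnergyModel | None = None) -> DuplexResult:
    """Global MFE over non-crossing antiparallel inter-strand pairings.

    Both strands are read 5'->3'; pairs (i, j) are antiparallel-monotone
    (increasing i, decreasing j).  Adjacent consecutive pairs stack;
    non-adjacent consecutive pairs cost one loop penalty.  The empty
    pairing (energy 0) is always admissible, and an energy of exactly 0
    is reported with no pairs.
    """
    model = model or EnergyModel()
    x, y = _encode(trf), _encode(target)
    n, m = len(x), len(y)
    INF = float("inf")
    eps = 1e-9
    # D[i][j]: best (energy, -count) of a pairing whose last pair is (i, j)
    dE = [[INF] * m for _ in range(n)]
    dC = [[0] * m for _ in range(n)]
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    # M: running best over the rectangle i' <= i, j' >= j
    mE = [[INF] * m for _ in range(n)]
    mC = [[0] * m for _ in range(n)]
    mArg: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]

    def better(e1, c1, e2, c2):
        return e1 < e2 - eps or (abs(e1 - e2) <= eps and c1 > c2)

    for i in range(n):
        for j in range(m - 1, -1, -1):
            code = _PAIR_CODE[x[i], y[j]] if x[i] >= 0 and y[j] >= 0 else -1
            if code >= 0:
                bE, bC, bP = 0.0, 1, None
                if i > 0 and j < m - 1:
                    pcode = _PAIR_CODE[x[i - 1], y[j + 1]] if x[i - 1] >= 0 and y[j + 1] >= 0 else -1
                    if pcode >= 0 and dE[i - 1][j + 1] < INF:
                        e = dE[i - 1][j + 1] + model.stack[pcode, code]
                        c = dC[i - 1][j + 1] + 1
                        if better(e, c, bE, bC):
                            bE, bC, bP = e, c, (i - 1, j + 1)
                    if mE[i - 1][j + 1] < INF:
                        e = mE[i - 1][j + 1] + model.loop_penalty
                        c = mC[i - 1][j + 1] + 1
                        if better(e, c, bE, bC):
                            bE, bC, bP = e, c, mArg[i - 1][j + 1]
                dE[i][j], dC[i][j] = bE, bC
                if bP is not None:
                    parent[(i, j)] = bP
            # fold D into the rectangle minimum
            cE, cC, cA = dE[i][j], dC[i][j], (i, j) if dE[i][j] < INF else None
            if i > 0 and mE[i - 1][j] < INF and better(mE[i - 1][j], mC[i - 1][j], cE, cC):
                cE, cC, cA = mE[i - 1][j], mC[i - 1][j], mArg[i - 1][j]
            if j < m - 1 and mE[i][j + 1] < INF and better(mE[i][j + 1], mC[i][j + 1], cE, cC):
                cE, cC, cA = mE[i][j + 1], mC[i][j + 1], mArg[i][j + 1]
            mE[i][j], mC[i][j], mArg[i][j] = cE, cC, cA

    bestE, bestC, bestA = 0.0, 0, None
    for i in range(n):
        for j in range(m):
            if dE[i][j] < INF and better(dE[i][j], dC[i][j], bestE, bestC):
                bestE, bestC, bestA = dE[i][j], dC[i][j], (i, j)
    if bestE > -eps or bestA is None:
        return DuplexResult(0.0, 0, ())
    pairs = []
    cur: tuple[int, int] | None = bestA
    while cur is not None:
        pairs.append(cur)
        cur = parent.get(cur)
    pairs.reverse()
    return DuplexResult(float(bestE), bestC, tuple(pairs))


# ---------------------------------------------------------------------------
# intramolecular local fold (Zuker-style under the bundled model)

_NEG = -1.0e17
_INF = 1.0e18


@njit(cache=True)
def _fold_tables(codes, blocked, stack, loop_penalty, min_hairpin):  # pragma: no cover - numba
    n = codes.shape[0]
    V = np.full((n, n), _INF)
    Wp = np.full((n, n), _INF)
    pairmat = np.full((n, n), -1, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            a, b = codes[i], codes[j]
            if a < 0 or b < 0 or blocked[i] or blocked[j]:
                continue
            if a == 0 and b == 3:
                pairmat[i, j] = 0
            elif a == 3 and b == 0:
                pairmat[i, j] = 1
            elif a == 1 and b == 2:
                pairmat[i, j] = 2
            elif a == 2 and b == 1:
                pairmat[i, j] = 3
            elif a == 2 and b == 3:
                pairmat[i, j] = 4
            elif a == 3 and b == 2:
                pairmat[i, j] = 5
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            code = pairmat[i, j]
            if code >= 0:
                best = _INF
                if j - i - 1 >= min_hairpin:
                    best = 0.0
                if j - 1 > i + 1:
                    inner = pairmat[i + 1, j - 1]
                    if inner >= 0 and V[i + 1, j - 1] < _INF:
                        e = V[i + 1, j - 1] + stack[code, inner]
                        if e < best:
                            best = e
                    if Wp[i + 1, j - 1] < _INF:
                        e = Wp[i + 1, j - 1] + loop_penalty
                        if e < best:
                            best = e
                V[i, j] = best
            # Wp over [i, j]
            best = _INF
            if j > i and Wp[i + 1, j] < best:
                best = Wp[i + 1, j]
            for k in range(i + 1, j + 1):
                if V[i, k] < _INF:
                    e = V[i, k]
                    if k + 1 <= j:
                        w = Wp[k + 1, j]
                        if w < 0.0:
                            e += w
                    if e < best:
                        best = e
            Wp[i, j] = best
    return V, Wp, pairmat


def _trace(i, j, paired_with, V, Wp, pairmat, stack, loop_penalty, min_hairpin, mode):
    """Deterministic traceback of one MFE structure from the DP tables."""
    eps = 1e-6
    stackv = [(i, j, mode)]
    while stackv:
        i, j, mode = stackv.pop()
        if i >= j:
            continue
        if mode == 0:  # W: best over [i, j], empty allowed
            if Wp[i, j] < -eps:
                stackv.append((i, j, 1))
            continue
        if mode == 1:  # Wp: at least one pair
            target = Wp[i, j]
            if j > i and abs(Wp[i + 1, j] - target) <= eps:
                stackv.append((i + 1, j, 1))
                continue
            done = False
            for k in range(i + 1, j + 1):
                if V[i, k] >= _INF:
                    continue
                e = V[i, k]
                rest = 0.0
                if k + 1 <= j and Wp[k + 1, j] < 0.0:
                    rest = Wp[k + 1, j]
                if abs(e + rest - target) <= eps:
                    paired_with[i], paired_with[k] = k, i
                    stackv.append((i, k, 2))
                    if k + 1 <= j and rest < 0.0:
                        stackv.append((k + 1, j, 1))
                    done = True
                    break
            if not done:  # numerical fallback: leave unpaired
                continue
            continue
        # mode == 2: V, (i, j) already recorded as paired
        target = V[i, j]
        code = pairmat[i, j]
        if j - 1 > i + 1:
            inner = pairmat[i + 1, j - 1]
            if inner >= 0 and V[i + 1, j - 1] < _INF and abs(
                V[i + 1, j - 1] + stack[code, inner] - target
            ) <= eps:
                paired_with[i + 1], paired_with[j - 1] = j - 1, i + 1
                stackv.append((i + 1, j - 1, 2))
                continue
        if j - i - 1 >= min_hairpin and abs(target) <= eps:
            continue
        if j - 1 > i + 1 and Wp[i + 1, j - 1] < _INF and abs(
            Wp[i + 1, j - 1] + loop_penalty - target
        ) <= eps:
            stackv.append((i + 1, j - 1, 1))


def local_fold(
    window: str,
    model: EnergyModel | None = None,
    constraint: Interval | None = None,
) -> tuple[str, float]:
    """MFE intramolecular structure of a window (dot-bracket, energy).

    No pseudoknots; hairpin loops need >= ``model.min_hairpin`` unpaired
    bases.  ``constraint`` forces a span of the window to stay unpaired.
    An energy of exactly 0 is reported as the open (all-dot) structure.
    """
    model = model or EnergyModel()
    if len(window) < 6:
        raise ValueError("fold window shorter than 6 nt")
    codes = _encode(window)
    n = len(codes)
    blocked = np.zeros(n, dtype=np.bool_)
    if constraint is not None:
        blocked[constraint.start : constraint.end] = True
    V, Wp, pairmat = _fold_tables(
        codes, blocked, model.stack, model.loop_penalty, model.min_hairpin
    )
    energy = min(0.0, float(Wp[0, n - 1]))
    paired_with = np.full(n, -1, dtype=np.int64)
    if energy < -1e-6:
        _trace(0, n - 1, paired_with, V, Wp, pairmat,
               model.stack, model.loop_penalty, model.min_hairpin, 0)
    structure = "".join(
        "." if p < 0 else ("(" if p > k else ")") for k, p in enumerate(paired_with)
    )
    return structure, energy


def accessibility_features(
    utr: str,
    site: Interval,
    model: EnergyModel | None = None,
    flank: int = 40,
) -> AccessibilityResult:
    """Fold the site's local window and measure how open the site is.

    The window is up to ``flank`` nt either side of the 6-nt seed match.
    ``opening_energy`` is the cost of forbidding all pairing at the site:
    E(fold | site unpaired) - E(fold), always >= 0.
    """
    model = model or EnergyModel()
    wstart = max(0, site.start - flank)
    wend = min(len(utr), site.end + flank)
    window = utr[wstart:wend]
    s0, s1 = site.start - wstart, site.end - wstart
    structure, e_free = local_fold(window, model)
    exposed_site = structure[s0:s1].count(".")
    f0, f1 = max(0, s0 - 10), min(len(window), s1 + 10)
    exposed_flanks = structure[f0:s0].count(".") + structure[s1:f1].count(".")
    _, e_open = local_fold(window, model, constraint=Interval("w", s0, s1))
    opening = max(0.0, e_open - e_free)
    return AccessibilityResult(exposed_site, exposed_flanks, opening)


# ---------------------------------------------------------------------------
# optional external backend (ViennaRNA command-line programs)


class ViennaBackend:
    """Adapter delegating to RNAduplex / RNAfold when they are on PATH.

    Provided for production parity with a full nearest-neighbor model;
    outputs honor the same contracts (mfe <= 0 reported as-is, structure
    as dot-bracket) but the numeric values differ from the bundled model.
    """

    def __init__(self) -> None:
        if shutil.which("RNAduplex") is None or shutil.which("RNAfold") is None:
            raise RuntimeError("ViennaRNA command-line programs not found on PATH")

    def duplex_mfe(self, trf: str, target: str) -> float:
        out = subprocess.run(
            ["RNAduplex", "--noLP"], input=f"{trf}\n{target}\n",
            capture_output=True, text=True, check=True,
        ).stdout
        # last parenthesised field is the energy, e.g. "(-7.40)"
        return float(out.strip().split("(")[-1].rstrip(")"))

    def local_fold(self, window: str) -> tuple[str, float]:
        out = subprocess.run(
            ["RNAfold", "--noPS"], input=f"{window}\n",
            capture_output=True, text=True, check=True,
        ).stdout
        line = out.strip().splitlines()[-1]
        structure = line.split(" ")[0]
        energy = float(line[line.rfind("(") + 1 : line.rfind(")")])
        return structure, energy
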