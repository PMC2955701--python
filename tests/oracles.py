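"""Independent brute-force oracles used by the unit and acceptance tests.

Everything in this module is written from the definitions alone and
must stay independent of the package's implementation paths it checks
(shared energy *parameters* are allowed; search/scan logic is not).
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


# ---------------------------------------------------------------------
# Seed rules (ungapped), coded directly from the rule statements
# ---------------------------------------------------------------------

def brute_force_rules(mirna_seed: str, window: str,
                      rule5_strict: bool = True) -> Set[int]:
    """Rules satisfied by the ungapped antiparallel seed alignment."""
    n = len(mirna_seed)
    flags = []  # "W" / "M" (GU) / "X"
    for i in range(n):
        pair = (mirna_seed[i], window[n - 1 - i])
        if pair in _WC:
            flags.append("W")
        elif pair in _GU:
            flags.append("M")
        else:
            flags.append("X")

    def longest(chars: str) -> int:
        best = cur = 0
        for f in flags:
            cur = cur + 1 if f in chars else 0
            best = max(best, cur)
        return best

    wc_run = longest("W")
    match_run = longest("WM")
    n_wc = flags.count("W")
    n_match = n_wc + flags.count("M")

    rules = set()
    if wc_run > 4:
        rules.add(1)
    if match_run > 5 and wc_run > 2:
        rules.add(2)
    if n_match > 6 and wc_run > 3:
        rules.add(3)
    if (flags[1] == flags[2] == flags[3] == "W" and n_wc > 3 and n_match > 4):
        rules.add(4)
    if n_match > 5 and n_wc > (5 if rule5_strict else 4):
        rules.add(5)
    return rules


def brute_force_seed_types(mirna_seed: str, window: str) -> Dict[str, bool]:
    """The six perfect seed-match types, straight from their definitions."""
    n = len(mirna_seed)
    wc = [(mirna_seed[i], window[n - 1 - i]) in _WC for i in range(n)]
    q1 = window[-1]
    return {
        "6mer": all(wc[1:7]),
        "7mer_a1": all(wc[1:7]) and q1 == "A",
        "7mer_m1": all(wc[0:7]),
        "7mer_m8": all(wc[1:8]),
        "8mer_a1": all(wc[1:8]) and q1 == "A",
        "8mer_m8": all(wc[0:8]),
    }


# ---------------------------------------------------------------------
# Duplex alignment enumeration (ungapped + at most `budget` bulged nt)
# ---------------------------------------------------------------------

def enumerate_duplex_min(mir: str, tgt: str, params, budget: int = 1
                         ) -> float:
    """Minimum alignment energy by exhaustive enumeration.

    Alignments are monotone chains of paired columns (i, j); the cost of
    consecutive columns is a stack when adjacent on both strands, else a
    loop/bulge penalty; leading and trailing overhangs are free.  The
    total bulged-nucleotide count |di - dj| summed over transitions must
    not exceed ``budget``.
    """
    def pairable(a: str, b: str) -> bool:
        return (a, b) in _WC or (a, b) in _GU

    cols = [(i, j) for i in range(len(mir)) for j in range(len(tgt))
            if pairable(mir[i], tgt[j])]
    best = [0.0]

    def extend(last: Tuple[int, int], energy: float, rem: int) -> None:
        best[0] = min(best[0], energy)
        li, lj = last
        for (i, j) in cols:
            if i <= li or j <= lj:
                continue
            di, dj = i - li - 1, j - lj - 1
            used = abs(di - dj)
            if used > rem:
                continue
            if di == 0 and dj == 0:
                cost = params.stack(mir[li], tgt[lj], mir[i], tgt[j])
            else:
                cost = params.loop_cost(di, dj)
            extend((i, j), energy + cost, rem - used)

    for start in cols:
        extend(start, 0.0, budget)
    return best[0]


# ---------------------------------------------------------------------
# Intramolecular structure enumeration (stack-only energies)
# ---------------------------------------------------------------------

def enumerate_structures(seq: str, blocked: Tuple[int, int] = None,
                         min_loop: int = 3):
    """All non-crossing pair sets (pseudoknot-free, hairpin >= min_loop)."""
    n = len(seq)

    def pairable(i: int, j: int) -> bool:
        if blocked and (blocked[0] <= i < blocked[1]
                        or blocked[0] <= j < blocked[1]):
            return False
        a, b = seq[i], seq[j]
        return (a, b) in _WC or (a, b) in _GU

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def structures(i: int, j: int) -> Tuple[Tuple[Tuple[int, int], ...], ...]:
        if j - i < min_loop + 1:
            return ((),)
        out = list(structures(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if pairable(i, k):
                for inner in structures(i + 1, k - 1):
                    for outer in structures(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        return tuple(out)

    return structures(0, n - 1)


def stack_energy_of_pairs(seq: str, pairs: Sequence[Tuple[int, int]],
                          stack_fn) -> float:
    """Stack-only energy of a pair set: every (i, j) stacked on
    (i+1, j-1) contributes one stack term."""
    pset = set(pairs)
    e = 0.0
    for (i, j) in pairs:
        if (i + 1, j - 1) in pset:
            e += stack_fn(seq[i], seq[j], seq[i + 1], seq[j - 1])
    return e


def enumerate_mfe(seq: str, stack_fn, blocked=None) -> float:
    structs = enumerate_structures(seq, blocked)
    return min(stack_energy_of_pairs(seq, p, stack_fn) for p in structs)


# ---------------------------------------------------------------------
# mRMR greedy (naive re-implementation)
# ---------------------------------------------------------------------

def naive_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI in bits for integer-valued vectors, by direct joint
    histogram summation."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    joint: Dict[Tuple[int, int], int] = {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px: Dict[int, float] = {}
    py: Dict[int, float] = {}
    for (a, b), c in joint.items():
        px[a] = px.get(a, 0) + c / n
        py[b] = py.get(b, 0) + c / n
    mi = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        mi += pab * np.log2(pab / (px[a] * py[b]))
    return max(0.0, mi)


def brute_force_mrmr(X: np.ndarray, y: np.ndarray) -> List[int]:
    """Greedy mRMR by naive rescans: step 1 maximises I(x;c); later
    steps maximise D - R of the candidate set, with D the mean
    feature-label MI and R the mean off-diagonal pairwise MI
    (ordered pairs, i != j).  Ties break to the lower index."""
    n_feat = X.shape[1]
    rel = [naive_mi(X[:, j], y) for j in range(n_feat)]
    selected: List[int] = []
    remaining = list(range(n_feat))
    while remaining:
        best_j, best_phi = None, None
        for j in remaining:
            cand = selected + [j]
            s = len(cand)
            D = sum(rel[i] for i in cand) / s
            R = sum(naive_mi(X[:, a], X[:, b])
                    for a in cand for b in cand if a != b) / (s * s)
            phi = D - R
            if best_phi is None or phi > best_phi + 1e-12:
                best_phi, best_j = phi, j
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


# ---------------------------------------------------------------------
# Window maxima
# ---------------------------------------------------------------------

def brute_force_window_max(starts: Sequence[int], utr_len: int,
                           window: int = 100) -> int:
    if not starts:
        return 0
    return max(
        sum(1 for s in starts if w <= s < w + window)
        for w in range(max(1, utr_len - window + 1))
    )
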