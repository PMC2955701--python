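"""miRNA:site hybrid structure and energies.

Computes the intermolecular minimum-energy alignment of the first 20
miRNA nucleotides against a candidate site and its 5' UTR context, with
the filter's seed pairing held fixed, plus a PITA-style accessibility
term from a pluggable intramolecular folding backend.

Energy model
------------
A simplified nearest-neighbour model: Turner-like stacking energies for
consecutive base pairs (W-C and G:U), a bulge penalty (open + per extra
nucleotide), a small symmetric internal-loop penalty per unpaired
nucleotide, and no mismatch term beyond helix interruption.  Parameters
live in :data:`DEFAULT_PARAMS` and can be overridden from a TSV file;
the dynamic programme, not the parameter values, is the tested contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .seqdata import GAP, GU, MISMATCH, WC, CandidateSite, MirnaSeq, UtrSeq
from .sitefilter import pair_status

logger = logging.getLogger(__name__)

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

# ---------------------------------------------------------------------
# Energy parameters
# ---------------------------------------------------------------------

# Stacks keyed by (top dinucleotide 5'->3', bottom dinucleotide 3'->5'),
# top strand = miRNA.  Values in kcal/mol, Turner-like.  Only pairs
# (W-C or G:U) appear; lookups fall back via 180-degree symmetry.
_STACKS_RAW = {
    ("AA", "UU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08, ("CA", "GU"): -2.11, ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35, ("CG", "GC"): -2.36, ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
    # G:U-containing stacks (approximate)
    ("AG", "UU"): -0.55, ("AU", "UG"): -1.36, ("CG", "GU"): -1.41,
    ("CU", "GG"): -1.53, ("GG", "CU"): -1.80, ("GU", "CG"): -2.11,
    ("GG", "UC"): -1.27, ("GU", "UA"): -1.00, ("UG", "AU"): -1.00,
    ("GA", "UU"): -0.50, ("UG", "GU"): -0.50, ("GU", "UG"): +0.47,
    ("GG", "UU"): -0.20, ("UU", "GG"): -0.20,
}


def _symmetrise(raw: Dict[Tuple[str, str], float]) -> Dict[Tuple[str, str], float]:
    table = {}
    for (top, bot), e in raw.items():
        table[(top, bot)] = e
        # rotate the stack 180 degrees: top 5'XY3'/bot 3'WZ5' == 5'ZW3'/3'YX5'
        table.setdefault((bot[::-1], top[::-1]), e)
    return table


_STACKS = _symmetrise(_STACKS_RAW)


@dataclass
class EnergyParams:
    stacks: Dict[Tuple[str, str], float]
    bulge_open: float = 3.0
    bulge_extend: float = 0.5
    loop_per_nt: float = 0.3
    default_stack: float = -0.5  # unlisted pair combinations

    def stack(self, m1: str, u1: str, m2: str, u2: str) -> float:
        """Energy of stacking pair (m1:u1) under (m2:u2); miRNA on top."""
        return self.stacks.get((m1 + m2, u1 + u2), self.default_stack)

    def loop_cost(self, di: int, dj: int) -> float:
        """Cost of the gap between two paired columns.

        ``di``/``dj`` are unpaired nucleotide counts on the miRNA / UTR
        side.  Zero on both sides means a stack (cost handled by caller).
        """
        if di == 0 and dj == 0:
            return 0.0
        if min(di, dj) == 0:  # bulge
            return self.bulge_open + self.bulge_extend * (max(di, dj) - 1)
        return self.loop_per_nt * (di + dj)


def load_params(path=None) -> EnergyParams:
    """Default parameters, optionally overridden by a stack-energy TSV
    with columns top, bottom, energy."""
    params = EnergyParams(stacks=dict(_STACKS))
    if path is not None:
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            params.stacks[(row["top"], row["bottom"])] = float(row["energy"])
        params.stacks = _symmetrise(params.stacks)
    return params


DEFAULT_PARAMS = load_params()


# ---------------------------------------------------------------------
# Duplex structure
# ---------------------------------------------------------------------

@dataclass
class DuplexStructure:
    """Secondary structure of one miRNA:site hybrid.

    ``status`` is indexed by miRNA position (p1 first, up to p20);
    ``dimer_code`` encodes the miRNA 2-mer at (p_m, p_m+1) as 1..16.
    ``bulges`` maps region -> (bulge structure count, bulged nt count)
    for site-side bulges.
    """

    status: Tuple[int, ...]
    dimer_code: Tuple[int, ...]
    seed_boundary: int
    e_seed: float
    e_three: float
    e_total: float
    bulges: Dict[str, Tuple[int, int]]
    pairs: Tuple[Tuple[int, int], ...] = ()  # (miRNA pos 1-based, UTR index)

    def counts(self, region: str) -> Dict[str, int]:
        """W-C / G:U / mismatch / gap counts over a region of the miRNA."""
        if region == "seed":
            sl = self.status[:8]
        elif region == "three":
            sl = self.status[8:20]
        elif region == "total":
            sl = self.status[:20]
        else:
            raise ValueError(region)
        return {
            "wc": sum(1 for s in sl if s == WC),
            "gu": sum(1 for s in sl if s == GU),
            "mismatch": sum(1 for s in sl if s == MISMATCH),
            "gap": sum(1 for s in sl if s == GAP),
        }


class DegenerateInputError(ValueError):
    pass


# ---------------------------------------------------------------------
# Intermolecular DP
# ---------------------------------------------------------------------

def duplex_align(mir: str, tgt: str, params: EnergyParams = DEFAULT_PARAMS,
                 max_bulge_nt: int = 4,
                 anchor: Optional[Tuple[str, str, int, int]] = None):
    """Minimum-energy antiparallel alignment of two RNA segments.

    ``mir`` is read 5'->3'; ``tgt`` is the target strand read 3'->5'
    (i.e. ``tgt[j]`` is the candidate partner of ``mir[j]`` in the
    in-register alignment).  Monotone alignments only (no pseudoknots),
    with at most ``max_bulge_nt`` bulged nucleotides in total; energy is
    the sum of stack terms between adjacent pairs plus loop/bulge costs
    between non-adjacent paired columns.  Dangling ends are free.

    ``anchor`` = (mirna_nt, target_nt, di_off, dj_off) describes a fixed
    pair immediately before the segments (e.g. the seed junction): the
    first chosen pair then pays a stack or loop term relative to it, so
    the optimisation balances helix gains against junction costs.

    Returns ``(energy, pairs)`` where pairs is a list of (i, j) indices
    into ``mir``/``tgt``; unpairable or empty input returns (0.0, []).
    """
    n, m = len(mir), len(tgt)
    if n == 0 or m == 0:
        return 0.0, []
    G = max_bulge_nt
    NEG = None
    # best[i][j][g] = min energy of an alignment whose last paired column
    # is (i, j) having used g bulged nucleotides
    best = [[[NEG] * (G + 1) for _ in range(m)] for _ in range(n)]
    back: Dict[Tuple[int, int, int], Optional[Tuple[int, int, int]]] = {}
    order = []
    for i in range(n):
        for j in range(m):
            if pair_status(mir[i], tgt[j]) == MISMATCH:
                continue
            for g in range(G + 1):
                # start a new helix; without an anchor the leading
                # overhang is free (bulge budget untouched, so g == 0)
                e_here = 0.0 if g == 0 else None
                src = None
                if anchor is not None:
                    a_m, a_t, di_off, dj_off = anchor
                    di, dj = i + di_off, j + dj_off
                    used = abs(di - dj)
                    if used == g:
                        if di == 0 and dj == 0:
                            start_cost = params.stack(a_m, a_t,
                                                      mir[i], tgt[j])
                        else:
                            start_cost = params.loop_cost(di, dj)
                        e_here = start_cost
                        src = None
                    else:
                        e_here = None
                for pi in range(i):
                    for pj in range(j):
                        di, dj = i - pi - 1, j - pj - 1
                        used = abs(di - dj)
                        gp = g - used
                        if gp < 0 or best[pi][pj][gp] is NEG:
                            continue
                        if di == 0 and dj == 0:
                            cost = params.stack(mir[pi], tgt[pj],
                                                mir[i], tgt[j])
                        else:
                            cost = params.loop_cost(di, dj)
                        cand = best[pi][pj][gp] + cost
                        if e_here is None or cand < e_here - 1e-12:
                            e_here = cand
                            src = (pi, pj, gp)
                if e_here is not None:
                    best[i][j][g] = e_here
                    back[(i, j, g)] = src
                    order.append((i, j, g))
    # trailing overhang free: answer is min over all end states (or 0)
    best_e, best_state = 0.0, None
    for (i, j, g) in order:
        e = best[i][j][g]
        if e < best_e - 1e-12:
            best_e, best_state = e, (i, j, g)
    pairs: List[Tuple[int, int]] = []
    state = best_state
    while state is not None:
        i, j, g = state
        pairs.append((i, j))
        state = back.get((i, j, g))
    pairs.reverse()
    return best_e, pairs


def _seed_energy(mirna: MirnaSeq, utr: UtrSeq, site: CandidateSite,
                 params: EnergyParams) -> Tuple[float, List[Tuple[int, int]]]:
    """Energy of the filter-fixed seed alignment + its (p, utr) pairs."""
    pairs: List[Tuple[int, int]] = []  # (p index 1-based, utr index)
    if not site.seed_gap:
        # statuses index miRNA positions; GAP marks a bulged miRNA nt
        u = site.end - 1
        for p, col in enumerate(site.seed_statuses, start=1):
            if col in (WC, GU):
                pairs.append((p, u))
            if col != GAP:
                u -= 1  # a miRNA bulge consumes no UTR nucleotide
    else:
        # site-side bulge: 9 UTR nt carry 8 statuses; locate the bulged
        # nucleotide by re-deriving which removal reproduces the statuses
        rev = utr.seq[site.start:site.end][::-1]  # rev[k] ~ candidate q_{k+1}
        for g in range(1, len(rev) - 1):
            idx = [x for x in range(len(rev)) if x != g]
            if all(
                pair_status(mirna.seq[i], rev[idx[i]]) == site.seed_statuses[i]
                for i in range(len(site.seed_statuses))
            ):
                for i, s in enumerate(site.seed_statuses):
                    if s in (WC, GU):
                        pairs.append((i + 1, site.end - 1 - idx[i]))
                break
    # energy over consecutive paired columns
    e = 0.0
    for (p1, u1), (p2, u2) in zip(pairs, pairs[1:]):
        di = p2 - p1 - 1
        dj = u1 - u2 - 1
        if di == 0 and dj == 0:
            e += params.stack(mirna.seq[p1 - 1], utr.seq[u1],
                              mirna.seq[p2 - 1], utr.seq[u2])
        else:
            e += params.loop_cost(di, dj)
    return e, pairs


def fold_duplex(mirna: MirnaSeq, utr: UtrSeq, site: CandidateSite,
                params: EnergyParams = DEFAULT_PARAMS,
                context_ext: int = 18, max_bulge_nt: int = 4
                ) -> DuplexStructure:
    """Fold the miRNA:site hybrid with the seed pairing held fixed.

    Only the first 20 miRNA nucleotides take part.  The 3' binding
    region (p9..p20) is aligned against the UTR stretch immediately 5'
    of the seed interval (up to ``context_ext`` nt).
    """
    site.validate_against(utr)
    if site.end - site.start < 6:
        raise DegenerateInputError("site shorter than 6 nt")

    L = min(mirna.M, 20)
    e_seed, seed_pairs = _seed_energy(mirna, utr, site, params)

    status = [MISMATCH] * L
    seed_len = len(site.seed_statuses)
    for i in range(min(seed_len, L, 9)):
        status[i] = site.seed_statuses[i]

    # site-side bulges per region
    bulges = {"seed": [0, 0], "three_prime": [0, 0], "total": [0, 0]}
    if site.seed_gap:
        bulges["seed"][0] += 1
        bulges["seed"][1] += 1

    # 3' region alignment: miRNA p9.. (or p10 when a rule-5 miRNA bulge
    # consumed p9) against the UTR 5' of the seed interval, both walking
    # away from the seed junction
    p_start = seed_len  # 0-based miRNA index of first 3'-region position
    mir3 = mirna.seq[p_start:L]
    ctx_lo = max(0, site.start - context_ext)
    tgt3 = utr.seq[ctx_lo:site.start][::-1]  # 3'->5' walk from the junction
    e_three, pairs3 = 0.0, []
    anchor = None
    if seed_pairs:
        # anchor the 3' optimisation on the 5'-most seed pair so the
        # junction loop/stack cost is part of the minimisation
        p_anchor, u_anchor = max(seed_pairs)
        anchor = (mirna.seq[p_anchor - 1], utr.seq[u_anchor],
                  p_start - p_anchor, u_anchor - site.start)
    if mir3 and tgt3:
        e_three, pairs3 = duplex_align(mir3, tgt3, params, max_bulge_nt,
                                       anchor=anchor)

    all_pairs = [(p, u) for p, u in seed_pairs]
    for i, j in pairs3:
        p = p_start + i + 1  # back to 1-based miRNA position
        u = site.start - 1 - j
        all_pairs.append((p, u))
        status[p - 1] = pair_status(mirna.seq[p - 1], utr.seq[u])

    # 3'-region statuses: positions between paired ones are mismatches by
    # default; miRNA nucleotides skipped between pairs closer than the
    # UTR-side distance are bulged (gap status)
    prev = None
    for i, j in pairs3:
        if prev is not None:
            di = i - prev[0] - 1
            dj = j - prev[1] - 1
            if di > dj:  # miRNA-side bulge: mark excess positions as GAP
                for k in range(prev[0] + 1, i):
                    if k - prev[0] > dj:
                        status[p_start + k] = GAP
            if dj > di:  # UTR-side bulge
                bulges["three_prime"][0] += 1
                bulges["three_prime"][1] += dj - di
        prev = (i, j)

    for region in ("seed", "three_prime"):
        bulges["total"][0] += bulges[region][0]
        bulges["total"][1] += bulges[region][1]

    # the junction term lives inside the anchored 3' optimisation
    e_total = e_seed + e_three

    # junction bulge accounting (site-side excess at the anchor)
    if anchor is not None and pairs3:
        di_j = pairs3[0][0] + anchor[2]
        dj_j = pairs3[0][1] + anchor[3]
        if dj_j > di_j:
            bulges["three_prime"][0] += 1
            bulges["three_prime"][1] += dj_j - di_j
            bulges["total"][0] += 1
            bulges["total"][1] += dj_j - di_j

    dimers = tuple(
        4 * _NT_INDEX[mirna.seq[i]] + _NT_INDEX[mirna.seq[i + 1]] + 1
        for i in range(min(L, 20) - 1)
    )

    # q_n pairs p8; derive from the actual seed pairing when possible
    n = site.end - site.start
    for p, u in seed_pairs:
        if p == 8:
            n = site.end - u
            break
    return DuplexStructure(
        status=tuple(status),
        dimer_code=dimers,
        seed_boundary=n,
        e_seed=e_seed,
        e_three=e_three,
        e_total=e_total,
        bulges={k: tuple(v) for k, v in bulges.items()},
        pairs=tuple(sorted(all_pairs)),
    )


# ---------------------------------------------------------------------
# Intramolecular folding (accessibility backend)
# ---------------------------------------------------------------------

def _pairable(a: int, b: int) -> bool:
    return (a + b == 3) or (a + b == 5)  # A(0)+U(3), C(1)+G(2), G(2)+U(3)


def _stack_table(params: EnergyParams) -> np.ndarray:
    nts = "ACGU"
    t = np.zeros((4, 4, 4, 4))
    for a in range(4):
        for b in range(4):
            for c in range(4):
                for d in range(4):
                    t[a, b, c, d] = params.stack(nts[a], nts[b], nts[c], nts[d])
    return t


def _mfe_python(enc: np.ndarray, blocked: np.ndarray, stacks: np.ndarray) -> float:
    """Stack-only MFE of one strand; O(n^3) Zuker-style recursion.

    V[i,j]: min energy with (i,j) paired; W[i,j]: min over substructures.
    Hairpin loops >= 3 nt; blocked positions may not pair.
    """
    n = len(enc)
    INF = 1e9
    V = np.full((n, n), INF)
    W = np.zeros((n, n))
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            if (not blocked[i] and not blocked[j]
                    and _pairable(int(enc[i]), int(enc[j]))):
                v = W[i + 1, j - 1] if j - 1 > i + 1 else 0.0
                if V[i + 1, j - 1] < INF / 2:
                    v = min(v, stacks[enc[i], enc[j], enc[i + 1], enc[j - 1]]
                            + V[i + 1, j - 1])
                V[i, j] = v
            w = min(W[i + 1, j], W[i, j - 1])
            for k in range(i + 4, j + 1):
                if V[i, k] < INF / 2:
                    rest = W[k + 1, j] if k + 1 <= j else 0.0
                    w = min(w, V[i, k] + rest)
            W[i, j] = w
    return float(W[0, n - 1]) if n > 1 else 0.0


try:  # optional numba acceleration; identical semantics
    from numba import njit

    _pairable_jit = njit(cache=False)(lambda a, b: (a + b == 3) or (a + b == 5))

    @njit(cache=False)
    def _mfe_numba(enc, blocked, stacks):  # pragma: no cover - mirrors python
        n = len(enc)
        INF = 1e9
        V = np.full((n, n), INF)
        W = np.zeros((n, n))
        for span in range(4, n):
            for i in range(0, n - span):
                j = i + span
                a, b = enc[i], enc[j]
                if (not blocked[i]) and (not blocked[j]) and (
                        a + b == 3 or a + b == 5):
                    v = W[i + 1, j - 1] if j - 1 > i + 1 else 0.0
                    if V[i + 1, j - 1] < INF / 2:
                        alt = stacks[enc[i], enc[j], enc[i + 1], enc[j - 1]] \
                            + V[i + 1, j - 1]
                        if alt < v:
                            v = alt
                    V[i, j] = v
                w = W[i + 1, j]
                if W[i, j - 1] < w:
                    w = W[i, j - 1]
                for k in range(i + 4, j + 1):
                    if V[i, k] < INF / 2:
                        rest = W[k + 1, j] if k + 1 <= j else 0.0
                        if V[i, k] + rest < w:
                            w = V[i, k] + rest
                W[i, j] = w
        return W[0, n - 1] if n > 1 else 0.0

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def mfe_fold(seq: str, blocked: Optional[Tuple[int, int]] = None,
             params: EnergyParams = DEFAULT_PARAMS,
             backend: str = "builtin") -> float:
    """Stack-only intramolecular MFE; ``blocked`` forces [lo, hi) unpaired."""
    if backend == "external":
        try:  # ViennaRNA, when importable, produces the same contract
            import RNA  # type: ignore

            fc = RNA.fold_compound(seq)
            if blocked:
                for i in range(blocked[0], blocked[1]):
                    fc.hc_add_up(i + 1)
            _, e = fc.mfe()
            return float(e)
        except ImportError:
            logger.warning("external folding backend unavailable; "
                           "falling back to builtin")
    enc = np.array([_NT_INDEX[c] for c in seq], dtype=np.int64)
    mask = np.zeros(len(seq), dtype=np.bool_)
    if blocked:
        mask[blocked[0]:blocked[1]] = True
    stacks = _stack_table(params)
    if _HAVE_NUMBA and len(seq) > 30:
        return float(_mfe_numba(enc, mask, stacks))
    return _mfe_python(enc, mask, stacks)


@dataclass
class AccessibilityResult:
    ddg: float
    window: Tuple[int, int]
    opening_cost: float = 0.0
    heuristic: bool = False


def accessibility(utr: UtrSeq, site: CandidateSite, duplex_energy: float,
                  window_pad: int = 70, params: EnergyParams = DEFAULT_PARAMS,
                  backend: str = "builtin") -> AccessibilityResult:
    """PITA-style openness of the site within its local UTR fold.

    Opening cost = MFE(window, site forced unpaired) - MFE(window) >= 0;
    ddg = duplex energy + opening cost (less favourable when the site is
    sequestered in local structure).
    """
    site.validate_against(utr)
    lo = max(0, site.start - window_pad)
    hi = min(len(utr), site.end + window_pad)
    window = utr.seq[lo:hi]
    rel = (site.start - lo, site.end - lo)
    try:
        e_free = mfe_fold(window, None, params, backend)
        e_open = mfe_fold(window, rel, params, backend)
        cost = max(0.0, e_open - e_free)
        return AccessibilityResult(ddg=duplex_energy + cost, window=(lo, hi),
                                   opening_cost=cost)
    except Exception as exc:  # pragma: no cover - defensive fallback
        logger.warning("folding backend failed (%s); heuristic fallback", exc)
        gc = sum(1 for c in window if c in "GC") / max(1, len(window))
        return AccessibilityResult(ddg=duplex_energy + 5.0 * gc,
                                   window=(lo, hi), opening_cost=5.0 * gc,
                                   heuristic=True)
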