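"""Site (113) and UTR (30) feature extraction.

Site feature groups, in fixed order: perfect seed match (6), pair-wise
binding structure (39), regional binding structure (18), conservation
(3), energy (4), seed context (40), site location (3).

UTR feature groups: UTR length (1), site density (4), binding-site
score aggregation (25).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .duplexer import AccessibilityResult, DuplexStructure
from .seqdata import GAP, GU, WC, CandidateSite, UtrSeq

_NT_CODE = {"A": 1, "C": 2, "G": 3, "U": 4}
_NTS = "ACGU"
_DIMERS = [a + b for a in _NTS for b in _NTS]

#: sentinel for "top score" features over empty categories
NO_SCORE = -1000.0

SEED_TYPES = ("6mer", "7mer_a1", "7mer_m1", "7mer_m8", "8mer_a1", "8mer_m8")
#: Table-3 style aliases (8mer_m1 is the historical name of 8mer_m8)
SEED_TYPE_ALIASES = {"8mer_m8": "8mer_m1"}
UTR_SCORE_CATEGORIES = SEED_TYPES + ("no_perfect_seed",)


def site_feature_names() -> List[str]:
    names = [f"seed_{t}" for t in SEED_TYPES]
    names += [f"status_p{m}" for m in range(1, 21)]
    names += [f"dimer_p{m}" for m in range(1, 20)]
    for region in ("seed", "three", "total"):
        names += [f"n_wc_{region}", f"n_gu_{region}", f"n_mismatch_{region}",
                  f"n_gap_{region}", f"bulge_count_{region}",
                  f"bulged_nt_{region}"]
    names += ["cons_seed", "cons_5p_context", "cons_3p_context"]
    names += ["e_seed", "e_three", "e_total", "ddg"]
    names += [f"comp_{n}" for n in _NTS]
    names += [f"comp_{d}" for d in _DIMERS]
    names += [f"ctx_type_r{j}" for j in range(1, 11)]
    names += [f"ctx_type_q{-j}" for j in range(0, 10)]
    names += ["dist_to_stop", "dist_to_nearest_end", "dist_ratio"]
    assert len(names) == 113
    return names


def utr_feature_names() -> List[str]:
    names = ["utr_length",
             "potential_density", "positive_density",
             "max_potential_100nt", "max_positive_100nt"]
    for cat in UTR_SCORE_CATEGORIES:
        alias = SEED_TYPE_ALIASES.get(cat, cat)
        names += [f"n_potential_{alias}", f"n_positive_{alias}",
                  f"top_score_{alias}"]
    names += ["top_score", "total_positive_score", "n_positive", "n_potential"]
    assert len(names) == 30
    return names


SITE_FEATURE_NAMES = site_feature_names()
UTR_FEATURE_NAMES = utr_feature_names()

SITE_GROUP_SIZES = {"seed_match": 6, "pairwise": 39, "regional": 18,
                    "conservation": 3, "energy": 4, "context": 40,
                    "location": 3}
UTR_GROUP_SIZES = {"utr_length": 1, "density": 4, "site_score": 25}


def schema_hash() -> str:
    """Stable hash of the canonical feature-name schema."""
    blob = "\n".join(SITE_FEATURE_NAMES + ["--"] + UTR_FEATURE_NAMES)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SiteFeatureVector:
    values: "np.ndarray"
    names: Tuple[str, ...] = tuple(SITE_FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != 113:
            raise ValueError(f"site vector length {len(self.values)} != 113")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class UtrFeatureVector:
    values: "np.ndarray"
    names: Tuple[str, ...] = tuple(UTR_FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != 30:
            raise ValueError(f"UTR vector length {len(self.values)} != 30")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


# ---------------------------------------------------------------------
# Site feature groups
# ---------------------------------------------------------------------

def seed_match_types(site: CandidateSite, utr: UtrSeq) -> Dict[str, bool]:
    """Which of the six perfect seed-match types the site exhibits.

    Evaluated on the filter's seed statuses: positions p_a..p_b must all
    be W-C matched; the A1 variants additionally require the UTR
    nucleotide opposite p1 (q1) to be literally A.
    """
    st = site.seed_statuses
    if site.seed_gap or any(s == GAP for s in st):
        # a gapped seed alignment cannot be a perfect seed match
        wc = [False] * 8
    else:
        wc = [s == WC for s in st[:8]] + [False] * max(0, 8 - len(st))
    q1 = site.q_nt(utr, 1)
    q1_is_a = q1 == "A"
    return {
        "6mer": all(wc[1:7]),
        "7mer_a1": all(wc[1:7]) and q1_is_a,
        "7mer_m1": all(wc[0:7]),
        "7mer_m8": all(wc[1:8]),
        "8mer_a1": all(wc[1:8]) and q1_is_a,
        "8mer_m8": all(wc[0:8]),
    }


def seed_match_features(site: CandidateSite, utr: UtrSeq) -> List[float]:
    types = seed_match_types(site, utr)
    return [1.0 if types[t] else 0.0 for t in SEED_TYPES]


def pairwise_features(duplex: DuplexStructure,
                      dimer_mode: str = "sequence") -> List[float]:
    """20 per-position match statuses + 19 2-mer content codes.

    ``dimer_mode="sequence"`` (default) encodes the miRNA 2-mer identity
    at (p_m, p_m+1) as 1..16; ``"status"`` encodes the pair of match
    statuses instead (alternative reading of "content").
    """
    statuses = list(duplex.status[:20]) + [0] * max(0, 20 - len(duplex.status))
    if dimer_mode == "sequence":
        dimers = list(duplex.dimer_code[:19])
        dimers += [0] * max(0, 19 - len(dimers))
    elif dimer_mode == "status":
        dimers = [4 * (statuses[m] - 1) + statuses[m + 1]
                  if statuses[m] and statuses[m + 1] else 0
                  for m in range(19)]
    else:
        raise ValueError(f"dimer_mode {dimer_mode!r}")
    return [float(v) for v in statuses + dimers]


def regional_features(duplex: DuplexStructure) -> List[float]:
    out: List[float] = []
    for region, bulge_key in (("seed", "seed"), ("three", "three_prime"),
                              ("total", "total")):
        c = duplex.counts(region)
        b = duplex.bulges[bulge_key]
        out += [c["wc"], c["gu"], c["mismatch"], c["gap"], b[0], b[1]]
    return [float(v) for v in out]


def _region_cons_mean(utr: UtrSeq, indices: Sequence[int]) -> float:
    """Mean conservation over UTR indices; absent positions count as 0."""
    if not indices:
        return 0.0
    return float(sum(utr.cons_at(i) for i in indices) / len(indices))


def conservation_features(site: CandidateSite, utr: UtrSeq) -> List[float]:
    seed_idx = list(range(site.start, site.end))
    ctx5 = [site.start - j for j in range(1, 11)]       # r1..r10
    ctx3 = [site.end + j for j in range(0, 10)]         # q0..q-9
    return [_region_cons_mean(utr, seed_idx),
            _region_cons_mean(utr, ctx5),
            _region_cons_mean(utr, ctx3)]


def energy_features(duplex: DuplexStructure,
                    access: AccessibilityResult) -> List[float]:
    return [duplex.e_seed, duplex.e_three, duplex.e_total, access.ddg]


def _context_nts(site: CandidateSite, utr: UtrSeq,
                 literal_3p: bool = False) -> Tuple[List[Optional[str]],
                                                    List[Optional[str]]]:
    """The 5' context (r1..r10) and 3' context (q0..q-9) nucleotides.

    Off-UTR positions come back as None.  ``literal_3p`` restores the
    9-nt reading {q0..q-8} for the 3' region.
    """
    ctx5 = [site.r_nt(utr, j) for j in range(1, 11)]
    span3 = 9 if literal_3p else 10
    ctx3 = [site.q_nt(utr, -j) for j in range(0, span3)]
    return ctx5, ctx3


def context_features(site: CandidateSite, utr: UtrSeq,
                     literal_3p: bool = False,
                     frequencies: bool = False) -> List[float]:
    """40 seed-context features: 20 composition + 20 positional.

    Composition = 4 single-nucleotide counts + 16 dinucleotide counts
    pooled over the two context regions (dinucleotides counted within
    each region; absent positions are excluded).  Positional = the
    nucleotide type code (1..4; 0 when absent) at each of r1..r10 and
    q0..q-9.
    """
    ctx5, ctx3 = _context_nts(site, utr, literal_3p)
    mono = {n: 0 for n in _NTS}
    di = {d: 0 for d in _DIMERS}
    n_mono = n_di = 0
    for region in (ctx5, ctx3):
        for nt in region:
            if nt is not None:
                mono[nt] += 1
                n_mono += 1
        for a, b in zip(region, region[1:]):
            if a is not None and b is not None:
                di[a + b] += 1
                n_di += 1
    comp = [mono[n] for n in _NTS] + [di[d] for d in _DIMERS]
    if frequencies:
        comp = [c / n_mono if n_mono else 0.0 for c in comp[:4]] + \
               [c / n_di if n_di else 0.0 for c in comp[4:]]
    ctx3_padded = list(ctx3) + [None] * (10 - len(ctx3))
    positional = [float(_NT_CODE.get(nt, 0)) if nt else 0.0
                  for nt in list(ctx5) + ctx3_padded]
    return [float(v) for v in comp] + positional


def location_features(site: CandidateSite, utr: UtrSeq) -> List[float]:
    """Distance to the stop codon (UTR 5' end), to the nearest UTR end,
    and that distance as a fraction of the UTR length."""
    dist_stop = site.start
    dist_end3 = len(utr) - site.end
    nearest = min(dist_stop, dist_end3)
    return [float(dist_stop), float(nearest),
            nearest / len(utr) if len(utr) else 0.0]


def extract_site_features(site: CandidateSite, utr: UtrSeq,
                          duplex: DuplexStructure,
                          access: AccessibilityResult,
                          **context_kwargs) -> SiteFeatureVector:
    values = (seed_match_features(site, utr)
              + pairwise_features(duplex)
              + regional_features(duplex)
              + conservation_features(site, utr)
              + energy_features(duplex, access)
              + context_features(site, utr, **context_kwargs)
              + location_features(site, utr))
    return SiteFeatureVector(np.array(values, dtype=float))


# ---------------------------------------------------------------------
# UTR features
# ---------------------------------------------------------------------

def max_sites_in_window(starts: Sequence[int], utr_len: int,
                        window: int = 100) -> int:
    """Maximum number of sites whose start falls in any ``window``-nt
    window of the UTR."""
    if not starts:
        return 0
    ss = sorted(starts)
    best = lo = 0
    for hi in range(len(ss)):  # window anchored at each site start
        while ss[hi] - ss[lo] >= window:
            lo += 1
        best = max(best, hi - lo + 1)
    return best


def extract_utr_features(utr: UtrSeq, sites: Sequence[CandidateSite],
                         site_scores: Sequence[float],
                         window: int = 100) -> UtrFeatureVector:
    """Aggregate candidate sites and their classifier scores per UTR.

    A site is *positive* when its site-stage decision score > 0.  Each
    site contributes to every perfect-seed category it exhibits, or to
    ``no_perfect_seed`` when it exhibits none.
    """
    if len(sites) != len(site_scores):
        raise ValueError("sites and site_scores length mismatch")
    L = len(utr)
    scores = np.asarray(site_scores, dtype=float)
    positive = scores > 0.0

    cats: Dict[str, List[float]] = {c: [] for c in UTR_SCORE_CATEGORIES}
    cat_pos: Dict[str, int] = {c: 0 for c in UTR_SCORE_CATEGORIES}
    for s, sc, pos in zip(sites, scores, positive):
        types = seed_match_types(s, utr)
        hit = [t for t in SEED_TYPES if types[t]]
        if not hit:
            hit = ["no_perfect_seed"]
        for t in hit:
            cats[t].append(float(sc))
            if pos:
                cat_pos[t] += 1

    starts = [s.start for s in sites]
    pos_starts = [s.start for s, p in zip(sites, positive) if p]

    values = [float(L),
              len(sites) / L if L else 0.0,
              int(positive.sum()) / L if L else 0.0,
              float(max_sites_in_window(starts, L, window)),
              float(max_sites_in_window(pos_starts, L, window))]
    for cat in UTR_SCORE_CATEGORIES:
        cat_scores = cats[cat]
        values += [float(len(cat_scores)), float(cat_pos[cat]),
                   max(cat_scores) if cat_scores else NO_SCORE]
    values += [float(scores.max()) if len(scores) else NO_SCORE,
               float(scores[positive].sum()) if len(scores) else 0.0,
               float(positive.sum()), float(len(sites))]
    return UtrFeatureVector(np.array(values, dtype=float))


# ---------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------

def to_frame(vectors, kind: str = "site") -> pd.DataFrame:
    names = SITE_FEATURE_NAMES if kind == "site" else UTR_FEATURE_NAMES
    return pd.DataFrame([v.values for v in vectors], columns=names)


def write_matrix(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema={schema_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)
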