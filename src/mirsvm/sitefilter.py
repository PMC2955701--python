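"""Seed-match site filter.

Scans a 3'UTR with a miRNA and emits candidate sites satisfying any of
five seed-match rules over the seed window p1..p8.  The filter is built
for sensitivity: downstream classifiers, not the filter, are responsible
for rejecting false positives.

Rule semantics ("more than k" == ">= k+1"):

1. a run of >= 5 continuous W-C matches;
2. a run of >= 6 continuous matches (W-C or G:U) and a run of >= 3
   continuous W-C matches;
3. >= 7 matches in total and a run of >= 4 continuous W-C matches, no gap;
4. p2, p3 and p4 each W-C matched, >= 4 W-C matches and >= 5 matches in
   total, no gap;
5. >= 6 matches and >= 6 W-C matches, at most one single-nucleotide gap
   on either strand (``rule5_strict=False`` relaxes to >= 5 W-C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Set, Tuple

from .seqdata import GAP, GU, MISMATCH, WC, CandidateSite, MirnaSeq, UtrSeq

logger = logging.getLogger(__name__)

SEED_LEN = 8

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}


def pair_status(a: str, b: str) -> int:
    """Match status of a miRNA/UTR nucleotide pair (no gap case)."""
    if (a, b) in _WC_PAIRS:
        return WC
    if (a, b) in _GU_PAIRS:
        return GU
    return MISMATCH


@dataclass(frozen=True)
class SeedAlignment:
    """One alignment of the miRNA seed against a UTR window.

    ``path`` is the alignment column sequence 5'->3' on the miRNA:
    status codes per column, where GAP columns consume one nucleotide of
    exactly one strand.  ``statuses`` indexes miRNA seed positions only
    (a site-side bulge does not consume a miRNA position but is recorded
    in ``site_gap``).
    """

    statuses: Tuple[int, ...]  # per miRNA position p1..p8 (p9 if extended)
    utr_span: int              # UTR nucleotides consumed
    gap_count: int             # bulged nucleotides (either strand)
    site_gap: bool             # the gap, if any, is on the UTR side
    path: Tuple[int, ...]      # column statuses incl. site-side GAP columns

    @property
    def n_wc(self) -> int:
        return sum(1 for s in self.statuses if s == WC)

    @property
    def n_match(self) -> int:
        return sum(1 for s in self.statuses if s in (WC, GU))

    def _max_run(self, ok) -> int:
        best = run = 0
        for s in self.path:
            if ok(s):
                run += 1
                best = max(best, run)
            else:
                run = 0
        return best

    @property
    def max_wc_run(self) -> int:
        return self._max_run(lambda s: s == WC)

    @property
    def max_match_run(self) -> int:
        return self._max_run(lambda s: s in (WC, GU))


def align_seed_ungapped(mirna_seed: str, window: str) -> SeedAlignment:
    """Ungapped antiparallel alignment: p_i pairs window[-i]."""
    n = len(mirna_seed)
    assert len(window) == n
    statuses = tuple(
        pair_status(mirna_seed[i], window[n - 1 - i]) for i in range(n)
    )
    return SeedAlignment(statuses=statuses, utr_span=n, gap_count=0,
                         site_gap=False, path=statuses)


def _align_seed_mirna_gap(mirna_seed9: str, window: str, g: int) -> SeedAlignment:
    """miRNA position ``g`` (0-based into p1..p9) bulged; 8 pairs remain."""
    kept = [mirna_seed9[i] for i in range(9) if i != g]
    statuses9 = []
    path = []
    k = 0
    for i in range(9):
        if i == g:
            statuses9.append(GAP)
            path.append(GAP)
        else:
            s = pair_status(kept[k], window[len(window) - 1 - k])
            statuses9.append(s)
            path.append(s)
            k += 1
    return SeedAlignment(statuses=tuple(statuses9), utr_span=8, gap_count=1,
                         site_gap=False, path=tuple(path))


def _align_seed_site_gap(mirna_seed: str, window9: str, g: int) -> SeedAlignment:
    """UTR nucleotide at antiparallel column ``g`` bulged out of a 9-nt window."""
    rev = window9[::-1]  # rev[i] pairs p_{i+1} once the bulge is removed
    kept = [rev[i] for i in range(9) if i != g]
    statuses = tuple(pair_status(mirna_seed[i], kept[i]) for i in range(8))
    path = []
    k = 0
    for i in range(9):
        if i == g:
            path.append(GAP)
        else:
            path.append(statuses[k])
            k += 1
    return SeedAlignment(statuses=statuses, utr_span=9, gap_count=1,
                         site_gap=True, path=tuple(path))


def rule_check(align: SeedAlignment, rule5_strict: bool = True) -> Set[int]:
    """Rule ids (subset of {1..5}) satisfied by one seed alignment."""
    rules: Set[int] = set()
    wc_run = align.max_wc_run
    match_run = align.max_match_run
    n_wc = align.n_wc
    n_match = align.n_match
    gapless = align.gap_count == 0

    if wc_run >= 5:
        rules.add(1)
    if match_run >= 6 and wc_run >= 3:
        rules.add(2)
    if gapless and n_match >= 7 and wc_run >= 4:
        rules.add(3)
    if (gapless and len(align.statuses) >= 4
            and all(align.statuses[i] == WC for i in (1, 2, 3))
            and n_wc >= 4 and n_match >= 5):
        rules.add(4)
    wc_floor = 6 if rule5_strict else 5
    if align.gap_count <= 1 and n_match >= 6 and n_wc >= wc_floor:
        rules.add(5)
    return rules


def _window_alignments(mirna: MirnaSeq, utr: UtrSeq, start: int,
                       allow_gaps: bool) -> List[SeedAlignment]:
    """All seed alignments anchored at UTR offset ``start``.

    The ungapped alignment pairs p1..p8 with utr[start:start+8]
    (antiparallel, q1 == utr[start+7]).  Gapped variants serve rule 5.
    """
    seq = utr.seq
    out = []
    if start + 8 <= len(seq):
        out.append(align_seed_ungapped(mirna.seq[:8], seq[start:start + 8]))
    if allow_gaps:
        if start + 8 <= len(seq) and mirna.M >= 9:
            for g in range(1, 8):  # interior miRNA bulge
                out.append(_align_seed_mirna_gap(mirna.seq[:9],
                                                 seq[start:start + 8], g))
        if start + 9 <= len(seq):
            for g in range(1, 8):  # interior UTR bulge
                out.append(_align_seed_site_gap(mirna.seq[:8],
                                                seq[start:start + 9], g))
    return out


def _gapped_plausible(mirna: MirnaSeq, utr: UtrSeq, start: int,
                      rule5_strict: bool) -> bool:
    """Cheap upper bound: a 1-gap alignment mixes a prefix of one
    register with a suffix of the +/-1-shifted register, so its W-C
    count cannot exceed the summed W-C counts of the two registers."""
    need = 6 if rule5_strict else 5
    seq = utr.seq

    def wc_count(win: str, mseq: str) -> int:
        n = min(len(win), len(mseq))
        return sum(1 for i in range(n)
                   if (mseq[i], win[n - 1 - i]) in _WC_PAIRS)

    w0 = wc_count(seq[start:start + 8], mirna.seq[:8])
    # +1-shifted registers reachable through a single bulge
    w_utr = wc_count(seq[start + 1:start + 9], mirna.seq[:8]) \
        if start + 9 <= len(seq) else 0
    w_mir = wc_count(seq[start:start + 8], mirna.seq[1:9]) \
        if mirna.M >= 9 else 0
    return w0 + max(w_utr, w_mir) >= need


def scan_sites(mirna: MirnaSeq, utr: UtrSeq, rule5_strict: bool = True,
               merge_overlap: float = 0.5) -> List[CandidateSite]:
    """Scan ``utr`` for candidate sites of ``mirna``.

    Each UTR offset whose best seed alignment satisfies >= 1 rule yields
    one candidate (lowest satisfied rule id recorded).  Gapped alignments
    are tried for rule 5 only.  Candidates whose seed intervals overlap
    by more than ``merge_overlap`` of the shorter interval are merged,
    keeping the one with more W-C matches.
    """
    candidates: List[CandidateSite] = []
    for start in range(0, len(utr.seq) - SEED_LEN + 1):
        best: Optional[Tuple[SeedAlignment, int]] = None
        ungapped = align_seed_ungapped(mirna.seq[:8],
                                       utr.seq[start:start + 8])
        rules = rule_check(ungapped, rule5_strict)
        if rules:
            best = (ungapped, min(rules))
        elif _gapped_plausible(mirna, utr, start, rule5_strict):
            # rule 5 is the only gap-tolerant rule
            for aln in _window_alignments(mirna, utr, start, allow_gaps=True):
                if aln.gap_count == 0:
                    continue
                if 5 in rule_check(aln, rule5_strict):
                    if best is None or aln.n_wc > best[0].n_wc:
                        best = (aln, 5)
        if best is not None:
            aln, rid = best
            candidates.append(CandidateSite(
                utr_id=utr.id, mirna_id=mirna.id,
                start=start, end=start + aln.utr_span,
                rule_id=rid, seed_statuses=aln.statuses,
                n_wc=aln.n_wc, n_match=aln.n_match,
                seed_gap=aln.site_gap,
            ))

    def _gapped(site: CandidateSite) -> bool:
        return site.seed_gap or any(s == GAP for s in site.seed_statuses)

    def _better(a: CandidateSite, b: CandidateSite) -> CandidateSite:
        # more W-C wins; ties prefer ungapped, then the lower rule id,
        # then the earlier start
        ka = (-a.n_wc, _gapped(a), a.rule_id, a.start)
        kb = (-b.n_wc, _gapped(b), b.rule_id, b.start)
        return a if ka <= kb else b

    merged: List[CandidateSite] = []
    for cand in candidates:  # already sorted by start
        if merged:
            prev = merged[-1]
            ov = min(prev.end, cand.end) - max(prev.start, cand.start)
            shorter = min(prev.end - prev.start, cand.end - cand.start)
            duplicate = ov > merge_overlap * shorter
            if not duplicate and ov > 0 and _gapped(cand) != _gapped(prev):
                # a gapped near-duplicate of a stronger ungapped site
                # (or vice versa) adds no independent locus
                gapped, plain = (cand, prev) if _gapped(cand) else (prev, cand)
                duplicate = gapped.n_wc <= plain.n_wc
            if duplicate:
                keep = _better(prev, cand)
                if keep is not prev:
                    logger.debug("merge: %s [%d,%d) replaces [%d,%d)",
                                 utr.id, cand.start, cand.end,
                                 prev.start, prev.end)
                merged[-1] = keep
                continue
        merged.append(cand)
    return merged


def registered_rules() -> Tuple[int, ...]:
    """Ids of the seed-match rules the filter applies."""
    return (1, 2, 3, 4, 5)
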