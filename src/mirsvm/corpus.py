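"""Training-corpus construction and synthetic fixture generation.

Positives come from a miRecords-like TSV (site sequences located in
their UTRs by exact match); negatives are derived from miRNA
over-expression differential-expression tables by keeping confidently
up-regulated genes.  The synthetic generator plants rule-satisfying
sites with elevated conservation and AU-rich context into random UTRs
and guarantees, by construction, that the site filter recovers every
planted locus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import sitefilter
from .seqdata import (CandidateSite, LabeledPair, MirnaSeq, UtrSeq,
                      write_conservation, write_fasta)

logger = logging.getLogger(__name__)

_NTS = "ACGU"
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def revcomp_rna(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------
# Positives
# ---------------------------------------------------------------------

def build_positives(records: pd.DataFrame, utrs: Sequence[UtrSeq],
                    mirnas: Sequence[MirnaSeq]) -> List[LabeledPair]:
    """Site- and UTR-level positive pairs from miRecords-like rows.

    Site sequences are located in their UTR by exact substring match;
    ambiguous (multi-hit) or absent sites are dropped with a log line.
    Duplicate (mirna, utr, interval) records collapse to one.  Rows
    without site information become UTR-level positives.
    """
    utr_by_id = {u.id: u for u in utrs}
    mirna_ids = {m.id for m in mirnas}
    pairs: List[LabeledPair] = []
    seen_sites = set()
    seen_utr = set()
    for _, row in records.iterrows():
        mid, uid = row["mirna_id"], row["utr_id"]
        if mid not in mirna_ids or uid not in utr_by_id:
            logger.warning("skipping pair (%s, %s): unmapped id", mid, uid)
            continue
        utr = utr_by_id[uid]
        site_seq = row.get("site_seq")
        if isinstance(site_seq, str) and site_seq:
            site_seq = site_seq.upper().replace("T", "U")
            hits = []
            pos = utr.seq.find(site_seq)
            while pos != -1:
                hits.append(pos)
                pos = utr.seq.find(site_seq, pos + 1)
            if len(hits) != 1:
                logger.warning("dropping site for (%s, %s): %d hits",
                               mid, uid, len(hits))
                continue
            start = hits[0]
            key = (mid, uid, start, start + len(site_seq))
            if key in seen_sites:
                continue  # only one record retained per shared region
            seen_sites.add(key)
            site = CandidateSite(utr_id=uid, mirna_id=mid, start=start,
                                 end=start + len(site_seq), rule_id=1)
            site.validate_against(utr)
            pairs.append(LabeledPair(mid, uid, "positive", "site", site))
            if (mid, uid) not in seen_utr:
                seen_utr.add((mid, uid))
                pairs.append(LabeledPair(mid, uid, "positive", "utr"))
        else:
            if (mid, uid) not in seen_utr:
                seen_utr.add((mid, uid))
                pairs.append(LabeledPair(mid, uid, "positive", "utr"))
    logger.info("built %d positive pairs", len(pairs))
    return pairs


# ---------------------------------------------------------------------
# Negatives
# ---------------------------------------------------------------------

@dataclass
class NegativeCriteria:
    """Thresholds for calling confident non-targets from over-expression
    data (up-regulated genes cannot be targets)."""

    p_value_max: float = 0.01
    log_fc_min: float = 0.585  # fold change >= 1.5
    consistency_min: float = 2 / 3

    def __post_init__(self) -> None:
        if not 0 < self.p_value_max <= 1:
            raise ValueError("p_value_max out of (0, 1]")
        if not 0 <= self.consistency_min <= 1:
            raise ValueError("consistency_min out of [0, 1]")


def build_negatives(expression: pd.DataFrame, criteria: NegativeCriteria,
                    mirna: MirnaSeq, utrs: Sequence[UtrSeq],
                    rule5_strict: bool = True) -> List[LabeledPair]:
    """UTR-level negatives from confidently up-regulated genes, plus
    their filter-derived candidate sites as site-level negatives."""
    timepoint_cols = [c for c in expression.columns if c.startswith("lfc_t")]
    utr_by_gene: Dict[str, UtrSeq] = {}
    for u in utrs:
        utr_by_gene.setdefault(u.gene, u)
        utr_by_gene.setdefault(u.id, u)
    pairs: List[LabeledPair] = []
    for _, row in expression.iterrows():
        if row["p_value"] > criteria.p_value_max:
            continue
        if row["log_fold_change"] < criteria.log_fc_min:
            continue
        if timepoint_cols:
            up = sum(1 for c in timepoint_cols if row[c] > 0)
            if up / len(timepoint_cols) < criteria.consistency_min:
                continue
        utr = utr_by_gene.get(row["gene"])
        if utr is None:
            continue
        pairs.append(LabeledPair(mirna.id, utr.id, "negative", "utr"))
        for site in sitefilter.scan_sites(mirna, utr, rule5_strict):
            pairs.append(LabeledPair(mirna.id, utr.id, "negative", "site",
                                     site))
    if not pairs:
        logger.warning("no gene passed the negative criteria")
    logger.info("built %d negative pairs", len(pairs))
    return pairs


# ---------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    n_pos: int = 30
    n_neg: int = 30
    utr_len: int = 300
    utr_len_jitter: int = 50
    sites_per_pos: Tuple[int, ...] = (1, 2)
    rule_mix: Tuple[float, ...] = (0.55, 0.15, 0.1, 0.1, 0.1)
    cons_background: float = 0.15
    cons_site: float = 0.9
    au_context: bool = True
    three_prime_pairing: bool = True
    clean_negatives: bool = False
    max_reject_tries: int = 2000
    mirna_len: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.utr_len) < 0:
            raise ValueError("counts must be >= 0")
        if self.clean_negatives and self.utr_len > 160:
            raise ValueError(
                "clean negatives are only feasible for short UTRs "
                "(rejection sampling would not terminate)")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NTS), size=n))


def _plant_seed_segment(rng: np.random.Generator, mirna: MirnaSeq,
                        rule: int) -> str:
    """A UTR segment (5'->3') whose ungapped seed alignment satisfies
    ``rule`` by construction.

    The perfect complement of p1..p8 satisfies every rule; degradations
    target the requested rule while remaining inside its thresholds.
    """
    comp = [_COMP[c] for c in mirna.seq[:8]]  # comp[i] pairs p_{i+1}
    if rule == 1:
        pass  # perfect: >= 5 continuous W-C guaranteed
    elif rule == 2:
        # one G:U inside an 8-run of matches: turn a C (pairing G) into U
        gpos = [i for i, c in enumerate(mirna.seq[:8]) if c == "G"]
        if gpos:
            comp[gpos[0]] = "U"
    elif rule == 3:
        # 7 matches, 4+ continuous W-C: wobble one edge position
        upos = [i for i, c in enumerate(mirna.seq[:8]) if c == "U" and i >= 6]
        if upos:
            comp[upos[0]] = "G"
    elif rule == 4:
        # p2..p4 W-C, >= 4 W-C, >= 5 matches: mismatch p8, wobble p7
        comp[7] = _COMP[comp[7]]  # self-complement of complement = original
        if mirna.seq[6] == "U":
            comp[6] = "G"
    elif rule == 5:
        pass  # perfect complement satisfies the strict reading too
    # antiparallel: q1 pairs p1 and q1 is the segment's 3' end
    return "".join(reversed(comp))


def _plant_site(rng: np.random.Generator, mirna: MirnaSeq, utr_chars: List[str],
                cons: np.ndarray, pos: int, rule: int,
                spec: SyntheticSpec) -> Tuple[int, int]:
    """Write one planted site into ``utr_chars`` at ``pos``; returns the
    seed interval."""
    seg = _plant_seed_segment(rng, mirna, rule)
    utr_chars[pos:pos + 8] = list(seg)
    # favourable 3' pairing immediately 5' of the seed interval
    if spec.three_prime_pairing and mirna.M > 8:
        three = mirna.seq[8:min(mirna.M, 20)]
        comp3 = "".join(reversed([_COMP[c] for c in three]))
        lo = max(0, pos - len(comp3))
        utr_chars[lo:pos] = list(comp3[len(comp3) - (pos - lo):])
    # AU-rich 3' context downstream of the site
    if spec.au_context:
        for j in range(pos + 8, min(len(utr_chars), pos + 18)):
            utr_chars[j] = "AU"[rng.integers(0, 2)]
    lo = max(0, pos - 14)
    hi = min(len(cons), pos + 18)
    cons[lo:hi] = np.clip(
        spec.cons_site + rng.normal(0, 0.03, hi - lo), 0.0, 1.0)
    return pos, pos + 8


def generate_synthetic(spec: SyntheticSpec):
    """Generate (mirnas, utrs-with-cons, labelled pairs, manifest).

    Positives carry >= 1 planted site drawn from ``rule_mix`` with
    elevated conservation and (optionally) AU-enriched context and 3'
    pairing; every planted locus is verified against the site filter.
    Negatives are random background; with ``clean_negatives`` they are
    rejection-sampled until the filter finds no site at all.
    """
    rng = np.random.default_rng(spec.seed)
    mirna = MirnaSeq(id="syn-mir-1", seq=_random_seq(rng, spec.mirna_len))

    utrs: List[UtrSeq] = []
    pairs: List[LabeledPair] = []
    manifest = {"seed": spec.seed, "mirna": mirna.seq, "planted": {},
                "spec": asdict(spec)}

    rule_ids = np.arange(1, 6)
    for i in range(spec.n_pos):
        L = int(spec.utr_len + rng.integers(-spec.utr_len_jitter,
                                            spec.utr_len_jitter + 1))
        chars = list(_random_seq(rng, L))
        cons = np.clip(rng.normal(spec.cons_background, 0.08, L), 0.0, 1.0)
        n_sites = int(rng.choice(spec.sites_per_pos))
        loci = []
        used: List[Tuple[int, int]] = []
        for _ in range(n_sites):
            rule = int(rng.choice(rule_ids, p=np.asarray(spec.rule_mix)
                                  / np.sum(spec.rule_mix)))
            for _try in range(50):
                pos = int(rng.integers(20, L - 30))
                if all(abs(pos - a) > 40 for a, _ in used):
                    break
            else:
                continue
            lo, hi = _plant_site(rng, mirna, chars, cons, pos, rule, spec)
            used.append((lo, hi))
            loci.append({"start": lo, "end": hi, "rule": rule})
        uid = f"pos_utr_{i:04d}"
        utr = UtrSeq(id=uid, seq="".join(chars), cons=cons, has_cons=True)
        # construction guarantee: the filter recovers every planted locus
        found = sitefilter.scan_sites(mirna, utr)
        for locus in loci:
            covered = any(s.start < locus["end"] and locus["start"] < s.end
                          for s in found)
            assert covered, f"planted site not recovered in {uid}"
        utrs.append(utr)
        manifest["planted"][uid] = loci
        pairs.append(LabeledPair(mirna.id, uid, "positive", "utr"))
        for locus in loci:
            match = next(s for s in found
                         if s.start < locus["end"] and locus["start"] < s.end)
            pairs.append(LabeledPair(mirna.id, uid, "positive", "site", match))

    for i in range(spec.n_neg):
        L = int(spec.utr_len + rng.integers(-spec.utr_len_jitter,
                                            spec.utr_len_jitter + 1))
        for _try in range(spec.max_reject_tries):
            seq = _random_seq(rng, L)
            utr = UtrSeq(id=f"neg_utr_{i:04d}", seq=seq,
                         cons=np.clip(rng.normal(spec.cons_background, 0.08,
                                                 L), 0.0, 1.0),
                         has_cons=True)
            sites = sitefilter.scan_sites(mirna, utr)
            if not spec.clean_negatives or not sites:
                break
        else:
            raise RuntimeError("rejection sampling failed for clean negative")
        utrs.append(utr)
        manifest["planted"][utr.id] = []
        pairs.append(LabeledPair(mirna.id, utr.id, "negative", "utr"))
        for site in sites:
            pairs.append(LabeledPair(mirna.id, utr.id, "negative", "site",
                                     site))

    return [mirna], utrs, pairs, manifest


def write_corpus(outdir, mirnas, utrs, pairs, manifest) -> None:
    """Emit a synthetic corpus as FASTA + wiggle + labels TSV + manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "mirna.fa", mirnas)
    write_fasta(outdir / "utrs.fa", utrs)
    write_conservation(outdir / "cons.wig", utrs)
    rows = []
    for p in pairs:
        rows.append({
            "mirna_id": p.mirna_id, "utr_id": p.utr_id, "label": p.label,
            "level": p.level,
            "start": p.site.start if p.site else "",
            "end": p.site.end if p.site else "",
            "rule_id": p.site.rule_id if p.site else "",
        })
    pd.DataFrame(rows).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
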