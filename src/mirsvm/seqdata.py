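"""Domain types, coordinate conventions and readers/writers.

Conventions
-----------
* All sequences are RNA, 5'->3', alphabet ``{A, C, G, U}``; ``T`` is
  normalised to ``U`` on input and lower case is upper-cased.
* Internal coordinates are 0-based half-open intervals on the UTR's
  5'->3' strand.  The 1-based ``p`` (miRNA, from the 5' end) and ``q``
  (site, from the 3' end) numbering used throughout the method is a view
  layer on top of these intervals: ``q1`` is the UTR nucleotide opposite
  ``p1``, and increasing ``q`` index walks 3'->5' along the UTR
  (antiparallel pairing).  ``q0, q-1, ...`` extend 3' of the site and
  ``r1, r2, ...`` extend 5' of it.
* Context positions that fall off either end of the UTR are reported as
  the sentinel ``None`` ("absent" nucleotide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: status codes shared across the package
WC, GU, MISMATCH, GAP = 1, 2, 3, 4


class ParseError(ValueError):
    """Raised when an input file violates a format invariant."""


def normalize_rna(seq: str) -> str:
    """Upper-case and convert T->U."""
    return seq.upper().replace("T", "U")


def _validate_seq(seq: str, record_id: str) -> None:
    if not seq:
        raise ParseError(f"record {record_id!r}: empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ParseError(
            f"record {record_id!r}: illegal character(s) {sorted(bad)}"
        )


@dataclass
class MirnaSeq:
    """A miRNA; positions ``p1..pM`` are 1-based from the 5' end."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = normalize_rna(self.seq)
        _validate_seq(self.seq, self.id)

    @property
    def M(self) -> int:
        return len(self.seq)

    def p(self, m: int) -> str:
        """Nucleotide at 1-based position ``m`` from the 5' end."""
        if not 1 <= m <= self.M:
            raise IndexError(f"p{m} out of range for miRNA of length {self.M}")
        return self.seq[m - 1]


@dataclass
class UtrSeq:
    """A 3'UTR with an optional per-nucleotide conservation track."""

    id: str
    seq: str
    gene: str = ""
    cons: Optional[np.ndarray] = None
    #: True when at least one real conservation value was read for this UTR
    has_cons: bool = False

    def __post_init__(self) -> None:
        self.seq = normalize_rna(self.seq)
        _validate_seq(self.seq, self.id)
        if not self.gene:
            self.gene = self.id
        if self.cons is not None:
            self.cons = np.asarray(self.cons, dtype=float)
            if len(self.cons) != len(self.seq):
                raise ValueError(
                    f"UTR {self.id!r}: conservation length {len(self.cons)} "
                    f"!= sequence length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def cons_at(self, i: int) -> float:
        """Conservation at 0-based position ``i``; 0.0 when absent."""
        if self.cons is None or not 0 <= i < len(self.seq):
            return 0.0
        return float(self.cons[i])


@dataclass
class CandidateSite:
    """A UTR interval passing a seed-match filter rule.

    ``start``/``end`` delimit the seed-paired interval (0-based
    half-open).  ``seed_statuses`` holds the per-miRNA-position match
    status over the seed window as produced by the filter; ``seed_gap``
    marks a site-side bulged nucleotide (rule 5) if any.
    """

    utr_id: str
    mirna_id: str
    start: int
    end: int
    rule_id: int
    seed_statuses: tuple = ()
    n_wc: int = 0
    n_match: int = 0
    seed_gap: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad site interval [{self.start}, {self.end})")
        if self.rule_id not in {1, 2, 3, 4, 5}:
            raise ValueError(f"rule_id {self.rule_id} not in 1..5")

    # ---- q / r coordinate views -------------------------------------
    def q_index(self, j: int) -> int:
        """UTR 0-based index of site position ``q_j``.

        ``j >= 1`` walks 3'->5' inside/through the site (q1 == end-1);
        ``j <= 0`` walks 3' of the site (q0 == end, q-1 == end+1, ...).
        """
        return self.end - j

    def q_nt(self, utr: UtrSeq, j: int) -> Optional[str]:
        i = self.q_index(j)
        if 0 <= i < len(utr):
            return utr.seq[i]
        return None

    def r_index(self, utr_or_none=None, j: int = 1) -> int:
        """UTR 0-based index of 5'-context position ``r_j`` (r1 == start-1)."""
        return self.start - j

    def r_nt(self, utr: UtrSeq, j: int) -> Optional[str]:
        i = self.start - j
        if 0 <= i < len(utr):
            return utr.seq[i]
        return None

    def validate_against(self, utr: UtrSeq) -> None:
        if self.end > len(utr):
            raise ValueError(
                f"site [{self.start},{self.end}) exceeds UTR {utr.id!r} "
                f"length {len(utr)}"
            )


@dataclass
class LabeledPair:
    """A labelled miRNA-site or miRNA-target pair."""

    mirna_id: str
    utr_id: str
    label: str  # "positive" | "negative"
    level: str  # "site" | "utr"
    site: Optional[CandidateSite] = None

    def __post_init__(self) -> None:
        if self.label not in {"positive", "negative"}:
            raise ValueError(f"label {self.label!r}")
        if self.level not in {"site", "utr"}:
            raise ValueError(f"level {self.level!r}")
        if (self.site is not None) != (self.level == "site"):
            raise ValueError("site must be present iff level == 'site'")


# ---------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------

def read_fasta(path, molecule: str = "utr"):
    """Read a FASTA file into :class:`MirnaSeq` or :class:`UtrSeq` records.

    IDs must be unique; ``T`` is converted to ``U``; case is normalised.
    """
    if molecule not in {"mirna", "utr"}:
        raise ValueError(f"molecule {molecule!r}")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_rna(str(rec.seq))
        _validate_seq(seq, rec.id)
        if molecule == "mirna":
            records.append(MirnaSeq(id=rec.id, seq=seq))
        else:
            records.append(UtrSeq(id=rec.id, seq=seq))
    logger.info("read %d %s records from %s", len(records), molecule, path)
    return records


def write_fasta(path, records: Iterable[Union[MirnaSeq, UtrSeq]]) -> None:
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------
# Conservation tracks (text wiggle / bedGraph)
# ---------------------------------------------------------------------

def read_conservation(path, utrs: Sequence[UtrSeq]) -> Sequence[UtrSeq]:
    """Attach per-nucleotide conservation scores to ``utrs`` in place.

    Supports fixedStep / variableStep wiggle (1-based) and 4-column
    bedGraph (0-based half-open); the chrom field must equal the UTR id.
    Positions not covered by the track default to 0.0; a per-UTR flag
    records whether any real score was present.  Scores outside [0, 1]
    raise :class:`ParseError`.
    """
    by_id = {u.id: u for u in utrs}
    tracks: dict = {uid: np.zeros(len(u), dtype=float) for uid, u in by_id.items()}
    touched: set = set()

    def _set(uid: str, pos0: int, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ParseError(
                f"conservation score {value} out of [0,1] for {uid!r}"
            )
        if uid in tracks and 0 <= pos0 < len(tracks[uid]):
            tracks[uid][pos0] = value
            touched.add(uid)

    mode = None  # ("fixed", uid, next_pos0, step) | ("variable", uid)
    n_values = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if fields[0] == "fixedStep":
                kv = dict(f.split("=") for f in fields[1:])
                mode = ["fixed", kv["chrom"], int(kv["start"]) - 1,
                        int(kv.get("step", 1))]
                continue
            if fields[0] == "variableStep":
                kv = dict(f.split("=") for f in fields[1:])
                mode = ["variable", kv["chrom"]]
                continue
            if len(fields) == 4 and mode is None:
                uid, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                for i in range(s, e):
                    _set(uid, i, v)
                n_values += e - s
            elif mode is not None and mode[0] == "fixed":
                _set(mode[1], mode[2], float(fields[0]))
                mode[2] += mode[3]
                n_values += 1
            elif mode is not None and mode[0] == "variable":
                _set(mode[1], int(fields[0]) - 1, float(fields[1]))
                n_values += 1
            else:
                raise ParseError(f"unparseable track line: {line!r}")

    for uid, utr in by_id.items():
        utr.cons = tracks[uid]
        utr.has_cons = uid in touched
    logger.info("read %d conservation values from %s", n_values, path)
    return utrs


def write_conservation(path, utrs: Iterable[UtrSeq]) -> None:
    """Write attached conservation tracks as fixedStep wiggle."""
    with open(path, "w") as fh:
        for utr in utrs:
            if utr.cons is None:
                continue
            fh.write(f"fixedStep chrom={utr.id} start=1 step=1\n")
            for v in utr.cons:
                fh.write(f"{v:.6g}\n")


# ---------------------------------------------------------------------
# Tabular records
# ---------------------------------------------------------------------

_EXPR_DEFAULT_COLS = {
    "gene": "gene",
    "log_fold_change": "log_fold_change",
    "p_value": "p_value",
}


def read_expression_table(path, colmap: Optional[dict] = None) -> pd.DataFrame:
    """Read a differential-expression TSV.

    ``colmap`` maps the canonical names ``gene``, ``log_fold_change``,
    ``p_value`` to the actual column headers.  Extra columns (e.g.
    per-timepoint fold changes) are preserved verbatim.
    """
    cols = dict(_EXPR_DEFAULT_COLS)
    if colmap:
        cols.update(colmap)
    df = pd.read_csv(path, sep="\t")
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    logger.info("read %d expression rows from %s", len(df), path)
    return df


def read_labeled_pairs(path) -> pd.DataFrame:
    """Read a miRecords-like TSV of labelled pairs.

    Required columns: ``mirna_id``, ``utr_id``; optional: ``site_seq``,
    ``label`` (defaults to positive).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna_id", "utr_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing mandatory column {col!r}")
    if "label" not in df.columns:
        df["label"] = "positive"
    logger.info("read %d labelled pair rows from %s", len(df), path)
    return df


def write_sites_tsv(path, sites: Iterable[CandidateSite],
                    utrs: Optional[dict] = None) -> None:
    rows = []
    for s in sites:
        seed = ""
        if utrs and s.utr_id in utrs:
            seed = utrs[s.utr_id].seq[s.start:s.end]
        rows.append((s.utr_id, s.mirna_id, s.start, s.end, s.rule_id, seed))
    pd.DataFrame(
        rows,
        columns=["utr_id", "mirna_id", "start", "end", "rule_id", "seed_string"],
    ).to_csv(path, sep="\t", index=False)
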