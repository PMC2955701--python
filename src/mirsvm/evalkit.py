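"""Evaluation statistics: ROC with an unscored-gene convention,
precision@k, cumulative fold-change curves, their integrated area
M(n), the cross-miRNA consistency C(n), and the binding-probability
logo."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .seqdata import GU, WC
from .duplexer import DuplexStructure

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# ROC with unscored genes
# ---------------------------------------------------------------------

def roc_with_unscored(scores: Dict[str, float], labels: Dict[str, int],
                      unscored_ids: Iterable[str] = ()
                      ) -> Tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC where unscored genes behave as a random predictor.

    Scored genes are ranked by descending score (ties grouped); the
    unscored remainder contributes the expected straight-line
    continuation of the curve to (1, 1).  AUC by trapezoid.
    """
    unscored = set(unscored_ids)
    y = np.array([labels[g] for g in scores if g not in unscored])
    s = np.array([scores[g] for g in scores if g not in unscored])
    n_pos = sum(v for v in labels.values())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")

    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    if len(s):
        order = np.argsort(-s, kind="stable")
        y_sorted = y[order]
        s_sorted = s[order]
        i = 0
        while i < len(s_sorted):
            j = i
            while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
                j += 1
            tp += int(np.sum(y_sorted[i:j] == 1))
            fp += int(np.sum(y_sorted[i:j] == 0))
            tpr.append(tp / n_pos)
            fpr.append(fp / n_neg)
            i = j
    # expected diagonal continuation over the unscored genes
    if fpr[-1] < 1.0 or tpr[-1] < 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    fpr_a, tpr_a = np.array(fpr), np.array(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return fpr_a, tpr_a, auc


def precision_at_k(ranked: Sequence[str], truth: Set[str],
                   ks: Sequence[int]) -> List[int]:
    """True-target counts among the top-k ranked predictions."""
    out = []
    for k in ks:
        if k > len(ranked):
            raise ValueError(f"k={k} exceeds ranking length {len(ranked)}")
        out.append(sum(1 for g in ranked[:k] if g in truth))
    return out


# ---------------------------------------------------------------------
# Cumulative fold change
# ---------------------------------------------------------------------

@dataclass
class CfcCurve:
    """Cumulative sum of fold changes over ranked predictions.

    ``c[0]`` anchors x = 0; empirical curves built from fold changes
    have ``c[0] == 0``.
    """

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)

    @property
    def n(self) -> int:
        return len(self.c) - 1

    @classmethod
    def from_fold_changes(cls, ranked_ids: Sequence[str],
                          fold_changes: Dict[str, float],
                          top: Optional[int] = None) -> "CfcCurve":
        """Rank-ordered cumulative sum; ids without a fold change are
        skipped (limited assay coverage), ties keep input order."""
        vals = [fold_changes[g] for g in ranked_ids if g in fold_changes]
        if top is not None:
            vals = vals[:top]
        return cls(np.concatenate([[0.0], np.cumsum(vals)]))


def m_score(curve: CfcCurve, n: int) -> float:
    """Average integrated area (1/n) * int_0^n c(x) dx, trapezoid rule
    on the piecewise-linear interpolation of the curve points."""
    if n > curve.n:
        raise ValueError(f"n={n} exceeds curve length {curve.n}")
    if n <= 0:
        raise ValueError("n must be positive")
    x = np.arange(n + 1)
    return float(np.trapezoid(curve.c[:n + 1], x) / n)


def consistency(m_scores: Sequence[float], mode: str = "sum") -> float:
    """C(n) across miRNAs: sum (as printed) or mean of the M(n) values."""
    m = np.asarray(m_scores, dtype=float)
    if mode == "sum":
        return float(m.sum())
    if mode == "mean":
        return float(m.mean())
    raise ValueError(f"mode {mode!r}")


# ---------------------------------------------------------------------
# Binding logo
# ---------------------------------------------------------------------

@dataclass
class BindingMatrix:
    """Sites x miRNA-position 0/1 pairing matrix with column means."""

    matrix: np.ndarray
    probabilities: np.ndarray
    mirna_seq: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.probabilities = np.asarray(self.probabilities, dtype=float)


def tarlogo(duplexes: Sequence[DuplexStructure], mirna_seq: str = "",
            include_gu: bool = True, n_positions: Optional[int] = None
            ) -> BindingMatrix:
    """Empirical per-position binding probabilities over predicted sites.

    Element (i, j) is 1 when miRNA position j+1 is paired (W-C, or G:U
    when ``include_gu``) in site i; probabilities are column means.
    """
    if not duplexes:
        raise ValueError("empty site list")
    if n_positions is None:
        n_positions = max(len(d.status) for d in duplexes)
        if mirna_seq:
            n_positions = max(n_positions, len(mirna_seq))
    paired = {WC, GU} if include_gu else {WC}
    rows = []
    for d in duplexes:
        row = [1 if (j < len(d.status) and d.status[j] in paired) else 0
               for j in range(n_positions)]
        rows.append(row)
    matrix = np.array(rows, dtype=int)
    return BindingMatrix(matrix=matrix, probabilities=matrix.mean(axis=0),
                         mirna_seq=mirna_seq)


def write_logo_table(path, logo: BindingMatrix) -> None:
    """Position-probability table (TSV): position, nucleotide, probability."""
    rows = []
    for j, p in enumerate(logo.probabilities, start=1):
        nt = logo.mirna_seq[j - 1] if j <= len(logo.mirna_seq) else "N"
        rows.append((j, nt, p))
    pd.DataFrame(rows, columns=["position", "nucleotide", "probability"]) \
        .to_csv(path, sep="\t", index=False)


def plot_logo(path, logo: BindingMatrix) -> None:
    """Letter-height logo: nucleotide letters scaled by binding probability."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728",
              "N": "#555555"}
    fig, ax = plt.subplots(figsize=(max(6, len(logo.probabilities) * 0.45), 2.5))
    for j, p in enumerate(logo.probabilities, start=1):
        nt = logo.mirna_seq[j - 1] if j <= len(logo.mirna_seq) else "N"
        ax.text(j, p / 2, nt, ha="center", va="center",
                fontsize=8 + 16 * p, color=colors.get(nt, "#555555"),
                fontweight="bold")
        ax.bar(j, p, width=0.85, color=colors.get(nt, "#555555"), alpha=0.15)
    ax.set_xlabel("miRNA position (5' to 3')")
    ax.set_ylabel("binding probability")
    ax.set_ylim(0, 1.05)
    ax.set_xticks(range(1, len(logo.probabilities) + 1))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def permutation_significance(*args, **kwargs):  # pragma: no cover
    """Hook for permutation-based CFC significance (not implemented)."""
    raise NotImplementedError(
        "permutation significance is out of scope; hook provided only")
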