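"""Two-sample positional residue enrichment between epitope and non-epitope sets.

For fixed-length aligned peptide sets, every (position, residue) cell is a
two-proportion comparison: frequency among positives vs frequency among
negatives. Cells are tested with the pooled two-proportion z-test, falling
back to an exact binomial test of the positive-class count against the
pooled proportion whenever any expected cell count is below 5. A cell is
flagged *enriched* (delta > 0) or *depleted* (delta < 0) when its
(optionally Bonferroni-corrected) p-value is at most alpha.

The overall enrichment/depletion rate summarizes the discrepancy as the
mean over positions of the summed |delta| of flagged residues at that
position, expressed as a percent. This is this package's working
definition of an otherwise loosely used summary quantity; it is 0 exactly
when no cell is flagged.

Variable-length sets must be aligned (truncated/padded) by the caller —
this module refuses ragged input rather than guessing an anchoring
convention. Graphical logo rendering is out of scope; the flagged-cell
delta matrix exports as TSV for any logo tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest, norm

from epiboost._alphabet import AA_INDEX, CANONICAL_ALPHABET
from epiboost.peptide_data import EpitopeDataset

__all__ = [
    "PositionEnrichmentTable",
    "position_composition",
    "two_sample_enrichment",
    "export_logo_matrix",
]


@dataclass
class PositionEnrichmentTable:
    """Per-(position, residue) frequencies, deltas, p-values and statuses.

    ``cells`` columns: position (0-based), residue, freq_pos, freq_neg,
    delta, p_value, status ('enriched' | 'depleted' | 'none').
    """

    length: int
    cells: pd.DataFrame
    alpha: float
    correction: str
    overall_rate: float  # percent

    def flagged(self) -> pd.DataFrame:
        return self.cells[self.cells["status"] != "none"]


def _composition_counts(
    dataset: EpitopeDataset, class_label: int
) -> tuple[np.ndarray, int, int]:
    seqs = [p.sequence for p in dataset if p.label == class_label]
    if not seqs:
        raise ValueError(f"no peptides with label {class_label}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            "positional analysis needs fixed-length input; got lengths "
            f"{sorted(lengths)} — align, truncate or pad first"
        )
    length = lengths.pop()
    counts = np.zeros((length, 20), dtype=int)
    for s in seqs:
        for j, res in enumerate(s):
            counts[j, AA_INDEX[res]] += 1
    return counts, length, len(seqs)


def position_composition(dataset: EpitopeDataset, class_label: int) -> pd.DataFrame:
    """Residue frequency per position for one class (rows: positions 0..L-1)."""
    counts, length, n = _composition_counts(dataset, class_label)
    return pd.DataFrame(
        counts / n,
        index=pd.RangeIndex(length, name="position"),
        columns=list(CANONICAL_ALPHABET),
    )


def _cell_pvalue(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-proportion test of x1/n1 vs x2/n2 (pooled z, exact fallback)."""
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 1.0
    expected = [n1 * p_pool, n1 * (1 - p_pool), n2 * p_pool, n2 * (1 - p_pool)]
    if min(expected) < 5:
        return binomtest(x1, n1, p_pool).pvalue
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(2 * norm.sf(abs(z)))


def two_sample_enrichment(
    pos: EpitopeDataset,
    neg: EpitopeDataset,
    alpha: float = 0.05,
    correction: str = "none",
) -> PositionEnrichmentTable:
    """Test every (position, residue) cell between two fixed-length sets.

    ``pos``/``neg`` may be the same dataset (labels 1 and 0 are selected
    from each respectively) or two disjoint single-class datasets.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"correction must be 'none' or 'bonferroni', got {correction!r}")
    counts_pos, len_pos, n_pos = _composition_counts(pos, 1)
    counts_neg, len_neg, n_neg = _composition_counts(neg, 0)
    if len_pos != len_neg:
        raise ValueError(
            f"positive length {len_pos} != negative length {len_neg}"
        )
    length = len_pos
    n_tests = length * 20
    rows = []
    for j in range(length):
        for a_idx, residue in enumerate(CANONICAL_ALPHABET):
            x1, x2 = int(counts_pos[j, a_idx]), int(counts_neg[j, a_idx])
            f1, f2 = x1 / n_pos, x2 / n_neg
            p = _cell_pvalue(x1, n_pos, x2, n_neg)
            if correction == "bonferroni":
                p = min(1.0, p * n_tests)
            delta = f1 - f2
            if p <= alpha and delta > 0:
                status = "enriched"
            elif p <= alpha and delta < 0:
                status = "depleted"
            else:
                status = "none"
            rows.append((j, residue, f1, f2, delta, p, status))
    cells = pd.DataFrame(
        rows,
        columns=[
            "position",
            "residue",
            "freq_pos",
            "freq_neg",
            "delta",
            "p_value",
            "status",
        ],
    )
    flagged = cells[cells["status"] != "none"]
    per_position = flagged.groupby("position")["delta"].apply(
        lambda d: d.abs().sum()
    )
    # mean over ALL positions (positions with no flagged cell contribute 0)
    overall_rate = 100.0 * float(per_position.reindex(range(length), fill_value=0.0).mean())
    return PositionEnrichmentTable(
        length=length,
        cells=cells,
        alpha=alpha,
        correction=correction,
        overall_rate=overall_rate,
    )


def export_logo_matrix(table: PositionEnrichmentTable, path: str | Path) -> None:
    """Write flagged-cell deltas as TSV (position, residue, delta, status).

    With no flagged cells the file contains only the header line.
    """
    table.flagged()[["position", "residue", "delta", "status"]].to_csv(
        path, sep="\t", index=False
    )


def save_enrichment_table(table: PositionEnrichmentTable, path: str | Path) -> None:
    """Full enrichment table TSV, one row per (position, residue)."""
    table.cells.to_csv(path, sep="\t", index=False)
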