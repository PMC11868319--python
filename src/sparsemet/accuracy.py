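"""Accuracy measures comparing observed and predicted breeding values.

Four per-simulation summaries of how well the sparse-data predictions (PBV)
reproduce the complete-data predictions (OBV): the Pearson correlation over
all lines, and three selection-oriented measures computed on the top
fraction (default 10%): common selected %, average observed rank of the
selected lines, and the selection differential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AmVector",
    "pearson_accuracy",
    "select_top",
    "common_selected_pct",
    "average_rank",
    "selection_differential",
    "compute_all_ams",
]

AM_NAMES = ("PC", "CG", "AR", "SD")


@dataclass
class AmVector:
    PC: float  # Pearson r(OBV, PBV) over all lines
    CG: float  # common % of top-k selections
    AR: float  # mean OBV-rank of the PBV-selected lines (best = 1)
    SD: float  # mean OBV of PBV-selected minus mean OBV of all lines

    def as_dict(self) -> dict:
        return {"PC": self.PC, "CG": self.CG, "AR": self.AR, "SD": self.SD}


def _vectors(bv):
    """Accept a BreedingValues-like object or an (ids, obv, pbv) triple."""
    if hasattr(bv, "obv"):
        return list(bv.line_ids), np.asarray(bv.obv, float), np.asarray(bv.pbv, float)
    ids, obv, pbv = bv
    return list(ids), np.asarray(obv, float), np.asarray(pbv, float)


def pearson_accuracy(bv) -> float:
    """Sample Pearson correlation between OBV and PBV over all lines."""
    _, obv, pbv = _vectors(bv)
    if len(obv) < 3:
        raise ValueError("need at least 3 lines for a correlation")
    if np.ptp(obv) == 0 or np.ptp(pbv) == 0:
        raise ValueError("zero variance in breeding values")
    return float(stats.pearsonr(obv, pbv).statistic)


def select_top(values, line_ids, k: int, ascending: bool = False) -> set:
    """The k line ids with the largest values; ties broken by line-id order."""
    values = np.asarray(values, float)
    if k > len(values):
        raise ValueError("k exceeds the number of lines")
    order = sorted(range(len(values)),
                   key=lambda i: ((values[i] if ascending else -values[i]),
                                  str(line_ids[i])))
    return {line_ids[i] for i in order[:k]}


def common_selected_pct(bv, k: int) -> float:
    """100 * |top_k(OBV) intersect top_k(PBV)| / k."""
    ids, obv, pbv = _vectors(bv)
    if k < 1:
        raise ValueError("k must be >= 1")
    return 100.0 * len(select_top(obv, ids, k) & select_top(pbv, ids, k)) / k


def average_rank(bv, k: int) -> float:
    """Mean OBV-rank (best = 1) of the k lines selected on PBV."""
    ids, obv, pbv = _vectors(bv)
    order = sorted(range(len(ids)), key=lambda i: (-obv[i], str(ids[i])))
    rank = {ids[i]: r + 1 for r, i in enumerate(order)}
    selected = select_top(pbv, ids, k)
    return float(np.mean([rank[l] for l in selected]))


def selection_differential(bv, k: int) -> float:
    """Mean OBV of the PBV-selected lines minus the mean OBV of all lines."""
    ids, obv, pbv = _vectors(bv)
    selected = select_top(pbv, ids, k)
    sel_mask = np.array([l in selected for l in ids])
    return float(obv[sel_mask].mean() - obv.mean())


def compute_all_ams(bv, top_fraction: float = 0.10) -> AmVector:
    """All four accuracy measures at the given selection intensity."""
    ids, obv, pbv = _vectors(bv)
    k = int(np.floor(top_fraction * len(ids)))
    if k < 1:
        raise ValueError("selection fraction selects no lines")
    triple = (ids, obv, pbv)
    return AmVector(
        PC=pearson_accuracy(triple),
        CG=common_selected_pct(triple, k),
        AR=average_rank(triple, k),
        SD=selection_differential(triple, k),
    )
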