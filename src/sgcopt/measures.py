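"""Optimality measures locating the SGC between best and worst codes.

All three ratio measures live on a 0-100% scale; values below 50% mean the
standard code sits closer to the cost-minimizing ("best") codes than to the
cost-maximizing ("worst") ones.

* ``m_s``   - single objective: 100 * |F(SGC) - F(best)| / |F(worst) - F(best)|.
* ``m_min`` - multi-objective: 100 * db_min / (db_min + dw_min), with db_min /
  dw_min the minimum Euclidean distances from the SGC's objective vector to
  the best / worst Pareto sets.
* ``m_mean`` - the same ratio built from average distances.

Plus results-side analytics over aggregated archives: the dominance-count
histogram (how many objectives each optimized code improves over the SGC),
order statistics of the structural distance ``d_str``, and the amino-acid x
codon-block assignment heatmap for block-structure codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import AA_LETTERS, GeneticCode, d_str

__all__ = [
    "DegenerateRangeError",
    "MeasureResult",
    "m_s",
    "m_min_mean",
    "count_better_objectives",
    "d_str_summary",
    "assignment_heatmap",
]


class DegenerateRangeError(ValueError):
    """The best-worst range collapsed; a ratio measure is undefined."""


@dataclass(frozen=True)
class MeasureResult:
    """One measure value (percent) with its constituent distances."""

    name: str
    value: float
    components: dict

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0 + 1e-9:
            raise ValueError(f"{self.name} outside [0, 100]: {self.value}")


def _vec(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def _set(xs) -> np.ndarray:
    if isinstance(xs, np.ndarray) and xs.ndim == 2:
        return np.asarray(xs, dtype=float)
    return np.stack([_vec(x) for x in xs])


def m_s(sgc_value: float, best_value: float, worst_value: float) -> MeasureResult:
    """Single-objective position of the SGC on the best-to-worst range."""
    dbw = abs(worst_value - best_value)
    if dbw == 0.0:
        raise DegenerateRangeError("best and worst values coincide")
    db = abs(sgc_value - best_value)
    return MeasureResult(
        "m_s",
        100.0 * db / dbw,
        {"db": db, "dbw": dbw, "sgc": sgc_value,
         "best": best_value, "worst": worst_value},
    )


def m_min_mean(sgc, best_set, worst_set) -> tuple[MeasureResult, MeasureResult]:
    """Multi-objective measures from Euclidean distances in objective space."""
    s = _vec(sgc)
    B = _set(best_set)
    W = _set(worst_set)
    if len(B) == 0 or len(W) == 0:
        raise ValueError("best and worst sets must be non-empty")
    db = np.sqrt(((B - s) ** 2).sum(axis=1))
    dw = np.sqrt(((W - s) ** 2).sum(axis=1))
    db_min, dw_min = db.min(), dw.min()
    db_mean, dw_mean = db.mean(), dw.mean()
    if db_min + dw_min == 0.0:
        raise DegenerateRangeError("all distances are zero")
    r_min = MeasureResult(
        "m_min",
        100.0 * db_min / (db_min + dw_min),
        {"db_min": float(db_min), "dw_min": float(dw_min)},
    )
    r_mean = MeasureResult(
        "m_mean",
        100.0 * db_mean / (db_mean + dw_mean),
        {"db_mean": float(db_mean), "dw_mean": float(dw_mean)},
    )
    return r_min, r_mean


def count_better_objectives(archive, sgc) -> pd.DataFrame:
    """Histogram over 0..k of objectives improved (strictly smaller) vs SGC."""
    s = _vec(sgc)
    F = _set(
        [m.objectives for m in archive] if hasattr(archive[0], "objectives")
        else archive
    )
    k = F.shape[1]
    better = (F < s).sum(axis=1)
    counts = np.bincount(better, minlength=k + 1)
    frame = pd.DataFrame(
        {
            "n_objectives_better": np.arange(k + 1),
            "count": counts,
            "percent": 100.0 * counts / len(F),
        }
    ).set_index("n_objectives_better")
    return frame


def d_str_summary(archive, reference: GeneticCode) -> dict:
    """Min / median / max of ``d_str`` against a reference code.

    The median of an even-sized set is the lower of the two middle order
    statistics, so it stays an attained integer distance.
    """
    codes = [m.code if hasattr(m, "code") else m for m in archive]
    if not codes:
        raise ValueError("archive is empty")
    dists = np.sort([d_str(c, reference) for c in codes])
    median = int(dists[(len(dists) - 1) // 2])
    return {"min": int(dists[0]), "median": median, "max": int(dists[-1]),
            "n": len(dists)}


def assignment_heatmap(archive, reference: GeneticCode) -> pd.DataFrame:
    """Counts of archive codes assigning amino acid a to reference block b.

    Rows: amino acids; columns: the reference code's blocks, labelled by the
    amino acid the reference assigns there.  Every archive member must be a
    block-structure code sharing the reference partition, so each row and
    column sums to the archive size.
    """
    codes = [m.code if hasattr(m, "code") else m for m in archive]
    ref_perm = reference.block_permutation()
    grid = np.zeros((20, 20), dtype=int)
    for code in codes:
        perm = code.block_permutation()  # raises for non-BS members
        for block, aa in enumerate(perm):
            grid[aa, block] += 1
    block_labels = [AA_LETTERS[a] for a in ref_perm]
    frame = pd.DataFrame(
        grid, index=list(AA_LETTERS), columns=block_labels
    )
    frame.index.name = "amino_acid"
    frame.columns.name = "reference_block"
    return frame
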