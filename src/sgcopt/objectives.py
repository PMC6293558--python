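"""Amino-acid property indices, replacement-cost matrices and objectives.

Each objective derives from one AAindex amino-acid property scale: the
20x20 matrix of squared value differences, max-normalized to [0, 1], prices
every amino-acid replacement, and the objective value of a genetic code is
the summed price over all sense-sense codon pairs one point mutation apart.
Pairs involving a stop codon are excluded (stops carry no property value and
are immutable in both code models), leaving 263 of the 288 neighbour pairs.

Also implements the deviation analytics: per amino acid, the absolute
difference between its max-normalized index value and the index mean --
amino acids with "average" properties are cheap to substitute, which is why
error-minimizing codes assign them many codons.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    AA_LETTERS,
    AA_NAMES3,
    GeneticCode,
    NeighborPairSet,
    SENSE_CODON_INDICES,
    neighbor_pairs,
)

__all__ = [
    "DEFAULT_ACCESSIONS",
    "AAindexFormatError",
    "DegenerateIndexError",
    "AminoAcidIndex",
    "CostMatrix",
    "ObjectiveVector",
    "parse_aaindex",
    "write_aaindex",
    "load_builtin_indices",
    "load_reference_deviation_table",
    "cost_matrix",
    "objective_value",
    "evaluate_objectives",
    "deviation_table",
    "spearman",
]

#: The eight representative AAindex accessions used as objectives.
DEFAULT_ACCESSIONS = (
    "BLAM930101",
    "BIOV880101",
    "MAXF760101",
    "TSAJ990101",
    "NAKH920108",
    "CEDJ970104",
    "LIFS790101",
    "MIYS990104",
)


class AAindexFormatError(ValueError):
    """An AAindex1 record could not be parsed."""


class DegenerateIndexError(ValueError):
    """An operation is undefined for a constant index."""


@dataclass(frozen=True)
class AminoAcidIndex:
    """A named 20-value amino-acid property scale (AAindex order)."""

    accession: str
    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20,) or not np.isfinite(v).all():
            raise AAindexFormatError(
                f"index {self.accession}: need 20 finite values"
            )
        object.__setattr__(self, "values", v)

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.values) == 0.0)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(AA_LETTERS, self.values.tolist()))


@dataclass(frozen=True)
class CostMatrix:
    """Max-normalized squared-difference replacement costs for one index.

    ``costs[a, b] = (v_a - v_b)^2 / max_xy (v_x - v_y)^2``; symmetric, zero
    diagonal, maximum entry exactly 1 unless the index is constant (then the
    matrix is all-zero and ``degenerate`` is set).
    """

    costs: np.ndarray
    source_accession: str
    degenerate: bool = False


@dataclass(frozen=True)
class ObjectiveVector:
    """Objective values of one code, labelled by accession."""

    values: np.ndarray
    accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.accessions):
            raise ValueError("values/accessions length mismatch")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


# --- AAindex1 flat-file I/O --------------------------------------------------

# AAindex1 'I' line column order, two rows of ten:
#   A R N D C Q E G H I  /  L K M F P S T W Y V
_I_HEADER_ORDER = "ARNDCQEGHILKMFPSTWYV"  # equals AA_LETTERS


def parse_aaindex(source) -> list[AminoAcidIndex]:
    """Parse AAindex1-format records from a path, string or text stream.

    Only the ``H`` (accession), ``D`` (description) and ``I`` (values)
    records are consumed; other record types are ignored.  Records with
    ``NA`` entries or a wrong value count raise :class:`AAindexFormatError`
    naming the accession.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.strip().startswith("H "):
            text = s
        else:
            with open(s) as fh:
                text = fh.read()

    out: list[AminoAcidIndex] = []
    for raw in text.split("//"):
        if not raw.strip():
            continue
        accession = None
        description = ""
        value_tokens: list[str] = []
        in_values = False
        for line in raw.splitlines():
            if not line.strip():
                continue
            key = line[0] if line[0] != " " else None
            if key == "I":
                in_values = True
                continue
            if key is None and in_values:
                value_tokens.extend(line.split())
                continue
            in_values = False
            if key == "H":
                accession = line[1:].strip().split()[0]
            elif key == "D":
                description = line[1:].strip()
        if accession is None:
            raise AAindexFormatError("record without an H (accession) line")
        if "NA" in value_tokens:
            raise AAindexFormatError(
                f"index {accession}: contains NA values"
            )
        if len(value_tokens) != 20:
            raise AAindexFormatError(
                f"index {accession}: expected 20 values, "
                f"got {len(value_tokens)}"
            )
        try:
            values = np.array([float(t) for t in value_tokens])
        except ValueError as exc:
            raise AAindexFormatError(
                f"index {accession}: unparseable value ({exc})"
            ) from exc
        out.append(AminoAcidIndex(accession, values, description))
    return out


def write_aaindex(indices, target) -> None:
    """Write indices as a minimal AAindex1 flat file (H, D, I records)."""
    lines: list[str] = []
    for idx in indices:
        lines.append(f"H {idx.accession}")
        if idx.description:
            lines.append(f"D {idx.description}")
        lines.append(
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T"
            "     G/W     H/Y     I/V"
        )
        lines.append("".join(f"{v:10.6f}" for v in idx.values[:10]))
        lines.append("".join(f"{v:10.6f}" for v in idx.values[10:]))
        lines.append("//")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w") as fh:
            fh.write(text)


def load_builtin_indices(accessions=DEFAULT_ACCESSIONS) -> list[AminoAcidIndex]:
    """The eight packaged index scales, in the requested accession order.

    Values are stored on the max-normalized scale (value / index maximum),
    which leaves cost matrices and deviation tables unchanged.
    """
    text = (
        resources.files("sgcopt.data").joinpath("aaindex8.txt").read_text()
    )
    pool = {idx.accession: idx for idx in parse_aaindex(text)}
    missing = [a for a in accessions if a not in pool]
    if missing:
        raise KeyError(
            f"accessions not in the packaged set: {missing}; "
            f"available: {sorted(pool)}"
        )
    return [pool[a] for a in accessions]


def load_reference_deviation_table() -> pd.DataFrame:
    """Reference deviation grid with codon counts, indexed by 3-letter name.

    Columns: the eight accessions, ``average`` (row mean), ``codons_best_us``
    (codon counts of a reference error-minimizing unrestricted code) and
    ``codons_sgc`` (SGC codon counts).
    """
    text = (
        resources.files("sgcopt.data")
        .joinpath("reference_deviation_table.csv")
        .read_text()
    )
    return pd.read_csv(io.StringIO(text), index_col="amino_acid")


# --- cost matrices and objective functions -----------------------------------


def cost_matrix(index: AminoAcidIndex) -> CostMatrix:
    """Max-normalized squared-difference replacement-cost matrix."""
    v = index.values
    diff2 = (v[:, None] - v[None, :]) ** 2
    peak = diff2.max()
    if peak == 0.0:
        return CostMatrix(
            np.zeros((20, 20)), index.accession, degenerate=True
        )
    return CostMatrix(diff2 / peak, index.accession)


def objective_value(
    code: GeneticCode,
    matrix: CostMatrix,
    pairs: NeighborPairSet | None = None,
) -> float:
    """Summed replacement cost over single-mutation sense codon pairs.

    Each unordered pair contributes once; pairs whose codons encode the same
    amino acid cost nothing.
    """
    if pairs is None:
        pairs = neighbor_pairs(sense_only=True)
    a = code.assignment[pairs.pairs[:, 0]]
    b = code.assignment[pairs.pairs[:, 1]]
    return float(matrix.costs[a, b].sum())


def evaluate_objectives(
    code: GeneticCode,
    matrices,
    pairs: NeighborPairSet | None = None,
) -> ObjectiveVector:
    """Objective vector of a code over a list of cost matrices."""
    if len(matrices) < 1:
        raise ValueError("need at least one cost matrix")
    if pairs is None:
        pairs = neighbor_pairs(sense_only=True)
    values = np.array(
        [objective_value(code, m, pairs) for m in matrices]
    )
    return ObjectiveVector(
        values, tuple(m.source_accession for m in matrices)
    )


def batch_objectives(
    assignments: np.ndarray,
    cost_stack: np.ndarray,
    pair_array: np.ndarray,
) -> np.ndarray:
    """Objective matrix ``(n_codes, k)`` for stacked codes.

    ``assignments`` is ``(n, 64)`` int, ``cost_stack`` ``(k, 20, 20)``,
    ``pair_array`` ``(p, 2)`` sense-sense codon-index pairs.  This is the
    vectorized engine path; it matches :func:`objective_value` exactly.
    """
    a = assignments[:, pair_array[:, 0]]
    b = assignments[:, pair_array[:, 1]]
    return cost_stack[:, a, b].sum(axis=2).T


# --- deviation analytics -----------------------------------------------------


def deviation_table(indices) -> pd.DataFrame:
    """Per-amino-acid absolute deviations from each index mean.

    Every index is first normalized by its (signed) maximum value; the table
    entry is ``|normalized value - mean of normalized values|``.  The final
    ``average`` column is the row mean across indices.  Rows are indexed by
    3-letter amino-acid names in alphabetical order.
    """
    cols = {}
    for idx in indices:
        if idx.is_constant:
            raise DegenerateIndexError(
                f"index {idx.accession} is constant; deviations undefined"
            )
        x = idx.values / idx.values.max()
        cols[idx.accession] = np.abs(x - x.mean())
    frame = pd.DataFrame(cols, index=[AA_NAMES3[a] for a in AA_LETTERS])
    frame = frame.sort_index()
    frame["average"] = frame.mean(axis=1)
    frame.index.name = "amino_acid"
    return frame


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateIndexError(
            "correlation undefined for a constant vector"
        )
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
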