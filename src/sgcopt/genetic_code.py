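"""Genetic-code representations and code-space combinatorics.

The standard genetic code (SGC) maps the 64 RNA codons onto the 20 standard
amino acids plus the stop signal.  Theoretical alternatives are drawn from two
search spaces:

* the **block-structure (BS) model** keeps the SGC's partition of the 61 sense
  codons into 20 amino-acid codon blocks and only permutes which amino acid
  sits on which block;
* the **unrestricted (US) model** allows any surjective assignment of the 61
  sense codons to the 20 amino acids.

In both models the three stop codons (UAA, UAG, UGA) keep their SGC meaning.
This module provides the code container, the standard code, the single-point
mutation neighbour graph, the structural Hamming distance ``d_str`` and exact
counts of the code spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BASES",
    "CODONS",
    "AA_LETTERS",
    "AA_NAMES3",
    "STOP",
    "STOP_INDEX",
    "STOP_CODONS",
    "SENSE_CODON_INDICES",
    "N_SENSE",
    "DSTR_MAX",
    "SGC_BLOCKS",
    "SGC_BLOCK_AA",
    "InvalidCodeError",
    "GeneticCode",
    "NeighborPairSet",
    "standard_code",
    "neighbor_pairs",
    "d_str",
    "count_codes",
    "random_code",
    "read_codes",
    "write_codes",
]

# --- alphabet and canonical orders -----------------------------------------

#: RNA bases in code-table order; codons are ordered lexicographically in it.
BASES = "UCAG"

#: All 64 codons in canonical (code-table) order.
CODONS: tuple[str, ...] = tuple(
    b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: One-letter amino-acid codes in the AAindex column order.
AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_LETTERS)}

AA_NAMES3: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

STOP = "*"
STOP_INDEX = 20
STOP_CODONS = ("UAA", "UAG", "UGA")
STOP_CODON_INDICES = tuple(CODON_INDEX[c] for c in STOP_CODONS)

_SGC_TABLE = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "UAU": "Y", "UAC": "Y", "UAA": STOP, "UAG": STOP,
    "UGU": "C", "UGC": "C", "UGA": STOP, "UGG": "W",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_SGC_ARRAY = np.array(
    [STOP_INDEX if _SGC_TABLE[c] == STOP else AA_INDEX[_SGC_TABLE[c]]
     for c in CODONS],
    dtype=np.int8,
)

#: Indices of the 61 sense codons in canonical order.
SENSE_CODON_INDICES = np.array(
    [i for i in range(64) if i not in STOP_CODON_INDICES], dtype=np.intp
)
N_SENSE = 61

#: Maximum structural distance between two codes with fixed stops.
DSTR_MAX = 61


def _sgc_blocks() -> tuple[tuple[int, ...], ...]:
    # one block per amino acid, ordered by the block's first codon
    seen: dict[int, list[int]] = {}
    order: list[int] = []
    for ci in SENSE_CODON_INDICES:
        aa = int(_SGC_ARRAY[ci])
        if aa not in seen:
            seen[aa] = []
            order.append(aa)
        seen[aa].append(int(ci))
    return tuple(tuple(seen[aa]) for aa in order)


#: The SGC's 20 sense-codon blocks in canonical (first-codon) order.
SGC_BLOCKS: tuple[tuple[int, ...], ...] = _sgc_blocks()

#: Amino acid (integer) on each SGC block, i.e. the identity permutation.
SGC_BLOCK_AA = np.array([_SGC_ARRAY[b[0]] for b in SGC_BLOCKS], dtype=np.int8)

_BLOCK_OF_CODON = np.full(64, -1, dtype=np.int8)
for _bi, _blk in enumerate(SGC_BLOCKS):
    for _ci in _blk:
        _BLOCK_OF_CODON[_ci] = _bi

#: Multiset of SGC block sizes {6,6,6,4,...,1,1}.
SGC_BLOCK_SIZES = tuple(len(b) for b in SGC_BLOCKS)


class InvalidCodeError(ValueError):
    """A codon assignment violates the genetic-code invariants."""


@dataclass(eq=False)
class GeneticCode:
    """A total map from the 64 codons to the 20 amino acids and stop.

    Parameters
    ----------
    assignment
        Length-64 integer array in canonical codon order; values ``0..19``
        are amino acids in AAindex order, ``20`` is stop.
    model
        ``"BS"`` (block-structure) or ``"US"`` (unrestricted).
    """

    assignment: np.ndarray
    model: str = "US"

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int8)
        self.validate()

    # -- construction --------------------------------------------------

    @classmethod
    def from_string(cls, text: str, model: str = "US") -> "GeneticCode":
        """Parse a 64-character serialization (one-letter codes, '*' stop)."""
        text = text.strip()
        if len(text) != 64:
            raise InvalidCodeError(
                f"expected 64 characters, got {len(text)}"
            )
        try:
            arr = np.array(
                [STOP_INDEX if ch == STOP else AA_INDEX[ch] for ch in text],
                dtype=np.int8,
            )
        except KeyError as exc:  # pragma: no cover - message path
            raise InvalidCodeError(f"unknown amino-acid code {exc}") from exc
        return cls(arr, model=model)

    @classmethod
    def from_permutation(cls, perm: np.ndarray) -> "GeneticCode":
        """Build a BS code from a permutation ``block -> amino acid``."""
        perm = np.asarray(perm, dtype=np.int8)
        if sorted(perm.tolist()) != list(range(20)):
            raise InvalidCodeError("block assignment is not a permutation")
        arr = _SGC_ARRAY.copy()
        for bi, blk in enumerate(SGC_BLOCKS):
            arr[list(blk)] = perm[bi]
        return cls(arr, model="BS")

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        a = self.assignment
        if a.shape != (64,):
            raise InvalidCodeError("assignment must have 64 entries")
        if a.min() < 0 or a.max() > STOP_INDEX:
            raise InvalidCodeError("assignment values out of range")
        for ci in STOP_CODON_INDICES:
            if a[ci] != STOP_INDEX:
                raise InvalidCodeError(
                    f"stop codon {CODONS[ci]} reassigned; stops are fixed"
                )
        sense = a[SENSE_CODON_INDICES]
        if (sense == STOP_INDEX).any():
            raise InvalidCodeError("stop assigned outside UAA/UAG/UGA")
        if len(np.unique(sense)) != 20:
            raise InvalidCodeError("code is not surjective on amino acids")
        if self.model not in ("BS", "US"):
            raise InvalidCodeError(f"unknown model tag {self.model!r}")
        if self.model == "BS":
            # the sense-codon partition must equal the SGC's up to relabeling
            for blk in SGC_BLOCKS:
                if len(set(int(a[ci]) for ci in blk)) != 1:
                    raise InvalidCodeError(
                        "BS code does not preserve the SGC block partition"
                    )
            if len({int(a[blk[0]]) for blk in SGC_BLOCKS}) != 20:
                raise InvalidCodeError("BS block labels are not a bijection")

    # -- accessors ------------------------------------------------------

    def meaning(self, codon: str) -> str:
        """One-letter amino-acid code ('*' for stop) of ``codon``."""
        v = int(self.assignment[CODON_INDEX[codon]])
        return STOP if v == STOP_INDEX else AA_LETTERS[v]

    def codon_counts(self) -> np.ndarray:
        """Number of sense codons per amino acid, AAindex order (length 20)."""
        return np.bincount(
            self.assignment[SENSE_CODON_INDICES], minlength=20
        )[:20]

    def block_permutation(self) -> np.ndarray:
        """For a BS code, the amino acid on each canonical SGC block."""
        if self.model != "BS":
            raise InvalidCodeError("block permutation defined for BS codes")
        return np.array(
            [self.assignment[blk[0]] for blk in SGC_BLOCKS], dtype=np.int8
        )

    def to_string(self) -> str:
        return "".join(
            STOP if v == STOP_INDEX else AA_LETTERS[v]
            for v in self.assignment
        )

    def copy(self) -> "GeneticCode":
        return GeneticCode(self.assignment.copy(), model=self.model)

    # -- dunder ---------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticCode):
            return NotImplemented
        return bool(np.array_equal(self.assignment, other.assignment))

    def __hash__(self) -> int:
        return hash(self.assignment.tobytes())

    def __repr__(self) -> str:
        return f"GeneticCode({self.to_string()!r}, model={self.model!r})"


def standard_code() -> GeneticCode:
    """The canonical standard genetic code (61 sense codons, 3 stops)."""
    return GeneticCode(_SGC_ARRAY.copy(), model="BS")


# --- single-point-mutation neighbour graph ---------------------------------


@dataclass(frozen=True)
class NeighborPairSet:
    """Unordered codon pairs differing at exactly one position.

    ``pairs`` is an ``(n, 2)`` array of codon indices with ``pairs[:, 0] <
    pairs[:, 1]``, in deterministic lexicographic order.  With ``sense_only``
    every pair touching a stop codon is removed (263 of the 288 pairs remain).
    """

    pairs: np.ndarray
    sense_only: bool = False

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        for i, j in self.pairs:
            yield (CODONS[i], CODONS[j])


def neighbor_pairs(sense_only: bool = False) -> NeighborPairSet:
    """All unordered single-substitution codon pairs (288; 263 sense-sense)."""
    out = []
    stops = set(STOP_CODON_INDICES)
    for i, codon in enumerate(CODONS):
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                other = codon[:pos] + b + codon[pos + 1:]
                j = CODON_INDEX[other]
                if i < j:
                    if sense_only and (i in stops or j in stops):
                        continue
                    out.append((i, j))
    out.sort()
    return NeighborPairSet(np.array(out, dtype=np.intp), sense_only)


# --- structural distance -----------------------------------------------------


def d_str(x: GeneticCode, y: GeneticCode) -> int:
    """Number of sense codons with different amino acids in ``x`` and ``y``.

    A Hamming metric on codes with fixed stops; its maximum is 61.
    """
    xs = x.assignment[SENSE_CODON_INDICES]
    ys = y.assignment[SENSE_CODON_INDICES]
    return int(np.count_nonzero(xs != ys))


# --- code-space combinatorics ------------------------------------------------


def count_codes(n_codons: int, n_meanings: int, surjective: bool = False) -> int:
    """Exact number of assignments of ``n_codons`` to ``n_meanings``.

    Without the surjectivity requirement this is ``n_meanings ** n_codons``;
    with it, the inclusion-exclusion surjection count
    ``sum_k (-1)^k C(m, k) (m - k)^n``.  A surjective request with more
    meanings than codons yields 0 (there is no onto map), not an error.
    """
    if n_codons < 0 or n_meanings < 1:
        raise ValueError("need n_codons >= 0 and n_meanings >= 1")
    if not surjective:
        return n_meanings ** n_codons
    return sum(
        (-1) ** k * math.comb(n_meanings, k) * (n_meanings - k) ** n_codons
        for k in range(n_meanings + 1)
    )


# --- random codes ------------------------------------------------------------


def random_code(model: str, rng: np.random.Generator) -> GeneticCode:
    """Draw a random code of the given model; stops stay fixed.

    BS: a uniformly random bijection of the 20 amino acids onto the SGC
    blocks.  US: a uniformly random injection places each amino acid on one
    distinct sense codon (guaranteeing surjectivity), and the remaining 41
    sense codons get independent uniform amino acids.
    """
    if model == "BS":
        return GeneticCode.from_permutation(rng.permutation(20))
    if model == "US":
        arr = _SGC_ARRAY.copy()
        anchors = rng.choice(N_SENSE, size=20, replace=False)
        rest = np.setdiff1d(np.arange(N_SENSE), anchors)
        arr[SENSE_CODON_INDICES[anchors]] = np.arange(20, dtype=np.int8)
        arr[SENSE_CODON_INDICES[rest]] = rng.integers(
            0, 20, size=rest.size, dtype=np.int8
        )
        return GeneticCode(arr, model="US")
    raise ValueError(f"unknown model {model!r}")


# --- plain-text code files ---------------------------------------------------


def write_codes(codes, path) -> None:
    """Write codes one 64-character line per code."""
    with open(path, "w") as fh:
        for code in codes:
            fh.write(code.to_string() + "\n")


def read_codes(path, model: str = "US") -> list[GeneticCode]:
    """Read and validate serialized codes (one per line, '#' comments)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(GeneticCode.from_string(line, model=model))
    return out
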