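"""Mutation and crossover operators for both genetic-code models.

BS codes are manipulated through their 20-element block permutation (the
stop block is pinned and never selected); US codes through the raw 64-codon
assignment.  Every operator preserves totality, surjectivity on the 20 amino
acids and the fixed stop codons, and is bit-reproducible under a seeded
``numpy.random.Generator``.

The private ``_*`` functions operate on bare arrays (in place where noted)
and are shared with the evolutionary engine's fast path; the public
functions wrap them for :class:`~sgcopt.genetic_code.GeneticCode` values.
"""

from __future__ import annotations

import numpy as np

from .genetic_code import (
    AA_INDEX,
    GeneticCode,
    N_SENSE,
    SENSE_CODON_INDICES,
    CODON_INDEX,
)

__all__ = [
    "bs_swap_mutation",
    "bs_pos_crossover",
    "us_point_mutation",
    "us_amino_swap",
    "us_crossover",
]


# --- BS model: block-permutation operators ----------------------------------


def _bs_swap(perm: np.ndarray, rng: np.random.Generator,
             blocks: tuple[int, int] | None = None) -> None:
    """Swap the amino acids of two distinct blocks (in place)."""
    if blocks is None:
        b1, b2 = rng.choice(20, size=2, replace=False)
    else:
        b1, b2 = blocks
        if b1 == b2:
            raise ValueError("swap needs two distinct blocks")
    perm[b1], perm[b2] = perm[b2], perm[b1]


def _pos_fill(own: np.ndarray, donor: np.ndarray,
              keep: np.ndarray) -> np.ndarray:
    """Position-based crossover fill for permutations.

    Kept positions inherit ``own``; the rest are filled scanning ``donor``
    in canonical block order, skipping amino acids already present.
    """
    child = np.full(20, -1, dtype=np.int8)
    child[keep] = own[keep]
    used = np.zeros(20, dtype=bool)
    used[own[keep]] = True
    ptr = 0
    for b in range(20):
        if child[b] >= 0:
            continue
        while used[donor[ptr]]:
            ptr += 1
        child[b] = donor[ptr]
        used[donor[ptr]] = True
    return child


def _bs_pos_crossover(
    perm1: np.ndarray,
    perm2: np.ndarray,
    rng: np.random.Generator,
    keep_masks: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    if keep_masks is None:
        keep1 = rng.random(20) < 0.5
        keep2 = rng.random(20) < 0.5
    else:
        keep1, keep2 = (np.asarray(m, dtype=bool) for m in keep_masks)
    return _pos_fill(perm1, perm2, keep1), _pos_fill(perm2, perm1, keep2)


def bs_swap_mutation(
    code: GeneticCode,
    rng: np.random.Generator,
    blocks: tuple[int, int] | None = None,
) -> GeneticCode:
    """Exchange the amino acids of two randomly selected codon blocks.

    ``blocks`` may pin the block pair (canonical block indices) for
    deterministic use; the stop block is never a candidate.
    """
    perm = code.block_permutation()
    _bs_swap(perm, rng, blocks)
    return GeneticCode.from_permutation(perm)


def bs_pos_crossover(
    p1: GeneticCode,
    p2: GeneticCode,
    rng: np.random.Generator,
    keep_masks: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[GeneticCode, GeneticCode]:
    """Position-based crossover of two BS codes.

    Offspring 1 keeps a random subset of parent 1's block assignments (each
    block kept with probability 0.5) and fills the remaining blocks with
    parent 2's amino acids scanned in canonical order, skipping duplicates;
    offspring 2 is built symmetrically.  ``keep_masks`` pins the two kept
    subsets for deterministic use.
    """
    c1, c2 = _bs_pos_crossover(
        p1.block_permutation(), p2.block_permutation(), rng, keep_masks
    )
    return GeneticCode.from_permutation(c1), GeneticCode.from_permutation(c2)


# --- US model: codon-assignment operators ------------------------------------


def _us_counts(arr: np.ndarray) -> np.ndarray:
    return np.bincount(arr[SENSE_CODON_INDICES], minlength=21)


def _us_point(arr: np.ndarray, rng: np.random.Generator,
              sense_pos: int | None = None,
              new_aa: int | None = None) -> None:
    """Reassign one sense codon to a different amino acid (in place).

    If the selected codon is the sole codon of its amino acid the code is
    left unchanged (applied-but-identity; no resampling).
    """
    if sense_pos is None:
        sense_pos = int(rng.integers(N_SENSE))
    ci = SENSE_CODON_INDICES[sense_pos]
    old = int(arr[ci])
    if _us_counts(arr)[old] == 1:
        return
    if new_aa is None:
        new_aa = int(rng.integers(19))
        if new_aa >= old:
            new_aa += 1
    elif new_aa == old:
        raise ValueError("new amino acid must differ from the current one")
    arr[ci] = new_aa


def _us_amino_swap(arr: np.ndarray, rng: np.random.Generator,
                   amino_acids: tuple[int, int] | None = None) -> None:
    """Exchange the complete codon sets of two amino acids (in place).

    The pair is drawn by sampling two sense codons until they encode
    different amino acids.
    """
    if amino_acids is None:
        while True:
            i, j = rng.integers(N_SENSE, size=2)
            a = int(arr[SENSE_CODON_INDICES[i]])
            b = int(arr[SENSE_CODON_INDICES[j]])
            if a != b:
                break
    else:
        a, b = amino_acids
        if a == b:
            raise ValueError("swap needs two distinct amino acids")
    mask_a = arr == a
    mask_b = arr == b
    arr[mask_a] = b
    arr[mask_b] = a


def _us_crossover(
    arr1: np.ndarray, arr2: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """US crossover on raw assignments; returns two new arrays.

    Offspring start as parent copies.  Amino acids are processed once each
    in a uniformly shuffled order; for the focal amino acid, codons shared
    by both parents stay put, differing codons are exchanged pairwise (a
    within-offspring meaning swap, which cannot change any codon count),
    and a leftover codon on one side is transferred: it takes the focal
    amino acid in one offspring and the amino acid it displaces in the
    other.  Codons that are the sole codon of their amino acid in a parent
    are frozen in the corresponding offspring, and a transfer that would
    leave an amino acid with no codon is skipped.
    """
    o1 = arr1.copy()
    o2 = arr2.copy()
    counts1 = _us_counts(arr1)
    counts2 = _us_counts(arr2)
    # static freeze masks: sole-for-its-amino-acid in the parent
    frozen1 = counts1[arr1] == 1
    frozen2 = counts2[arr2] == 1
    c1 = counts1.copy()  # live counts of the offspring
    c2 = counts2.copy()

    for aa in rng.permutation(20):
        s1 = set(np.flatnonzero(arr1 == aa).tolist())
        s2 = set(np.flatnonzero(arr2 == aa).tolist())
        d1 = np.array(sorted(s1 - s2), dtype=np.intp)
        d2 = np.array(sorted(s2 - s1), dtype=np.intp)
        rng.shuffle(d1)
        rng.shuffle(d2)
        n = min(len(d1), len(d2))
        for u, v in zip(d1[:n], d2[:n]):
            if not frozen1[u] and not frozen1[v]:
                o1[u], o1[v] = o1[v], o1[u]
            if not frozen2[u] and not frozen2[v]:
                o2[u], o2[v] = o2[v], o2[u]
        for w in d2[n:]:  # parent 2 has an extra codon for aa
            if frozen1[w] or frozen2[w]:
                continue
            b1 = int(o1[w])
            b2 = int(o2[w])
            if b1 == aa or b2 == b1 or c1[b1] < 2 or c2[b2] < 2:
                continue
            o1[w] = aa          # aa gains w in offspring 1 ...
            c1[b1] -= 1
            c1[aa] += 1
            o2[w] = b1          # ... and cedes w to the displaced aa in 2
            c2[b2] -= 1
            c2[b1] += 1
        for w in d1[n:]:  # parent 1 has an extra codon for aa
            if frozen1[w] or frozen2[w]:
                continue
            b1 = int(o1[w])
            b2 = int(o2[w])
            if b2 == aa or b1 == b2 or c2[b2] < 2 or c1[b1] < 2:
                continue
            o2[w] = aa
            c2[b2] -= 1
            c2[aa] += 1
            o1[w] = b2
            c1[b1] -= 1
            c1[b2] += 1
    return o1, o2


def us_point_mutation(
    code: GeneticCode,
    rng: np.random.Generator,
    codon: str | None = None,
    amino_acid: str | None = None,
) -> GeneticCode:
    """Assign a randomly selected different amino acid to a random codon.

    The selected codon keeps its meaning when it is the only codon of its
    amino acid (surjectivity guard).  ``codon``/``amino_acid`` pin the
    choices for deterministic use.
    """
    arr = code.assignment.copy()
    sense_pos = None
    if codon is not None:
        sense_pos = int(np.flatnonzero(
            SENSE_CODON_INDICES == CODON_INDEX[codon]
        )[0])
    new_aa = AA_INDEX[amino_acid] if amino_acid is not None else None
    _us_point(arr, rng, sense_pos, new_aa)
    return GeneticCode(arr, model="US")


def us_amino_swap(
    code: GeneticCode,
    rng: np.random.Generator,
    amino_acids: tuple[str, str] | None = None,
) -> GeneticCode:
    """Exchange the codon sets of two amino acids picked via random codons."""
    arr = code.assignment.copy()
    pair = None
    if amino_acids is not None:
        pair = (AA_INDEX[amino_acids[0]], AA_INDEX[amino_acids[1]])
    _us_amino_swap(arr, rng, pair)
    return GeneticCode(arr, model="US")


def us_crossover(
    p1: GeneticCode, p2: GeneticCode, rng: np.random.Generator
) -> tuple[GeneticCode, GeneticCode]:
    """Structure-preserving crossover of two US codes."""
    o1, o2 = _us_crossover(p1.assignment, p2.assignment, rng)
    return GeneticCode(o1, model="US"), GeneticCode(o2, model="US")
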