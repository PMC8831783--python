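"""Standard genetic code tables and codon-graph combinatorics.

Everything downstream (rate matrices, the Gillespie simulator, the pruning
likelihood) operates on the 61 sense codons of the standard nuclear genetic
code, indexed lexicographically over the nucleotide alphabet ``A, C, G, T``
with the three stop codons (TAA, TAG, TGA) removed.  Mutations into stop
codons carry rate zero throughout the package: the substitution process
never visits them.

The central object is :class:`CodonSpace`, a cached, immutable collection of
index tables describing the single-nucleotide codon graph:

* ``A(i)`` -- the amino acid encoded by codon ``i``;
* ``i[k]`` -- the nucleotide at codon position ``k``;
* ``M(i, j)`` -- the nucleotide change underlying a neighboring codon pair;
* ``N(i)`` -- the nonsynonymous sense-codon neighbors of ``i``.

Amino acids are indexed alphabetically by one-letter code
(``ACDEFGHIKLMNPQRSTVWY``).
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_SENSE = 61
N_AMINO_ACIDS = 20

#: weak (A, T) and strong (C, G) nucleotide index sets
WEAK = frozenset((0, 3))
STRONG = frozenset((1, 2))

#: sentinel target indices in the neighbor table
STOP_TARGET = -1
SELF_TARGET = -2


@dataclass(frozen=True)
class NeighborMutation:
    """One single-nucleotide variant of a codon."""

    codon: str
    index: int  # sense-codon index, or STOP_TARGET for a stop codon
    position: int  # 0, 1 or 2
    source_nt: str
    target_nt: str
    is_synonymous: bool
    is_stop: bool


def ws_class(source_nt: int, target_nt: int) -> int:
    """Weak/strong direction of a nucleotide change.

    Returns +1 for weak->strong (AT -> GC), -1 for strong->weak, and 0 for
    changes within a class (A<->T, G<->C).
    """
    if source_nt in WEAK and target_nt in STRONG:
        return 1
    if source_nt in STRONG and target_nt in WEAK:
        return -1
    return 0


class CodonSpace:
    """Index tables over the 61 sense codons of the standard genetic code.

    Attributes
    ----------
    codons : list of str
        The 61 sense codons in lexicographic (A < C < G < T) order.  This is
        the row/column order of every 61x61 matrix in the package.
    stops : list of str
        The three stop codons.
    aa_of : ndarray of shape (61,)
        Amino-acid index (alphabetical one-letter order) per codon.
    codon_nt : ndarray of shape (61, 3)
        Nucleotide index at each codon position.
    nb_target : ndarray of shape (61, 9)
        Target sense-codon index for each of the nine single-nucleotide
        variants (3 positions x 3 alternative nucleotides, in fixed order),
        or ``STOP_TARGET`` when the variant is a stop codon.
    nb_pos, nb_src, nb_dst : ndarray of shape (61, 9)
        Position and source/target nucleotide of each variant.
    nb_syn : bool ndarray of shape (61, 9)
        True where the variant is a sense codon encoding the same amino acid.
    nb_ws : int8 ndarray of shape (61, 9)
        Weak/strong class of the nucleotide change (+1 WS, -1 SW, 0 neither).
    """

    def __init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[1]
        all_codons = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]
        self.stops = sorted(table.stop_codons)
        self.codons = [c for c in all_codons if c not in table.stop_codons]
        if len(self.codons) != N_SENSE or len(self.stops) != 3:
            raise RuntimeError("standard genetic code tables are inconsistent")
        self.codon_index = {c: i for i, c in enumerate(self.codons)}
        self.amino_acids = AMINO_ACIDS
        self.aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        self.aa_of = np.array(
            [self.aa_index[table.forward_table[c]] for c in self.codons], dtype=np.intp
        )
        nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
        self.codon_nt = np.array(
            [[nt_index[n] for n in c] for c in self.codons], dtype=np.intp
        )

        # Nine variant slots per codon: position-major, alternative nucleotides
        # in alphabetical order.
        nb_target = np.full((N_SENSE, 9), STOP_TARGET, dtype=np.intp)
        nb_pos = np.zeros((N_SENSE, 9), dtype=np.intp)
        nb_src = np.zeros((N_SENSE, 9), dtype=np.intp)
        nb_dst = np.zeros((N_SENSE, 9), dtype=np.intp)
        nb_syn = np.zeros((N_SENSE, 9), dtype=bool)
        nb_ws = np.zeros((N_SENSE, 9), dtype=np.int8)
        for i, codon in enumerate(self.codons):
            slot = 0
            for pos in range(3):
                src = nt_index[codon[pos]]
                for dst in range(4):
                    if dst == src:
                        continue
                    variant = codon[:pos] + NUCLEOTIDES[dst] + codon[pos + 1 :]
                    j = self.codon_index.get(variant, STOP_TARGET)
                    nb_target[i, slot] = j
                    nb_pos[i, slot] = pos
                    nb_src[i, slot] = src
                    nb_dst[i, slot] = dst
                    if j != STOP_TARGET:
                        nb_syn[i, slot] = self.aa_of[j] == self.aa_of[i]
                    nb_ws[i, slot] = ws_class(src, dst)
                    slot += 1
        self.nb_target = nb_target
        self.nb_pos = nb_pos
        self.nb_src = nb_src
        self.nb_dst = nb_dst
        self.nb_syn = nb_syn
        self.nb_ws = nb_ws
        #: mask of variant slots that land on a sense codon
        self.nb_sense = nb_target != STOP_TARGET

    # ------------------------------------------------------------------ #
    # paper-symbol accessors

    def translate(self, codon: str) -> str:
        """A(i): one-letter amino acid encoded by a sense codon."""
        return AMINO_ACIDS[self.aa_of[self._index(codon)]]

    def position_nt(self, codon: str, k: int) -> str:
        """i[k]: the nucleotide at position k (1-based, per convention)."""
        if k not in (1, 2, 3):
            raise ValueError("codon positions are 1, 2 or 3")
        return NUCLEOTIDES[self.codon_nt[self._index(codon), k - 1]]

    def nucleotide_change(self, i: str, j: str) -> tuple[str, str]:
        """M(i, j): the (source, target) nucleotides of a neighbor pair.

        Defined iff the two sense codons differ at exactly one position.
        """
        ii, jj = self._index(i), self._index(j)
        diff = np.nonzero(self.codon_nt[ii] != self.codon_nt[jj])[0]
        if len(diff) != 1:
            raise ValueError(f"codons {i} and {j} are not single-nucleotide neighbors")
        k = diff[0]
        return NUCLEOTIDES[self.codon_nt[ii, k]], NUCLEOTIDES[self.codon_nt[jj, k]]

    def nonsynonymous_neighbors(self, codon: str) -> set[str]:
        """N(i): sense-codon neighbors encoding a different amino acid."""
        i = self._index(codon)
        mask = self.nb_sense[i] & ~self.nb_syn[i]
        return {self.codons[j] for j in self.nb_target[i, mask]}

    def neighbors(self, codon: str, include_stops: bool = False) -> list[NeighborMutation]:
        """All nine single-nucleotide variants of a sense codon.

        Stop-codon targets are excluded unless ``include_stops`` is set.
        """
        i = self._index(codon)
        out = []
        for slot in range(9):
            j = self.nb_target[i, slot]
            is_stop = j == STOP_TARGET
            if is_stop and not include_stops:
                continue
            pos = int(self.nb_pos[i, slot])
            variant = (
                codon[:pos] + NUCLEOTIDES[self.nb_dst[i, slot]] + codon[pos + 1 :]
            )
            out.append(
                NeighborMutation(
                    codon=variant,
                    index=int(j),
                    position=pos,
                    source_nt=NUCLEOTIDES[self.nb_src[i, slot]],
                    target_nt=NUCLEOTIDES[self.nb_dst[i, slot]],
                    is_synonymous=bool(self.nb_syn[i, slot]),
                    is_stop=bool(is_stop),
                )
            )
        return out

    def _index(self, codon: str) -> int:
        codon = codon.upper().replace("U", "T")
        try:
            return self.codon_index[codon]
        except KeyError:
            raise ValueError(f"{codon!r} is not a sense codon of the standard code")

    # ------------------------------------------------------------------ #
    # derived combinatorics

    def reachable_pair_mask(self) -> np.ndarray:
        """Boolean (20, 20) mask of amino-acid pairs one nonsynonymous
        nucleotide change apart (symmetric, False on the diagonal)."""
        mask = np.zeros((N_AMINO_ACIDS, N_AMINO_ACIDS), dtype=bool)
        rows = np.repeat(self.aa_of, 9).reshape(N_SENSE, 9)
        sel = self.nb_sense & ~self.nb_syn
        mask[rows[sel], self.aa_of[self.nb_target[sel]]] = True
        return mask


@functools.lru_cache(maxsize=1)
def codon_space() -> CodonSpace:
    """The shared, cached :class:`CodonSpace` instance."""
    return CodonSpace()


def neighbors(codon: str, include_stops: bool = False) -> list[NeighborMutation]:
    """Module-level convenience wrapper around :meth:`CodonSpace.neighbors`."""
    return codon_space().neighbors(codon, include_stops=include_stops)


def amino_acid_pair_census() -> dict[str, int]:
    """Count amino-acid pairs in the single-nucleotide codon graph.

    Returns ``total_pairs`` (all unordered amino-acid pairs), ``reachable_pairs``
    (unordered pairs connected by at least one single-nucleotide nonsynonymous
    change under the standard code) and ``directed_nonzero`` (ordered pairs,
    i.e. nonzero entries of a directional 20x20 rate tensor).
    """
    space = codon_space()
    mask = space.reachable_pair_mask()
    directed = int(mask.sum())
    return {
        "total_pairs": N_AMINO_ACIDS * (N_AMINO_ACIDS - 1) // 2,
        "reachable_pairs": directed // 2,
        "directed_nonzero": directed,
    }
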