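"""Standard genetic code over the 61 sense codons.

Codon substitution models operate on the sense-codon alphabet: the three
stop codons of the standard code are excluded from the state space, and
every remaining triplet receives a fixed index 0..60.  All other modules
index codon states through this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
MISSING = -1  # codon state for gapped / ambiguous triplets

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition (A<->G, C<->T)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with a canonical index over sense codons.

    The default instance is the standard nuclear code (NCBI table 1):
    61 sense codons, 3 stops (TAA, TAG, TGA).
    """

    codon_table: dict[str, str]
    stop_codons: frozenset[str]
    sense_codons: tuple[str, ...] = field(init=False)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        sense = tuple(
            a + b + c
            for a in NUCLEOTIDES
            for b in NUCLEOTIDES
            for c in NUCLEOTIDES
            if a + b + c not in self.stop_codons
        )
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "index", {cdn: i for i, cdn in enumerate(sense)})
        if len(self.codon_table) + len(self.stop_codons) != 64:
            raise ValueError("codon table plus stops must cover all 64 triplets")

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def translate(self, codon: str) -> str:
        """Amino acid for a sense codon, '*' for a stop, 'X' otherwise."""
        codon = codon.upper().replace("U", "T")
        if codon in self.stop_codons:
            return "*"
        return self.codon_table.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self.stop_codons

    def is_synonymous(self, i: int, j: int) -> bool:
        return self.codon_table[self.sense_codons[i]] == self.codon_table[self.sense_codons[j]]

    def single_difference(self, i: int, j: int) -> tuple[int, str, str] | None:
        """Position and nucleotides of the change if codons i, j differ at
        exactly one position, else None."""
        a, b = self.sense_codons[i], self.sense_codons[j]
        diffs = [(k, a[k], b[k]) for k in range(3) if a[k] != b[k]]
        if len(diffs) == 1:
            return diffs[0]
        return None


def _standard() -> GeneticCode:
    tbl = CodonTable.unambiguous_dna_by_id[1]
    fwd = {c.replace("U", "T"): aa for c, aa in tbl.forward_table.items()}
    stops = frozenset(c.replace("U", "T") for c in tbl.stop_codons)
    return GeneticCode(codon_table=fwd, stop_codons=stops)


STANDARD_CODE = _standard()
assert STANDARD_CODE.n_states == 61
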