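"""In-frame coding-sequence alignments: I/O, pseudogene screening,
codon frequencies and pairwise identities.

An alignment is stored both as raw aligned nucleotide strings (for
round-trip writing and nucleotide-level checks such as frameshift
detection) and as a matrix of sense-codon indices, with gapped or
ambiguous triplets marked MISSING.  Codon models treat MISSING states as
likelihood-neutral (all partial likelihoods one), the usual convention
for partially sequenced accessions.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import MISSING, NUCLEOTIDES, STANDARD_CODE, GeneticCode

__all__ = [
    "CodonAlignment",
    "CodonFrequencies",
    "OrfScreenReport",
    "AlignmentError",
    "FrameError",
    "read_codon_alignment",
    "write_codon_alignment",
    "screen_orfs",
    "estimate_frequencies",
    "pairwise_identity",
]

GAP_CHARS = set("-.?~")


class AlignmentError(ValueError):
    """Malformed alignment (unequal lengths, duplicate names, ...)."""


class FrameError(AlignmentError):
    """Sequence length not divisible by three."""


@dataclass
class CodonAlignment:
    """Aligned coding sequences decoded to sense-codon indices.

    Attributes
    ----------
    taxa : ordered taxon names (unique)
    codons : (n_taxa, L) int array of sense-codon indices; MISSING (=-1)
        marks gapped or ambiguous triplets
    nuc_seqs : raw aligned nucleotide strings, upper case, length 3L
    code : genetic code used for decoding
    """

    taxa: list[str]
    codons: np.ndarray
    nuc_seqs: dict[str, str]
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            dupes = [t for t, k in Counter(self.taxa).items() if k > 1]
            raise AlignmentError(f"duplicate taxon names: {dupes}")
        if self.codons.shape[0] != len(self.taxa):
            raise AlignmentError("codon matrix rows do not match taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        """Alignment length in codons."""
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        """Alignment restricted to the given taxa, in the given order."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise AlignmentError(f"taxa not in alignment: {missing}")
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(
            taxa=list(taxa),
            codons=self.codons[idx].copy(),
            nuc_seqs={t: self.nuc_seqs[t] for t in taxa},
            code=self.code,
        )

    def codon_string(self, taxon: str, site: int) -> str:
        return self.nuc_seqs[taxon][3 * site : 3 * site + 3]


def _decode(name: str, seq: str, code: GeneticCode) -> np.ndarray:
    if len(seq) % 3 != 0:
        raise FrameError(f"sequence {name!r} has length {len(seq)}, not a multiple of 3")
    out = np.full(len(seq) // 3, MISSING, dtype=np.int16)
    for i in range(0, len(seq), 3):
        triplet = seq[i : i + 3]
        if all(ch in NUCLEOTIDES for ch in triplet):
            out[i // 3] = code.index.get(triplet, MISSING)  # stops stay MISSING here
            if triplet in code.stop_codons:
                out[i // 3] = MISSING
    return out


def _from_records(records: list[tuple[str, str]], code: GeneticCode) -> CodonAlignment:
    if not records:
        raise AlignmentError("empty alignment")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    taxa = [n for n, _ in records]
    seqs = {n: s for n, s in records}
    codons = np.vstack([_decode(n, s, code) for n, s in records])
    return CodonAlignment(taxa=taxa, codons=codons, nuc_seqs=seqs, code=code)


def read_codon_alignment(
    path: str | Path,
    format: str = "fasta",
    code: GeneticCode = STANDARD_CODE,
) -> CodonAlignment:
    """Read an in-frame coding alignment from FASTA or relaxed sequential
    PHYLIP ("phyml format").

    Raises FrameError if any sequence length is not a multiple of three
    and AlignmentError if lengths are unequal or names repeat.  Triplets
    containing gaps, ambiguity codes, or a stop codon decode to MISSING;
    stop codons are flagged later by :func:`screen_orfs`, which inspects
    the raw nucleotide strings.
    """
    path = Path(path)
    if format == "fasta":
        records = [(r.id, str(r.seq).upper().replace("U", "T")) for r in SeqIO.parse(str(path), "fasta")]
    elif format == "phylip":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        records = [(r.id, str(r.seq).upper().replace("U", "T")) for r in aln]
    else:
        raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'phylip')")
    return _from_records(records, code)


def write_codon_alignment(aln: CodonAlignment, path: str | Path, format: str = "fasta") -> None:
    """Write the raw aligned nucleotide sequences back out (FASTA or
    relaxed sequential PHYLIP)."""
    path = Path(path)
    if format == "fasta":
        recs = [SeqRecord(Seq(aln.nuc_seqs[t]), id=t, description="") for t in aln.taxa]
        SeqIO.write(recs, str(path), "fasta")
    elif format == "phylip":
        buf = io.StringIO()
        buf.write(f" {aln.n_taxa} {3 * aln.length}\n")
        for t in aln.taxa:
            buf.write(f"{t}  {aln.nuc_seqs[t]}\n")
        path.write_text(buf.getvalue())
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# pseudogene screening


@dataclass
class OrfScreenReport:
    """Outcome of the complete-protein screen: per-sequence status and counts.

    status values: "kept", "premature-stop", "frameshift".
    """

    status: dict[str, str]

    @property
    def kept(self) -> list[str]:
        return [t for t, s in self.status.items() if s == "kept"]

    @property
    def excluded(self) -> dict[str, str]:
        return {t: s for t, s in self.status.items() if s != "kept"}

    def to_tsv(self) -> str:
        lines = ["sequence\tstatus"]
        lines += [f"{t}\t{s}" for t, s in self.status.items()]
        return "\n".join(lines) + "\n"


def _gap_runs(seq: str) -> list[int]:
    runs, n = [], 0
    for ch in seq:
        if ch in GAP_CHARS:
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


def _screen_one(seq: str, code: GeneticCode) -> str:
    # frameshift: any gap run whose length is not a multiple of 3 breaks
    # the reading frame relative to the alignment consensus
    if any(r % 3 for r in _gap_runs(seq)):
        return "frameshift"
    # premature stop: a stop codon followed by any further coding material;
    # a stop in the final (possibly gap-trailing) position is a normal
    # terminator
    ncod = len(seq) // 3
    for i in range(ncod):
        triplet = seq[3 * i : 3 * i + 3]
        if code.is_stop(triplet):
            tail = seq[3 * (i + 1) :]
            if any(ch not in GAP_CHARS for ch in tail):
                return "premature-stop"
    return "kept"


def screen_orfs(aln: CodonAlignment) -> tuple[CodonAlignment, OrfScreenReport]:
    """Remove sequences that do not encode a complete protein.

    A sequence is excluded when it contains an internal (non-terminal)
    stop codon, or an alignment gap run whose length is not a multiple of
    three (a frameshifting indel).  Screening is idempotent.
    """
    status = {t: _screen_one(aln.nuc_seqs[t], aln.code) for t in aln.taxa}
    report = OrfScreenReport(status=status)
    kept = report.kept
    if not kept:
        raise AlignmentError("no functional sequences remain after screening")
    return aln.subset(kept), report


# ---------------------------------------------------------------------------
# codon equilibrium frequencies


@dataclass
class CodonFrequencies:
    """Equilibrium frequency vector over the 61 sense codons."""

    scheme: str
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (61,):
            raise ValueError("pi must have 61 entries")
        if np.any(self.pi < 0) or not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must be non-negative and sum to 1")


_SCHEMES = ("equal", "F1x4", "F3x4", "F61")

# pseudocounts guard against zero equilibrium frequencies, which would
# break the reversibility of the rate matrix
_F61_PSEUDOCOUNT = 0.5
_NT_PSEUDOCOUNT = 0.5


def estimate_frequencies(
    aln: CodonAlignment, scheme: str = "F3x4", code: GeneticCode = STANDARD_CODE
) -> CodonFrequencies:
    """Estimate sense-codon equilibrium frequencies.

    equal: uniform 1/61.  F61: observed codon counts (+0.5 pseudocount).
    F1x4/F3x4: products of overall / positional nucleotide frequencies
    over sense codons, renormalized.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {_SCHEMES}")
    if aln.n_taxa == 0 or aln.length == 0:
        raise AlignmentError("cannot estimate frequencies from an empty alignment")
    if scheme == "equal":
        return CodonFrequencies("equal", np.full(61, 1.0 / 61))
    if scheme == "F61":
        counts = np.full(61, _F61_PSEUDOCOUNT)
        observed = aln.codons[aln.codons >= 0]
        np.add.at(counts, observed, 1.0)
        return CodonFrequencies("F61", counts / counts.sum())

    # nucleotide counts from non-missing codons only, per codon position
    nt_counts = np.full((3, 4), _NT_PSEUDOCOUNT)  # rows: codon positions, cols: TCAG
    nt_index = {c: k for k, c in enumerate(NUCLEOTIDES)}
    for ti, taxon in enumerate(aln.taxa):
        seq = aln.nuc_seqs[taxon]
        for site in np.nonzero(aln.codons[ti] >= 0)[0]:
            for pos in range(3):
                nt_counts[pos, nt_index[seq[3 * site + pos]]] += 1
    if scheme == "F1x4":
        overall = nt_counts.sum(axis=0)
        nt_freq = np.tile(overall / overall.sum(), (3, 1))
    else:  # F3x4
        nt_freq = nt_counts / nt_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            nt_freq[0, nt_index[c[0]]] * nt_freq[1, nt_index[c[1]]] * nt_freq[2, nt_index[c[2]]]
            for c in code.sense_codons
        ]
    )
    return CodonFrequencies(scheme, pi / pi.sum())


# ---------------------------------------------------------------------------
# pairwise identities


def pairwise_identity(
    aln: CodonAlignment, a: str, b: str, level: str = "nucleotide"
) -> float:
    """Percent identity between two rows, at nucleotide or amino-acid level.

    Columns where either row is MISSING are excluded from both numerator
    and denominator; the result is rounded to the nearest integer percent.
    """
    if level not in ("nucleotide", "amino-acid"):
        raise ValueError("level must be 'nucleotide' or 'amino-acid'")
    ra, rb = aln.row(a), aln.row(b)
    shared = (ra >= 0) & (rb >= 0)
    if not shared.any():
        raise AlignmentError(f"no shared ungapped columns between {a!r} and {b!r}")
    sites = np.nonzero(shared)[0]
    if level == "nucleotide":
        same = total = 0
        for s in sites:
            ca, cb = aln.codon_string(a, int(s)), aln.codon_string(b, int(s))
            same += sum(x == y for x, y in zip(ca, cb))
            total += 3
        return round(100.0 * same / total)
    code = aln.code
    sense = code.sense_codons
    aa_same = sum(
        code.codon_table[sense[ra[s]]] == code.codon_table[sense[rb[s]]] for s in sites
    )
    return round(100.0 * aa_same / len(sites))
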