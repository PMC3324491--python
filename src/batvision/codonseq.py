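"""In-frame codon alignments: reading, validation, translation, degeneracy.

A codon alignment is the basic substrate of every downstream analysis:
Ka/Ks distances, codon-model likelihoods, ancestral reconstruction and the
convergence test all consume the validated container defined here.  The
genetic code is taken from the NCBI tables shipped with Biopython; the
standard (vertebrate nuclear) code is the default throughout, since the
dim-light-vision genes this pipeline was built around (CRX, SAG, RH1) are
nuclear.

Site degeneracy follows the three-category scheme used by the Li-Wu-Luo
distance: a codon position is 0-fold, 2-fold or 4-fold degenerate according
to whether 0, some, or all 3 of its single-nucleotide mutants are
synonymous.  Three-fold degenerate positions (isoleucine third positions)
are binned as 2-fold, the Li-Wu-Luo convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentIntegrityError, FrameError

NUCLEOTIDES = "ACGT"
GAP_CHARS = frozenset("-.")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True when a<->b is a transition (A<->G or C<->T)."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table.

    ``table`` maps every codon (uppercase DNA) to a one-letter amino acid,
    with ``*`` for stops.  Built from the NCBI tables in Biopython.
    """

    table: dict
    name: str

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.table)}")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = "*"
        return cls(table=table, name=bio.names[0] if bio.names else str(table_id))

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1)

    @property
    def stop_codons(self) -> tuple:
        return tuple(sorted(c for c, aa in self.table.items() if aa == "*"))

    @property
    def sense_codons(self) -> tuple:
        """The sense codons in lexicographic order (61 for the standard code)."""
        return tuple(sorted(c for c, aa in self.table.items() if aa != "*"))

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon) == "*"

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; gaps propagate to ``-`` and ambiguity to ``X``."""
        codon = codon.upper()
        if any(c in GAP_CHARS for c in codon):
            return "-"
        aa = self.table.get(codon)
        if aa is None:  # ambiguity code somewhere in the triplet
            return "X"
        return aa


STANDARD_CODE = GeneticCode.standard()


def classify_degeneracy(codon: str, position: int, code: GeneticCode = STANDARD_CODE) -> int:
    """Degeneracy class (0, 2 or 4) of one position of a sense codon.

    ``position`` is 1-based (1..3).  The class is determined by how many of
    the three single-nucleotide mutants at that position encode the same
    amino acid: none -> 0-fold, all three -> 4-fold, otherwise 2-fold
    (3-fold isoleucine sites fall into the 2-fold bin).  Mutations to stop
    codons count as nonsynonymous.

    Raises ``ValueError`` for stop codons, gaps or ambiguity — callers must
    skip such sites.
    """
    codon = codon.upper()
    if position not in (1, 2, 3):
        raise ValueError(f"position must be 1..3, got {position}")
    aa = code.table.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"cannot classify degeneracy of non-sense codon {codon!r}")
    i = position - 1
    n_syn = 0
    for nt in NUCLEOTIDES:
        if nt == codon[i]:
            continue
        mutant = codon[:i] + nt + codon[i + 1:]
        if code.table[mutant] == aa:
            n_syn += 1
    if n_syn == 0:
        return 0
    if n_syn == 3:
        return 4
    return 2


def degeneracy_profile(code: GeneticCode = STANDARD_CODE) -> dict:
    """Class label for every (sense codon, position) pair."""
    return {
        (codon, pos): classify_degeneracy(codon, pos, code)
        for codon in code.sense_codons
        for pos in (1, 2, 3)
    }


@dataclass
class CodonAlignment:
    """Taxa-indexed, column-aligned in-frame coding sequences.

    Rows are uppercase strings of equal length W with W % 3 == 0. Ambiguity
    characters are preserved on input and treated as missing data by all
    consumers.  Validation rejects internal stop codons (gap-containing
    codons are exempt).
    """

    taxa: list
    seqs: list
    code: GeneticCode = field(default_factory=GeneticCode.standard)

    def __post_init__(self):
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa and seqs must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentIntegrityError(f"duplicate taxon names: {dupes}")
        self.seqs = [s.upper().replace(".", "-") for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise FrameError(f"sequences have unequal lengths: {sorted(lengths)}")
        w = len(self.seqs[0]) if self.seqs else 0
        if w % 3 != 0:
            raise FrameError(f"alignment width {w} is not a multiple of 3")
        self._check_stops()

    def _check_stops(self):
        for taxon, seq in zip(self.taxa, self.seqs):
            for j in range(self.n_codons):
                codon = seq[3 * j: 3 * j + 3]
                if any(c in GAP_CHARS for c in codon):
                    continue
                if self.code.table.get(codon) == "*":
                    raise AlignmentIntegrityError(
                        f"in-frame stop codon {codon} in taxon {taxon!r} at codon index {j + 1}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def width(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_codons(self) -> int:
        return self.width // 3

    def codon(self, row: int, site: int) -> str:
        """Codon of sequence ``row`` at 0-based codon column ``site``."""
        return self.seqs[row][3 * site: 3 * site + 3]

    def codon_column(self, site: int) -> list:
        return [self.codon(i, site) for i in range(self.n_taxa)]

    def sequence_of(self, taxon: str) -> str:
        return self.seqs[self.taxa.index(taxon)]

    def subset(self, taxa: list) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), [self.seqs[i] for i in idx], self.code)


@dataclass
class ProteinAlignment:
    """Aligned amino acid sequences (one column per codon column)."""

    taxa: list
    seqs: list

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence_of(self, taxon: str) -> str:
        return self.seqs[self.taxa.index(taxon)]


@dataclass
class AlignmentSummary:
    """Per-alignment descriptive counts, serializable as JSON/TSV."""

    aligned_length_bp: int
    variable_nt_sites: int
    aa_variable_sites: int
    indel_events: int
    premature_stops: int

    FIELDS = (
        "aligned_length_bp",
        "variable_nt_sites",
        "aa_variable_sites",
        "indel_events",
        "premature_stops",
    )

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        head = "\t".join(self.FIELDS)
        vals = "\t".join(str(getattr(self, f)) for f in self.FIELDS)
        return f"{head}\n{vals}\n"


def read_codon_alignment(path, code: GeneticCode = STANDARD_CODE) -> CodonAlignment:
    """Read a FASTA codon alignment and validate frame and integrity."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FrameError(f"no FASTA records found in {path}")
    taxa = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return CodonAlignment(taxa, seqs, code)


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    """Write FASTA, one sequence per line (round-trip stable)."""
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.seqs):
            fh.write(f">{taxon}\n{seq}\n")


def translate_alignment(aln: CodonAlignment, code: GeneticCode = None) -> ProteinAlignment:
    """Translate every codon column; gap codons -> '-', ambiguity -> 'X'."""
    code = code or aln.code
    prot = []
    for seq in aln.seqs:
        prot.append("".join(
            code.translate_codon(seq[3 * j: 3 * j + 3]) for j in range(len(seq) // 3)
        ))
    return ProteinAlignment(list(aln.taxa), prot)


def _column_variable(chars) -> bool:
    observed = {c for c in chars if c not in GAP_CHARS and c in NUCLEOTIDES}
    return len(observed) >= 2


def summarize_alignment(aln: CodonAlignment) -> AlignmentSummary:
    """Descriptive counts over a validated codon alignment.

    Variable nucleotide sites are columns with >=2 distinct unambiguous,
    non-gap nucleotides; amino-acid-variable sites are codon columns whose
    translations contain >=2 distinct unambiguous residues. Indel events
    count maximal gap runs over all rows.  Premature stops are zero by
    construction (validation rejects them) but the field is reported for
    interface completeness.
    """
    w = aln.width
    variable_nt = sum(
        1 for j in range(w) if _column_variable(s[j] for s in aln.seqs)
    )
    prot = translate_alignment(aln)
    aa_variable = 0
    for j in range(aln.n_codons):
        observed = {p[j] for p in prot.seqs if p[j] not in ("-", "X")}
        if len(observed) >= 2:
            aa_variable += 1
    indel_events = 0
    for seq in aln.seqs:
        in_gap = False
        for c in seq:
            if c in GAP_CHARS:
                if not in_gap:
                    indel_events += 1
                in_gap = True
            else:
                in_gap = False
    return AlignmentSummary(
        aligned_length_bp=w,
        variable_nt_sites=variable_nt,
        aa_variable_sites=aa_variable,
        indel_events=indel_events,
        premature_stops=0,
    )
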