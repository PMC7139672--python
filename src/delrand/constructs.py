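"""Sequence data model for tagged enzyme constructs.

A recombinant construct carries an N-terminal destination/signal peptide
("tag") fused to the mature enzyme.  Residues are addressed in two schemes:

* ``construct`` numbering: 1-based over the full translated protein.
* ``mature`` numbering: position 1 is the first residue of the mature
  enzyme (the residue the crystal structure calls 1); tag residues take
  negative indices counting back from -1.  Index 0 does not exist.

The packaged reference construct is the pelB-tagged Bacillus subtilis
lipase A (BSLA) expression protein: a 23-residue tag followed by the
181-residue mature lipase (204 residues total), together with its
E. coli-optimized ORF.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "ProteinConstruct",
    "ResidueAddress",
    "translate_orf",
    "map_address",
    "extract_region",
    "read_single_fasta",
    "write_fasta",
    "load_bsla_construct",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
_DNA = frozenset("ACGT")

Scheme = Literal["mature", "construct"]


def translate_orf(dna: str) -> str:
    """Translate a coding-strand ORF with the standard genetic code.

    A single trailing stop codon is stripped; an internal stop raises
    ``ValueError``, as do non-ACGT characters and lengths that are not a
    multiple of three.
    """
    seq = dna.upper()
    if not seq:
        raise ValueError("empty ORF")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-ACGT characters in ORF: {sorted(bad)}")
    if len(seq) % 3 != 0:
        raise ValueError(f"ORF length {len(seq)} is not a multiple of 3")
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        pos = protein.index("*") + 1
        raise ValueError(f"premature stop codon at codon {pos}")
    return protein


def _validate_protein(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-canonical residues in {what}: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class ResidueAddress:
    """A residue position in either the mature or construct scheme.

    Mature-scheme indices may be negative (tag residues, counted back from
    -1); construct-scheme indices are strictly positive.  Index 0 is
    invalid in both schemes.
    """

    scheme: Scheme
    index: int

    def __post_init__(self) -> None:
        if self.scheme not in ("mature", "construct"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.index == 0:
            raise ValueError("residue index 0 does not exist (1-based, PDB-style)")
        if self.scheme == "construct" and self.index < 0:
            raise ValueError("construct indices are strictly positive")


@dataclass(frozen=True)
class ProteinConstruct:
    """A tagged expression construct: tag + mature protein + coding ORF.

    Invariants checked at construction: the ORF translates exactly to
    ``tag_sequence + mature_sequence`` followed by a single stop codon,
    and all sequences use canonical alphabets.
    """

    name: str
    tag_sequence: str
    mature_sequence: str
    orf_dna: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "tag_sequence", _validate_protein(self.tag_sequence, "tag"))
        object.__setattr__(
            self, "mature_sequence", _validate_protein(self.mature_sequence, "mature sequence")
        )
        object.__setattr__(self, "orf_dna", self.orf_dna.upper())
        if not self.orf_dna.endswith(("TAA", "TAG", "TGA")):
            raise ValueError("ORF must end with a stop codon")
        translated = translate_orf(self.orf_dna)
        expected = self.tag_sequence + self.mature_sequence
        if translated != expected:
            raise ValueError(
                f"ORF translation ({len(translated)} aa) does not match "
                f"tag+mature protein ({len(expected)} aa)"
            )

    @property
    def tag_length(self) -> int:
        return len(self.tag_sequence)

    @property
    def mature_length(self) -> int:
        return len(self.mature_sequence)

    @property
    def construct_sequence(self) -> str:
        return self.tag_sequence + self.mature_sequence

    def mature_residue(self, index: int) -> str:
        """One-letter code at a (positive) mature index."""
        if not 1 <= index <= self.mature_length:
            raise IndexError(f"mature index {index} out of range 1..{self.mature_length}")
        return self.mature_sequence[index - 1]

    def mature_codon_slice(self, index: int) -> slice:
        """ORF nucleotide slice coding for the given mature residue."""
        if not 1 <= index <= self.mature_length:
            raise IndexError(f"mature index {index} out of range 1..{self.mature_length}")
        start = (self.tag_length + index - 1) * 3
        return slice(start, start + 3)


def map_address(
    construct: ProteinConstruct, addr: ResidueAddress, target_scheme: Scheme
) -> ResidueAddress:
    """Convert a residue address between mature and construct numbering.

    Mature 1 corresponds to construct ``tag_length + 1``; tag residues get
    mature indices -tag_length..-1.  Round-tripping is the identity.
    """
    tag = construct.tag_length
    total = len(construct.construct_sequence)
    if addr.scheme == "construct":
        if not 1 <= addr.index <= total:
            raise IndexError(f"construct index {addr.index} out of range 1..{total}")
        if target_scheme == "construct":
            return addr
        mature = addr.index - tag
        if mature <= 0:
            mature -= 1  # skip the non-existent index 0
        return ResidueAddress("mature", mature)
    # mature scheme
    if addr.index > 0:
        if addr.index > construct.mature_length:
            raise IndexError(
                f"mature index {addr.index} out of range 1..{construct.mature_length}"
            )
        construct_index = addr.index + tag
    else:
        if addr.index < -tag:
            raise IndexError(f"tag index {addr.index} out of range -{tag}..-1")
        construct_index = addr.index + tag + 1
    if target_scheme == "mature":
        return addr
    return ResidueAddress("construct", construct_index)


def extract_region(construct: ProteinConstruct, start: int, end: int) -> str:
    """Inclusive 1-based slice of the mature sequence."""
    if not 1 <= start <= end <= construct.mature_length:
        raise IndexError(
            f"region {start}..{end} out of mature range 1..{construct.mature_length}"
        )
    return construct.mature_sequence[start - 1 : end]


# --- FASTA I/O -------------------------------------------------------------

def read_single_fasta(path) -> tuple[str, str]:
    """Read a one-record FASTA file; returns (id, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_BSLA_TAG = "MGKYLLPTAAAGLLLLAAQPAHM"


def load_bsla_construct() -> ProteinConstruct:
    """The packaged pelB-BSLA reference construct (protein + ORF fixtures)."""
    data = resources.files("delrand") / "data"
    _, protein = _fasta_from_traversable(data / "bsla_construct_protein.fasta")
    _, orf = _fasta_from_traversable(data / "bsla_construct_orf.fasta")
    tag = _BSLA_TAG
    if not protein.startswith(tag):
        raise ValueError("packaged BSLA protein fixture does not start with the pelB tag")
    return ProteinConstruct(
        name="pelB-BSLA",
        tag_sequence=tag,
        mature_sequence=protein[len(tag):],
        orf_dna=orf,
    )


def _fasta_from_traversable(trav) -> tuple[str, str]:
    lines = trav.read_text().splitlines()
    header = lines[0].lstrip(">").split()[0]
    return header, "".join(lines[1:]).upper()
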