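"""Deletion/randomization library design.

The strategy: inside a structurally variable region, delete the two
"middle" residues and saturate the two residues that become the new
junction, each with an NNK degenerate codon.  This yields, per region, a
library of 400 ordered amino-acid junction pairs on a backbone two
residues shorter than wildtype.  The module derives the deleted block and
randomized junction from a target region, enumerates the encoded
variants, names them in the field's substitution/deletion nomenclature
(e.g. ``F41L-ΔW42-ΔD43-K44P``), and constructs fully overlapping
QuickChange-style mutagenic primer pairs that introduce the deletion and
the two degenerate codons simultaneously.

The default "middle" rule places the deleted block so that it starts at
region offset floor((L - deletion_size)/2) + 1 (1-based, L = region
length).  An explicit ``deleted_override`` supports designs that shifted
the block by hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, NamedTuple

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

from . import nnk as _nnk
from .constructs import ProteinConstruct, extract_region, translate_orf

__all__ = [
    "TargetRegion",
    "DeletionRandomizationDesign",
    "PrimerPair",
    "Variant",
    "design_deletion_randomization",
    "enumerate_variants",
    "variant_name",
    "parse_variant_name",
    "design_quickchange_primers",
    "melting_temperature",
]


@dataclass(frozen=True)
class TargetRegion:
    """A contiguous mature-numbered region targeted for deletion/randomization."""

    name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} does not match "
                f"span {self.start}..{self.end}"
            )
        if len(self.sequence) < 4:
            raise ValueError(
                f"{self.name}: region too short ({len(self.sequence)} aa); need two "
                "flanks plus a deletable pair"
            )

    @classmethod
    def from_construct(
        cls, construct: ProteinConstruct, name: str, start: int, end: int
    ) -> "TargetRegion":
        return cls(name, start, end, extract_region(construct, start, end))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DeletionRandomizationDesign:
    """A region's deletion/randomization plan.

    ``designed_template`` is the region sequence after deletion, with ``?``
    at the randomized junction positions; ``degenerate_orf`` is the full
    construct ORF with the deleted codons removed and IUPAC degenerate
    codons at the junction.
    """

    region: TargetRegion
    deleted_positions: tuple[int, int]
    randomized_positions: tuple[int, int]
    designed_template: str
    degenerate_orf: str
    codon: str = "NNK"

    @property
    def deletion_size(self) -> int:
        return self.deleted_positions[1] - self.deleted_positions[0] + 1


def design_deletion_randomization(
    region: TargetRegion,
    construct: ProteinConstruct,
    deletion_size: int = 2,
    deleted_override: tuple[int, int] | None = None,
    codon: str = "NNK",
) -> DeletionRandomizationDesign:
    """Derive the deleted block and randomized junction for a target region.

    By default the deleted block of ``deletion_size`` consecutive residues
    starts in the middle of the region; the residues immediately flanking
    the block become the randomized junction.  Both flanks must lie inside
    the region.
    """
    L = len(region)
    if L < deletion_size + 2:
        raise ValueError(
            f"{region.name}: region length {L} cannot accommodate a "
            f"{deletion_size}-residue deletion plus two junction flanks"
        )
    if extract_region(construct, region.start, region.end) != region.sequence:
        raise ValueError(f"{region.name}: region sequence does not match construct")
    if deleted_override is not None:
        del_start, del_end = deleted_override
        if del_end - del_start + 1 != deletion_size:
            raise ValueError("deleted_override span does not match deletion_size")
    else:
        offset = (L - deletion_size) // 2 + 1  # 1-based within the region
        del_start = region.start + offset - 1
        del_end = del_start + deletion_size - 1
    left, right = del_start - 1, del_end + 1
    if left < region.start or right > region.end:
        raise ValueError(
            f"{region.name}: deleted block {del_start}-{del_end} leaves no junction "
            f"flank inside {region.start}..{region.end}"
        )

    template = []
    for pos in range(region.start, region.end + 1):
        if del_start <= pos <= del_end:
            continue
        template.append("?" if pos in (left, right) else region.sequence[pos - region.start])
    dcodon = _nnk.expand_degenerate_codon(codon)  # validates the IUPAC triplet

    orf = construct.orf_dna
    pieces = []
    for i in range(0, len(orf), 3):
        mature_pos = i // 3 - construct.tag_length + 1
        if del_start <= mature_pos <= del_end:
            continue
        if mature_pos in (left, right):
            pieces.append(dcodon.iupac)
        else:
            pieces.append(orf[i : i + 3])
    return DeletionRandomizationDesign(
        region=region,
        deleted_positions=(del_start, del_end),
        randomized_positions=(left, right),
        designed_template="".join(template),
        degenerate_orf="".join(pieces),
        codon=dcodon.iupac,
    )


class Variant(NamedTuple):
    codons: tuple[str, str]
    aa_pair: str
    mature_sequence: str


def _edited_mature(
    design: DeletionRandomizationDesign, construct: ProteinConstruct, aa_pair: str
) -> str:
    seq = list(construct.mature_sequence)
    left, right = design.randomized_positions
    seq[left - 1] = aa_pair[0]
    seq[right - 1] = aa_pair[1]
    del_start, del_end = design.deleted_positions
    return "".join(seq[: del_start - 1] + seq[del_end:])


def enumerate_variants(
    design: DeletionRandomizationDesign,
    construct: ProteinConstruct,
    include_stops: bool = False,
) -> Iterator[Variant]:
    """Iterate all junction codon pairs and the mature proteins they encode.

    For NNK x NNK this walks 1024 codon pairs; with ``include_stops=False``
    (default) pairs with a stop at either position are dropped, leaving
    31 x 31 codon pairs covering 400 distinct amino-acid pairs.  Stop-pair
    variants are yielded with an empty mature sequence when requested.
    """
    dcodon = _nnk.expand_degenerate_codon(design.codon)
    for c1 in dcodon.codons:
        a1 = _nnk.CODON_TABLE[c1]
        for c2 in dcodon.codons:
            a2 = _nnk.CODON_TABLE[c2]
            pair = a1 + a2
            if "*" in pair:
                if include_stops:
                    yield Variant((c1, c2), pair, "")
                continue
            yield Variant((c1, c2), pair, _edited_mature(design, construct, pair))


def variant_name(
    design: DeletionRandomizationDesign, aa_pair: str, construct: ProteinConstruct
) -> str:
    """Nomenclature string for a junction pair, e.g. ``F41L-ΔW42-ΔD43-K44P``.

    Substitution tokens carry no new-residue letter when the randomized
    position retains the wildtype residue (e.g. ``F41-ΔW42-ΔD43-K44P``).
    """
    if len(aa_pair) != 2 or any(a == "*" for a in aa_pair):
        raise ValueError(f"invalid amino-acid pair {aa_pair!r}")
    left, right = design.randomized_positions
    tokens = []
    wt_left = construct.mature_residue(left)
    tokens.append(f"{wt_left}{left}" + (aa_pair[0] if aa_pair[0] != wt_left else ""))
    for pos in range(design.deleted_positions[0], design.deleted_positions[1] + 1):
        tokens.append(f"Δ{construct.mature_residue(pos)}{pos}")
    wt_right = construct.mature_residue(right)
    tokens.append(f"{wt_right}{right}" + (aa_pair[1] if aa_pair[1] != wt_right else ""))
    return "-".join(tokens)


def parse_variant_name(
    name: str, construct: ProteinConstruct
) -> tuple[tuple[int, int], tuple[int, int], str]:
    """Inverse of :func:`variant_name`.

    Returns ``(deleted_positions, randomized_positions, aa_pair)`` and
    validates every wildtype letter against the construct.
    """
    tokens = name.split("-")
    if len(tokens) < 3:
        raise ValueError(f"cannot parse variant name {name!r}")
    deleted: list[int] = []
    subs: list[tuple[int, str]] = []
    for tok in tokens:
        if tok.startswith("Δ"):
            wt, pos = tok[1], int(tok[2:])
            if construct.mature_residue(pos) != wt:
                raise ValueError(f"{tok}: wildtype residue mismatch")
            deleted.append(pos)
        else:
            wt = tok[0]
            rest = tok[1:]
            new = rest[-1] if rest and rest[-1].isalpha() else wt
            pos = int(rest[:-1] if rest and rest[-1].isalpha() else rest)
            if construct.mature_residue(pos) != wt:
                raise ValueError(f"{tok}: wildtype residue mismatch")
            subs.append((pos, new))
    if len(subs) != 2 or not deleted:
        raise ValueError(f"expected two junction tokens and a deleted block in {name!r}")
    deleted.sort()
    if deleted != list(range(deleted[0], deleted[-1] + 1)):
        raise ValueError("deleted positions are not consecutive")
    subs.sort()
    (lpos, laa), (rpos, raa) = subs
    if lpos != deleted[0] - 1 or rpos != deleted[-1] + 1:
        raise ValueError("junction tokens do not flank the deleted block")
    return (deleted[0], deleted[-1]), (lpos, rpos), laa + raa


# --- Primer construction ---------------------------------------------------

@dataclass(frozen=True)
class PrimerPair:
    """Fully overlapping QuickChange-style mutagenic primers (5'->3').

    The forward primer reads along the coding strand: left homology arm,
    the two degenerate junction codons, right homology arm — with the
    deleted codons absent.  The reverse primer is the reverse complement
    of the same span.  Arm melting temperatures are computed on the
    non-degenerate arms only.
    """

    forward: str
    reverse: str
    left_arm: int
    right_arm: int
    tm_left: float
    tm_right: float
    tm_method_left: str
    tm_method_right: str
    tm_target: float


def melting_temperature(seq: str, method: str = "nearest_neighbor", **params) -> float:
    """Primer-arm melting temperature in degrees Celsius.

    ``wallace``: the rule of thumb 2(A+T) + 4(G+C).  ``nearest_neighbor``:
    unified nearest-neighbor thermodynamics (Allawi & SantaLucia 1997
    table as shipped by Biopython) with its default entropy salt
    correction; keyword parameters are passed through (Na, dnac1, ...).
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"degenerate or invalid symbols in {seq!r}")
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return float(2 * at + 4 * gc)
    if method == "nearest_neighbor":
        return float(_mt.Tm_NN(seq, **params))
    raise ValueError(f"unknown Tm method {method!r}")


def _arm_tm(seq: str, nn_min_len: int = 14) -> tuple[float, str]:
    method = "nearest_neighbor" if len(seq) >= nn_min_len else "wallace"
    return melting_temperature(seq, method), method


def design_quickchange_primers(
    orf: str,
    design: DeletionRandomizationDesign,
    construct: ProteinConstruct,
    min_arm: int = 15,
    tm_target: float = 60.0,
    max_arm: int = 45,
) -> PrimerPair:
    """Build the mutagenic primer pair for a deletion/randomization design.

    Each homology arm starts at ``min_arm`` nucleotides and grows one base
    at a time until its melting temperature reaches ``tm_target`` or
    ``max_arm`` is hit (a warning is emitted in the latter case).
    """
    orf = orf.upper()
    left_pos, right_pos = design.randomized_positions
    left_codon = construct.mature_codon_slice(left_pos)
    right_codon = construct.mature_codon_slice(right_pos)
    if orf[: len(construct.orf_dna)] != construct.orf_dna:
        raise ValueError("ORF does not match the design's construct")

    junction = design.codon * 2

    def grow(start_len: int, leftward: bool) -> tuple[str, float, str]:
        n = start_len
        while True:
            if leftward:
                lo = left_codon.start - n
                if lo < 0:
                    raise ValueError("left arm runs off the 5' end of the ORF")
                arm = orf[lo : left_codon.start]
            else:
                hi = right_codon.stop + n
                if hi > len(orf):
                    raise ValueError("right arm runs off the 3' end of the ORF")
                arm = orf[right_codon.stop : hi]
            tm, method = _arm_tm(arm)
            if tm >= tm_target or n >= max_arm:
                if tm < tm_target:
                    warnings.warn(
                        f"{design.region.name}: arm reached max_arm={max_arm} nt with "
                        f"Tm {tm:.1f} C below target {tm_target:.1f} C"
                    )
                return arm, tm, method
            n += 1

    left_arm, tm_left, m_left = grow(min_arm, leftward=True)
    right_arm, tm_right, m_right = grow(min_arm, leftward=False)
    forward = left_arm + junction + right_arm
    reverse = str(Seq(forward).reverse_complement())
    return PrimerPair(
        forward=forward,
        reverse=reverse,
        left_arm=len(left_arm),
        right_arm=len(right_arm),
        tm_left=tm_left,
        tm_right=tm_right,
        tm_method_left=m_left,
        tm_method_right=m_right,
        tm_target=tm_target,
    )


def translate_degenerate_template(dna: str) -> str:
    """Translate a degenerate ORF, writing ``?`` at multi-residue codons.

    Used to check that a design's degenerate ORF reproduces its full-length
    designed mature sequence.  A trailing stop is stripped.
    """
    if len(dna) % 3 != 0:
        raise ValueError("length not a multiple of 3")
    out = []
    for i in range(0, len(dna), 3):
        codon = _nnk.expand_degenerate_codon(dna[i : i + 3])
        aas = {str(Seq(c).translate()) for c in codon.codons}
        out.append(next(iter(aas)) if len(aas) == 1 else "?")
    prot = "".join(out)
    return prot[:-1] if prot.endswith("*") else prot
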