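"""Degenerate-codon combinatorics and clone-coverage statistics.

An NNK codon (N = A/C/G/T, K = G/T) spans 32 codons encoding all 20 amino
acids plus a single stop (TAG).  A two-NNK junction therefore encodes
32 x 32 = 1024 codon pairs, 400 distinct ordered amino-acid pairs once
stop-containing pairs are dropped.  The coverage statistics model ideal
uniform codon sampling, independent across the two junction positions;
synthesis and transformation biases are deliberately out of scope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "DegenerateCodon",
    "AADistribution",
    "CoverageReport",
    "expand_degenerate_codon",
    "aa_distribution",
    "pair_contains_residue_null",
    "coverage_statistics",
    "NNK",
]

_IUPAC = {k.upper(): v.upper() for k, v in ambiguous_dna_values.items()}

# standard genetic code, materialized once for fast tallies
CODON_TABLE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product("ACGT", repeat=3)
}


@dataclass(frozen=True)
class DegenerateCodon:
    """An IUPAC triplet together with its expanded ACGT codon set."""

    iupac: str
    codons: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.codons)


def expand_degenerate_codon(iupac: str) -> DegenerateCodon:
    """Cartesian expansion of a 3-letter IUPAC degenerate codon."""
    trip = iupac.upper()
    if len(trip) != 3:
        raise ValueError(f"degenerate codon must have 3 symbols, got {trip!r}")
    for sym in trip:
        if sym not in _IUPAC:
            raise ValueError(f"invalid IUPAC nucleotide symbol {sym!r}")
    codons = tuple(
        "".join(bases) for bases in itertools.product(*(_IUPAC[s] for s in trip))
    )
    return DegenerateCodon(trip, codons)


NNK = expand_degenerate_codon("NNK")


@dataclass(frozen=True)
class AADistribution:
    """Codon counts and uniform-sampling probabilities per amino acid.

    The stop codon is tallied under ``*``.  Counts sum to the size of the
    expanded codon set; probabilities sum to 1.
    """

    codon: DegenerateCodon
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return len(self.codon)

    def probability(self, aa: str, condition_on_no_stop: bool = False) -> float:
        denom = self.total - self.counts.get("*", 0) if condition_on_no_stop else self.total
        if condition_on_no_stop and aa == "*":
            return 0.0
        return self.counts.get(aa, 0) / denom

    def amino_probabilities(self, condition_on_no_stop: bool = True) -> dict[str, float]:
        """Probabilities over the 20 amino acids (optionally stop-conditioned)."""
        return {
            aa: self.probability(aa, condition_on_no_stop)
            for aa in sorted(self.counts)
            if aa != "*"
        }


def aa_distribution(codon: DegenerateCodon | str) -> AADistribution:
    if isinstance(codon, str):
        codon = expand_degenerate_codon(codon)
    counts: dict[str, int] = {}
    for c in codon.codons:
        aa = CODON_TABLE[c]
        counts[aa] = counts.get(aa, 0) + 1
    return AADistribution(codon, counts)


def pair_contains_residue_null(
    residue: str, codon: DegenerateCodon | str = NNK, condition_on_no_stop: bool = True
) -> float:
    """Null probability that a random junction pair contains ``residue``.

    With conditioning (default) the per-position probability is
    P(residue | non-stop codon); the pair-level null is 1 - (1 - p)^2.
    This is the "random chance" baseline against which observed residue
    prevalence in screened variants is compared.
    """
    dist = aa_distribution(codon)
    if dist.counts.get(residue, 0) == 0:
        raise ValueError(f"residue {residue!r} is not encodable by {dist.codon.iupac}")
    p = dist.probability(residue, condition_on_no_stop)
    return 1.0 - (1.0 - p) ** 2


@dataclass(frozen=True)
class CoverageReport:
    """Clone-sampling coverage of the junction-pair space.

    ``expected_distinct_pairs`` and ``expected_stop_fraction`` are analytic;
    ``full_coverage_probability`` is a seeded Monte-Carlo estimate of the
    probability that all non-stop pairs are observed at least once.
    """

    n_clones: int
    codon: str
    n_pairs: int
    expected_distinct_pairs: float
    expected_stop_fraction: float
    full_coverage_probability: float
    full_coverage_se: float
    seed: int
    mc_reps: int

    def to_dict(self) -> dict:
        return {
            "n_clones": self.n_clones,
            "codon": self.codon,
            "n_pairs": self.n_pairs,
            "expected_distinct_pairs": self.expected_distinct_pairs,
            "expected_stop_fraction": self.expected_stop_fraction,
            "full_coverage_probability": self.full_coverage_probability,
            "full_coverage_se": self.full_coverage_se,
            "seed": self.seed,
            "mc_reps": self.mc_reps,
        }


def pair_probabilities(codon: DegenerateCodon | str = NNK) -> dict[str, float]:
    """Ordered amino-acid pair probabilities, conditioned on no stop codon."""
    dist = aa_distribution(codon)
    aas = dist.amino_probabilities(condition_on_no_stop=True)
    return {
        a + b: pa * pb for a, pa in aas.items() for b, pb in aas.items()
    }


def coverage_statistics(
    n_clones: int,
    codon: DegenerateCodon | str = NNK,
    seed: int = 0,
    mc_reps: int = 500,
) -> CoverageReport:
    """Coverage statistics for sampling ``n_clones`` from a two-codon junction.

    The expected number of distinct amino-acid pairs is the coupon-collector
    expectation sum(1 - (1 - p_pair)^n) over all ordered non-stop pairs, with
    pair probabilities from the stop-conditioned codon distribution.  The
    expected fraction of clones carrying at least one stop codon is analytic
    (1 - (31/32)^2 for NNK).  Full-coverage probability is estimated by
    seeded Monte Carlo with a binomial standard error.
    """
    if n_clones < 0:
        raise ValueError("n_clones must be non-negative")
    if mc_reps < 1:
        raise ValueError("mc_reps must be positive")
    if isinstance(codon, str):
        codon = expand_degenerate_codon(codon)
    dist = aa_distribution(codon)
    p_stop = dist.probability("*")
    pairs = pair_probabilities(codon)
    probs = np.array(list(pairs.values()))
    expected_distinct = float(np.sum(1.0 - (1.0 - probs) ** n_clones))
    stop_fraction = 1.0 - (1.0 - p_stop) ** 2

    rng = np.random.default_rng(seed)
    n_pairs = len(probs)
    if n_clones == 0:
        hits = 0
    else:
        hits = 0
        for _ in range(mc_reps):
            draws = rng.choice(n_pairs, size=n_clones, p=probs)
            if len(np.unique(draws)) == n_pairs:
                hits += 1
    p_full = hits / mc_reps
    se = math.sqrt(p_full * (1.0 - p_full) / mc_reps)
    return CoverageReport(
        n_clones=n_clones,
        codon=codon.iupac,
        n_pairs=n_pairs,
        expected_distinct_pairs=expected_distinct,
        expected_stop_fraction=stop_fraction,
        full_coverage_probability=p_full,
        full_coverage_se=se,
        seed=seed,
        mc_reps=mc_reps,
    )
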