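"""Screening-outcome statistics for junction-pair libraries.

After plate screening, each sequenced clone contributes a record
(library, ordered junction amino-acid pair, active/inactive).  The
module parses such tables, computes residue prevalence among active vs
inactive variants (e.g. the fraction of active pairs containing a
glycine), per-position residue counts, and a Fisher exact enrichment
test formalizing the active-vs-inactive comparison.

Duplicate pairs are counted as listed by default — sequencing the same
junction pair in two independent clones is two observations.  A
``distinct`` mode collapses duplicates per (library, pair, label).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

import pandas as pd
from scipy import stats

from .constructs import AMINO_ACIDS

__all__ = [
    "ScreeningRecord",
    "PrevalenceResult",
    "EnrichmentResult",
    "parse_pair_table",
    "residue_prevalence",
    "position_counts",
    "enrichment_test",
    "load_bsla_screening_records",
]

Label = Literal["active", "inactive"]
Scope = Literal["any", "first", "second"]


@dataclass(frozen=True)
class ScreeningRecord:
    library: str
    pair: str
    label: Label

    def __post_init__(self) -> None:
        if len(self.pair) != 2 or set(self.pair) - AMINO_ACIDS:
            raise ValueError(f"malformed junction pair {self.pair!r}")
        if self.label not in ("active", "inactive"):
            raise ValueError(f"label must be active/inactive, got {self.label!r}")


def parse_pair_table(source) -> list[ScreeningRecord]:
    """Read a TSV with columns ``library``, ``pair``, ``label``.

    Records are preserved in file order and duplicates retained; libraries
    with no sequenced variants of a label simply contribute no rows.
    """
    # keep_default_na: the pair "NA" (Asn-Ala) must not parse as missing
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = {"library", "pair", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        ScreeningRecord(str(r.library), str(r.pair).upper(), str(r.label))
        for r in df.itertuples(index=False)
    ]


def load_bsla_screening_records() -> list[ScreeningRecord]:
    """The packaged BSLA screening table (entries as printed, repeats kept)."""
    from importlib import resources
    import io

    text = (resources.files("delrand") / "data" / "bsla_screening_pairs.tsv").read_text()
    return parse_pair_table(io.StringIO(text))


def _matches(pair: str, residue: str, scope: Scope) -> bool:
    if scope == "any":
        return residue in pair
    if scope == "first":
        return pair[0] == residue
    if scope == "second":
        return pair[1] == residue
    raise ValueError(f"unknown position scope {scope!r}")


@dataclass(frozen=True)
class PrevalenceResult:
    """Count/fraction of records of one label whose pair matches a residue."""

    residue: str
    position_scope: Scope
    label: Label
    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total

    @property
    def percent(self) -> int:
        """Display percent, rounded half-up to an integer."""
        pct = Decimal(100 * self.count) / Decimal(self.total)
        return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def residue_prevalence(
    records: Iterable[ScreeningRecord],
    residue: str,
    position_scope: Scope = "any",
    label: Label = "active",
    distinct: bool = False,
) -> PrevalenceResult:
    """Prevalence of a residue among one label's junction pairs.

    ``distinct=True`` collapses duplicate (library, pair) entries before
    counting; the default counts entries as listed.
    """
    subset = [r for r in records if r.label == label]
    if distinct:
        seen = set()
        uniq = []
        for r in subset:
            key = (r.library, r.pair)
            if key not in seen:
                seen.add(key)
                uniq.append(r)
        subset = uniq
    if not subset:
        raise ValueError(f"no {label} records to compute prevalence over")
    count = sum(_matches(r.pair, residue, position_scope) for r in subset)
    return PrevalenceResult(residue, position_scope, label, count, len(subset))


def position_counts(
    records: Iterable[ScreeningRecord],
    library: str,
    label: Label,
    position: Literal["first", "second"],
) -> dict[str, int]:
    """Residue counts at one junction position, entries as listed."""
    if position not in ("first", "second"):
        raise ValueError(f"position must be first/second, got {position!r}")
    idx = 0 if position == "first" else 1
    counts: dict[str, int] = {}
    for r in records:
        if r.library == library and r.label == label:
            aa = r.pair[idx]
            counts[aa] = counts.get(aa, 0) + 1
    return counts


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher exact test of residue presence vs activity.

    ``contingency`` rows are (residue present, residue absent), columns
    (active, inactive).  The odds ratio uses the Haldane-Anscombe +0.5
    correction when any cell is zero.
    """

    residue: str
    position_scope: Scope
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def enrichment_test(
    records: Iterable[ScreeningRecord], residue: str, position_scope: Scope = "any"
) -> EnrichmentResult:
    records = list(records)
    a = sum(r.label == "active" and _matches(r.pair, residue, position_scope) for r in records)
    b = sum(r.label == "inactive" and _matches(r.pair, residue, position_scope) for r in records)
    c = sum(r.label == "active" and not _matches(r.pair, residue, position_scope) for r in records)
    d = sum(r.label == "inactive" and not _matches(r.pair, residue, position_scope) for r in records)
    if a + c == 0 or b + d == 0:
        raise ValueError("both activity labels must be present")
    table = [[a, b], [c, d]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if 0 in (a, b, c, d):
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(
        residue=residue,
        position_scope=position_scope,
        contingency=((a, b), (c, d)),
        odds_ratio=float(orr),
        p_value=float(p),
    )
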