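"""Structure-ensemble superposition and per-residue variability profiling.

Candidate regions for deletion/randomization are stretches of residues
whose Cα positions vary strongly across superposed homologous structures.
The module consumes a reference structure plus an ensemble of member
structures with externally supplied residue correspondences (e.g. from an
aligned FASTA produced by a structural aligner); it does not perform
multiple structure alignment itself.

Each member is rigidly superposed onto the reference (Kabsch least
squares over its mapped Cα pairs, or over an explicit fit selection such
as a rigid core), and per reference residue the profile records the
quadratic-mean Cα deviation across the members that map it.  Maximal runs
of high-RMSD residues are then called as candidate regions, with an
exclusion set for catalytically required stretches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnsembleMember",
    "StructureEnsemble",
    "VariabilityProfile",
    "RegionCall",
    "kabsch_superpose",
    "variability_profile",
    "call_regions",
    "correspondence_from_alignment",
]


@dataclass(frozen=True)
class EnsembleMember:
    """One ensemble structure: Cα coordinates plus a reference correspondence.

    ``mapping`` sends a reference mature index to a row of ``coords``;
    it must be injective and may be partial (gaps allowed).
    """

    name: str
    coords: np.ndarray  # (n, 3) Cα coordinates, Å
    mapping: dict[int, int]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"{self.name}: coords must be (n, 3)")
        object.__setattr__(self, "coords", coords)
        rows = list(self.mapping.values())
        if len(set(rows)) != len(rows):
            raise ValueError(f"{self.name}: correspondence is not injective")
        if rows and (min(rows) < 0 or max(rows) >= len(coords)):
            raise ValueError(f"{self.name}: correspondence points outside coords")


@dataclass(frozen=True)
class StructureEnsemble:
    """Reference Cα coordinates (by mature index) and ensemble members."""

    reference: dict[int, np.ndarray]
    members: tuple[EnsembleMember, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "reference",
            {int(i): np.asarray(c, dtype=float) for i, c in self.reference.items()},
        )
        object.__setattr__(self, "members", tuple(self.members))
        if not self.reference:
            raise ValueError("empty reference")
        for m in self.members:
            shared = set(m.mapping) & set(self.reference)
            if len(shared) < 3:
                raise ValueError(f"{m.name}: fewer than 3 residues mapped to reference")


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets (b onto a).

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_b @ rotation.T + translation`` minimizes the paired RMSD
    against ``coords_a``.  The rotation is proper (determinant +1).
    Requires at least three non-collinear pairs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinear/coincident sets leave the rotation under-determined
    if min(np.linalg.matrix_rank(a0, tol=1e-8), np.linalg.matrix_rank(b0, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear or coincident) point set")
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    diff = (b @ rot.T + trans) - a
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return rot, trans, rmsd


_MISSING = float("nan")


@dataclass(frozen=True)
class VariabilityProfile:
    """Per-reference-residue RMS Cα deviation and member coverage.

    ``rmsd[i]`` is NaN (missing), not 0 Å, for residues no member maps.
    """

    indices: tuple[int, ...]
    rmsd: np.ndarray
    coverage: np.ndarray

    def as_dict(self) -> dict[int, tuple[float, int]]:
        return {
            i: (float(r), int(c))
            for i, r, c in zip(self.indices, self.rmsd, self.coverage)
        }

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("mature_index\trmsd_A\tcoverage\n")
            for i, r, c in zip(self.indices, self.rmsd, self.coverage):
                rtxt = "NA" if np.isnan(r) else f"{r:.6f}"
                fh.write(f"{i}\t{rtxt}\t{int(c)}\n")


def variability_profile(
    ensemble: StructureEnsemble, fit_residues: set[int] | None = None
) -> VariabilityProfile:
    """Per-residue RMS Cα deviation across globally superposed members.

    Each member is superposed onto the reference once, using all its
    mapped residues by default or the intersection with ``fit_residues``
    when a rigid-core selection is given.  Per reference residue i,
    rmsd(i) is the quadratic mean, over members mapping i, of the Cα
    distance after that member's global superposition.
    """
    if not ensemble.members:
        raise ValueError("empty ensemble")
    indices = sorted(ensemble.reference)
    idx_pos = {i: k for k, i in enumerate(indices)}
    sq = np.zeros(len(indices))
    cov = np.zeros(len(indices), dtype=int)
    for m in ensemble.members:
        shared = sorted(set(m.mapping) & set(ensemble.reference))
        fit = shared if fit_residues is None else sorted(set(shared) & fit_residues)
        if len(fit) < 3:
            raise ValueError(f"{m.name}: fewer than 3 residues available for fitting")
        ref_fit = np.array([ensemble.reference[i] for i in fit])
        mem_fit = m.coords[[m.mapping[i] for i in fit]]
        rot, trans, _ = kabsch_superpose(ref_fit, mem_fit)
        moved = m.coords @ rot.T + trans
        for i in shared:
            d = moved[m.mapping[i]] - ensemble.reference[i]
            sq[idx_pos[i]] += float(d @ d)
            cov[idx_pos[i]] += 1
    rmsd = np.where(cov > 0, np.sqrt(sq / np.maximum(cov, 1)), _MISSING)
    return VariabilityProfile(tuple(indices), rmsd, cov)


@dataclass(frozen=True)
class RegionCall:
    """A maximal run of consecutive high-variability residues."""

    start: int
    end: int
    mean_rmsd: float
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1


def call_regions(
    profile: VariabilityProfile,
    threshold: float = 2.0,
    min_length: int = 2,
    min_coverage: int = 1,
    exclusion: set[int] | frozenset[int] = frozenset(),
) -> list[RegionCall]:
    """Call candidate regions from a variability profile.

    A candidate is a maximal run of consecutive residues with
    rmsd >= ``threshold`` and coverage >= ``min_coverage``, of length at
    least ``min_length``.  Runs containing an excluded index (e.g. a
    catalytic stretch) are returned flagged ``excluded=True`` so callers
    can drop them from design candidates while still reporting them.
    The 2.0 Å default threshold is a shipped convention, always
    user-overridable and echoed into output.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    lookup = profile.as_dict()
    calls: list[RegionCall] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if len(run) < min_length:
            return
        vals = [lookup[i][0] for i in run]
        hit = sorted(set(run) & set(exclusion))
        calls.append(
            RegionCall(
                start=run[0],
                end=run[-1],
                mean_rmsd=float(np.mean(vals)),
                excluded=bool(hit),
                exclusion_reason=f"contains excluded residues {hit}" if hit else "",
            )
        )

    prev = None
    for i in sorted(lookup):
        r, c = lookup[i]
        ok = (not np.isnan(r)) and r >= threshold and c >= min_coverage
        if ok and prev is not None and i == prev + 1 and run:
            run.append(i)
        elif ok:
            flush(run)
            run = [i]
        else:
            flush(run)
            run = []
        prev = i
    flush(run)
    return calls


def correspondence_from_alignment(ref_aligned: str, member_aligned: str) -> dict[int, int]:
    """Reference-index -> member-index map from two aligned sequences.

    Both strings come from the same alignment (equal length, ``-`` gaps);
    indices are 1-based over the ungapped sequences.  Columns gapped on
    either side are skipped.
    """
    if len(ref_aligned) != len(member_aligned):
        raise ValueError("aligned sequences differ in length")
    mapping: dict[int, int] = {}
    ri = mi = 0
    for a, b in zip(ref_aligned, member_aligned):
        if a != "-":
            ri += 1
        if b != "-":
            mi += 1
        if a != "-" and b != "-":
            mapping[ri] = mi
    return mapping
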