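"""Superposition and variability profiling against independent oracles."""

import numpy as np
import pytest

from delrand.io_cli import build_ensemble_from_pdbs, make_structure_fixture
from delrand.structvar import (
    EnsembleMember,
    StructureEnsemble,
    call_regions,
    correspondence_from_alignment,
    kabsch_superpose,
    variability_profile,
)


def quaternion_superpose_rmsd(a, b):
    """Horn's closed-form quaternion method; independent of the SVD route."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = b0.T @ a0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w = np.linalg.eigvalsh(k)[-1]
    ssd = ((a0**2).sum() + (b0**2).sum()) - 2.0 * w
    return float(np.sqrt(max(ssd, 0.0) / len(a)))


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def test_kabsch_identity():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    rot, trans, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(trans, 0.0, atol=1e-12)


def test_kabsch_pure_translation():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    shifted = pts + np.array([5.0, 0, 0])
    rot, trans, rmsd = kabsch_superpose(pts, shifted)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(trans, [-5.0, 0, 0], atol=1e-12)


def test_kabsch_toy_case_matches_quaternion_oracle():
    """90° z-rotation with one point perturbed by 1 Å."""
    a = np.array([[1.0, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]])
    rot90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
    b = a @ rot90.T
    b[0] += np.array([0.0, 0, 1.0])
    _, _, rmsd = kabsch_superpose(a, b)
    assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-6)


def test_kabsch_matches_quaternion_oracle_on_random_sets():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = rng.integers(3, 11)
        a = rng.normal(size=(n, 3)) * 5
        b = a @ random_rotation(rng).T + rng.normal(size=3) * 10
        b += rng.normal(size=(n, 3)) * rng.uniform(0, 1.5)
        rot, _, rmsd = kabsch_superpose(a, b)
        assert abs(np.linalg.det(rot) - 1.0) < 1e-9  # proper rotation
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-8)


def test_kabsch_rejects_degenerate_inputs():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="degenerate"):
        kabsch_superpose(line, line)
    two = np.zeros((2, 3))
    with pytest.raises(ValueError, match="at least 3"):
        kabsch_superpose(two, two)


def _helix(n):
    i = np.arange(1, n + 1)
    th = np.deg2rad(100.0) * i
    return np.stack([2.3 * np.cos(th), 2.3 * np.sin(th), 1.5 * i], axis=1)


def _identity_member(name, coords):
    return EnsembleMember(name, coords, {i + 1: i for i in range(len(coords))})


def test_profile_zero_for_exact_copies():
    ref = _helix(30)
    ensemble = StructureEnsemble(
        {i + 1: ref[i] for i in range(30)},
        tuple(_identity_member(f"m{k}", ref.copy()) for k in range(4)),
    )
    profile = variability_profile(ensemble)
    np.testing.assert_allclose(profile.rmsd, 0.0, atol=1e-9)
    assert (profile.coverage == 4).all()


def test_profile_recovers_constructed_loop_displacement_exactly():
    """3.0 Å loop shift recovered to 1e-6 with rigid-core superposition."""
    rng = np.random.default_rng(11)
    ref = _helix(60)
    members = []
    for k in range(5):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords = ref.copy()
        coords[39:46] += 3.0 * direction  # residues 40..46
        members.append(_identity_member(f"m{k}", coords))
    ensemble = StructureEnsemble({i + 1: ref[i] for i in range(60)}, tuple(members))
    core = set(range(1, 40)) | set(range(47, 61))
    prof = variability_profile(ensemble, fit_residues=core).as_dict()
    for i in range(40, 47):
        assert prof[i][0] == pytest.approx(3.0, abs=1e-6)
    for i in sorted(core):
        assert prof[i][0] == pytest.approx(0.0, abs=1e-6)
    # default all-residue fit absorbs part of the shift but stays close
    default = variability_profile(ensemble).as_dict()
    for i in range(40, 47):
        assert default[i][0] == pytest.approx(3.0, abs=1.0)
    for i in sorted(core):
        assert default[i][0] < 1.0


def test_profile_recovers_loop_displacement_through_pdb_fixture(tmp_path):
    """Same construction via the on-disk fixture; PDB has 3-decimal coords."""
    manifest = make_structure_fixture(
        tmp_path, n_residues=60, loop_span=(40, 46), displacement=3.0, n_members=5, seed=11
    )
    ensemble = build_ensemble_from_pdbs(
        manifest["reference"], manifest["members"], manifest["alignment"]
    )
    core = set(range(1, 40)) | set(range(47, 61))
    prof = variability_profile(ensemble, fit_residues=core).as_dict()
    for i in range(40, 47):
        assert prof[i][0] == pytest.approx(3.0, abs=5e-3)
    for i in sorted(core):
        assert prof[i][0] == pytest.approx(0.0, abs=5e-3)


def test_single_member_profile_equals_kabsch_deviations():
    rng = np.random.default_rng(5)
    ref = _helix(25)
    member = ref + rng.normal(size=ref.shape) * 0.4
    ensemble = StructureEnsemble(
        {i + 1: ref[i] for i in range(25)}, (_identity_member("m", member),)
    )
    profile = variability_profile(ensemble)
    rot, trans, _ = kabsch_superpose(ref, member)
    moved = member @ rot.T + trans
    per_res = np.linalg.norm(moved - ref, axis=1)
    np.testing.assert_allclose(profile.rmsd, per_res, atol=1e-10)


def test_profile_invariant_under_member_rigid_motion():
    rng = np.random.default_rng(7)
    ref = _helix(20)
    member = ref + rng.normal(size=ref.shape) * 0.5
    rot = random_rotation(rng)
    moved = member @ rot.T + np.array([10.0, -4.0, 2.0])
    refd = {i + 1: ref[i] for i in range(20)}
    p1 = variability_profile(StructureEnsemble(refd, (_identity_member("a", member),)))
    p2 = variability_profile(StructureEnsemble(refd, (_identity_member("b", moved),)))
    np.testing.assert_allclose(p1.rmsd, p2.rmsd, atol=1e-9)


def test_loop_rmsd_monotone_in_displacement_scale(tmp_path):
    values = []
    for k, scale in enumerate((1.0, 1.5, 2.0, 3.0)):
        d = tmp_path / f"s{k}"
        manifest = make_structure_fixture(
            d, n_residues=50, loop_span=(20, 26), displacement=3.0 * scale, n_members=4, seed=3
        )
        ens = build_ensemble_from_pdbs(
            manifest["reference"], manifest["members"], manifest["alignment"]
        )
        prof = variability_profile(ens).as_dict()
        values.append(np.mean([prof[i][0] for i in range(20, 27)]))
    assert values == sorted(values)


def test_member_with_too_few_mapped_residues_rejected():
    ref = _helix(10)
    refd = {i + 1: ref[i] for i in range(10)}
    with pytest.raises(ValueError, match="fewer than 3"):
        StructureEnsemble(refd, (EnsembleMember("m", ref[:2], {1: 0, 2: 1}),))


def test_empty_ensemble_rejected():
    ref = _helix(5)
    ensemble = StructureEnsemble({i + 1: ref[i] for i in range(5)}, ())
    with pytest.raises(ValueError, match="empty"):
        variability_profile(ensemble)


# --- Region calling --------------------------------------------------------

def _profile_from_values(values):
    import delrand.structvar as sv

    rmsd = np.array(values, dtype=float)
    cov = np.ones(len(values), dtype=int)
    return sv.VariabilityProfile(tuple(range(1, len(values) + 1)), rmsd, cov)


def test_call_regions_empty_on_flat_profile():
    assert call_regions(_profile_from_values([0.0] * 10), threshold=1.0) == []


def test_call_regions_toy_profile_matches_brute_force():
    """Profile [0,0,5,5,5,0,2,5,5,0], threshold 3, min_length 2 -> (3-5), (8-9)."""
    values = [0, 0, 5, 5, 5, 0, 2, 5, 5, 0]
    calls = call_regions(_profile_from_values(values), threshold=3.0, min_length=2)
    assert [(c.start, c.end) for c in calls] == [(3, 5), (8, 9)]
    # brute-force run scan
    hits = [i + 1 for i, v in enumerate(values) if v >= 3.0]
    runs = []
    for i in hits:
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    assert [(r[0], r[-1]) for r in runs if len(r) >= 2] == [(c.start, c.end) for c in calls]


def test_call_regions_exclusion_flag():
    values = [0, 0, 5, 5, 5, 0, 2, 5, 5, 0]
    calls = call_regions(
        _profile_from_values(values), threshold=3.0, min_length=2, exclusion={4}
    )
    assert calls[0].excluded is True and "4" in calls[0].exclusion_reason
    assert calls[1].excluded is False


def test_call_regions_respects_min_coverage():
    import delrand.structvar as sv

    rmsd = np.array([5.0] * 6)
    cov = np.array([3, 3, 1, 1, 3, 3])
    profile = sv.VariabilityProfile(tuple(range(1, 7)), rmsd, cov)
    calls = call_regions(profile, threshold=3.0, min_length=2, min_coverage=2)
    assert [(c.start, c.end) for c in calls] == [(1, 2), (5, 6)]


def test_missing_residues_are_nan_not_zero():
    ref = _helix(10)
    refd = {i + 1: ref[i] for i in range(10)}
    member = EnsembleMember("partial", ref[:5], {i + 1: i for i in range(5)})
    profile = variability_profile(StructureEnsemble(refd, (member,)))
    d = profile.as_dict()
    assert np.isnan(d[10][0]) and d[10][1] == 0
    assert not np.isnan(d[1][0])


def test_correspondence_from_alignment():
    mapping = correspondence_from_alignment("AC-GT", "A-TGT")
    # gapped columns (C/-, -/T) are skipped on either side
    assert mapping == {1: 1, 3: 3, 4: 4}
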