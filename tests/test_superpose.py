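import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopscape import (RegionSpec, SyntheticSpec, displacement_profile,
                       generate_structure, kabsch_fit, refine_superposition,
                       rmsd)
from loopscape.errors import FitError, PairingError, RefinementError

from conftest import SMALL_LOOPS, random_rotation


def _cloud(rng, n=20, scale=10.0):
    return rng.normal(0, scale, (n, 3))


def test_self_fit_is_identity():
    rng = np.random.default_rng(0)
    P = _cloud(rng)
    fit = kabsch_fit(P, P)
    assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(fit.translation, 0.0, atol=1e-9)
    assert fit.kept_mask.all() and fit.n_cycles_run == 0


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_known_transform_recovery(seed):
    """Fitting Q = R0 P + t0 recovers (R0, t0) to 1e-6 and rmsd <= 1e-9."""
    rng = np.random.default_rng(seed)
    P = _cloud(rng, n=30)
    R0 = random_rotation(rng)
    t0 = rng.normal(0, 5, 3)
    Q = P @ R0.T + t0
    fit = kabsch_fit(P, Q)
    assert fit.rmsd <= 1e-9
    np.testing.assert_allclose(fit.rotation, R0, atol=1e-6)
    np.testing.assert_allclose(fit.translation, t0, atol=1e-6)


def test_rotation_is_always_proper():
    rng = np.random.default_rng(7)
    for _ in range(20):
        P, Q = _cloud(rng, 5), _cloud(rng, 5)
        R = kabsch_fit(P, Q).rotation
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)


def test_mirror_image_keeps_positive_residual():
    """A reflected point set cannot be fit to zero by a proper rotation;
    the fitted rmsd still beats a dense rotation-grid minimum."""
    from _oracles import rotation_grid_min_rmsd
    rng = np.random.default_rng(11)
    P = _cloud(rng, 4)
    Q = P.copy()
    Q[:, 0] *= -1.0  # mirror
    fit = kabsch_fit(P, Q)
    assert fit.rmsd > 0.1
    grid = Rotation.random(100_000, rng=np.random.default_rng(0)).as_matrix()
    assert fit.rmsd <= rotation_grid_min_rmsd(P, Q, grid) + 1e-9


def test_rmsd_trivial_cases():
    P = np.array([[0.0, 0.0, 0.0]])
    Q = np.array([[3.0, 4.0, 0.0]])
    assert rmsd(P, P) == 0.0
    assert rmsd(P, Q) == pytest.approx(5.0)


def test_rmsd_matches_direct_formula():
    rng = np.random.default_rng(21)
    P, Q = _cloud(rng), _cloud(rng)
    direct = np.sqrt(np.sum((P - Q) ** 2) / len(P))
    assert rmsd(P, Q) == pytest.approx(direct, abs=1e-12)


def test_rmsd_symmetry_after_superposition():
    rng = np.random.default_rng(5)
    P, Q = _cloud(rng), _cloud(rng)
    assert rmsd(P, Q, superpose=True) == pytest.approx(
        rmsd(Q, P, superpose=True), abs=1e-9)


def test_common_rigid_transform_invariance():
    rng = np.random.default_rng(9)
    P, Q = _cloud(rng), _cloud(rng)
    R0, t0 = random_rotation(rng), rng.normal(0, 5, 3)
    before = rmsd(P, Q, superpose=True)
    after = rmsd(P @ R0.T + t0, Q @ R0.T + t0, superpose=True)
    assert after == pytest.approx(before, abs=1e-6)


def test_pairing_and_degeneracy_errors():
    rng = np.random.default_rng(1)
    with pytest.raises(PairingError):
        kabsch_fit(_cloud(rng, 5), _cloud(rng, 6))
    with pytest.raises(FitError):
        kabsch_fit(_cloud(rng, 2), _cloud(rng, 2))
    line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    with pytest.raises(FitError, match="collinear"):
        kabsch_fit(line, line)


def test_refine_without_outliers_matches_plain_fit():
    rng = np.random.default_rng(3)
    P = _cloud(rng, 50)
    Q = P + rng.normal(0, 0.05, P.shape)
    plain = kabsch_fit(P, Q)
    ref = refine_superposition(P, Q)
    assert ref.n_cycles_run == 1
    assert ref.kept_mask.all()
    assert ref.rmsd == pytest.approx(plain.rmsd, abs=1e-12)
    np.testing.assert_allclose(ref.rotation, plain.rotation, atol=1e-12)


@pytest.mark.parametrize("seed", [13, 17, 19])
def test_refine_rejects_planted_outlier(seed):
    """One pair displaced by 10 Å is dropped; the kept rmsd reflects the
    planted noise level (sigma*sqrt(3)), not the outlier."""
    rng = np.random.default_rng(seed)
    sigma = 0.05
    P = _cloud(rng, 50)
    Q = P + rng.normal(0, sigma, P.shape)
    Q[7] += np.array([10.0, 0.0, 0.0])
    fit = refine_superposition(P, Q)
    assert not fit.kept_mask[7]
    assert fit.kept_mask.sum() >= 45
    noise_level = sigma * np.sqrt(3)
    assert fit.rmsd < 1.2 * noise_level
    assert fit.rmsd > 0.2 * noise_level


def test_refine_kept_rmsd_monotone_in_cycles():
    rng = np.random.default_rng(23)
    P = _cloud(rng, 60)
    Q = P + rng.normal(0, 0.05, P.shape)
    for i in (3, 11, 28):
        Q[i] += rng.normal(0, 4.0, 3)
    values = [refine_superposition(P, Q, max_cycles=k).rmsd
              for k in (1, 2, 3, 5)]
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


def test_refine_all_rejected_raises():
    # two clusters so far apart that rejection spirals down to < 3 pairs
    rng = np.random.default_rng(2)
    P = _cloud(rng, 12)
    Q = P.copy()
    Q[::2] += 40.0
    Q += rng.normal(0, 0.01, Q.shape)
    with pytest.raises((RefinementError, FitError)):
        refine_superposition(P, Q, max_cycles=10, reject_sigma=0.5)


def test_refine_max_cycles_zero_is_plain_fit():
    rng = np.random.default_rng(4)
    P, Q = _cloud(rng), _cloud(rng)
    fit = refine_superposition(P, Q, max_cycles=0)
    assert fit.n_cycles_run == 0 and fit.kept_mask.all()


# ---------------------------------------------------------------------------
# displacement profiles


def test_displacement_profile_self_is_zero(small_spec):
    s, _ = generate_structure(small_spec)
    prof = displacement_profile(s, "A", s, "A", core=list(SMALL_LOOPS),
                                core_is_exclusion=True)
    assert np.allclose(prof.displacement, 0.0, atol=1e-9)


def test_displacement_profile_planted_translation(small_spec):
    """Loop residues translated by exactly 4 Å show up at 4 Å; the rigid
    core stays at zero."""
    s, _ = generate_structure(small_spec)
    moved = copy.deepcopy(s)
    shift = np.array([4.0, 0.0, 0.0])
    loop = RegionSpec("L3", 32, 44)
    for r in moved.residues("A"):
        if loop.contains(r.seq_num):
            for a in r.atoms:
                a.coords = a.coords + shift
    prof = displacement_profile(s, "A", moved, "A", core=[loop],
                                core_is_exclusion=True)
    for (cid, num), d in zip(prof.residue_keys, prof.displacement):
        if loop.contains(num):
            assert d == pytest.approx(4.0, abs=1e-6)
        else:
            assert d == pytest.approx(0.0, abs=1e-6)


def test_displacement_profile_invariance_under_rigid_motion(small_spec):
    s, _ = generate_structure(small_spec)
    moved = copy.deepcopy(s)
    rng = np.random.default_rng(6)
    R0, t0 = random_rotation(rng), rng.normal(0, 8, 3)
    for r in moved.residues("A"):
        for a in r.atoms:
            a.coords = R0 @ a.coords + t0
    base = displacement_profile(s, "A", s, "A", core=list(SMALL_LOOPS),
                                core_is_exclusion=True)
    prof = displacement_profile(s, "A", moved, "A", core=list(SMALL_LOOPS),
                                core_is_exclusion=True)
    np.testing.assert_allclose(prof.displacement, base.displacement, atol=1e-6)


def test_displacement_profile_reports_unpaired(small_spec):
    s, _ = generate_structure(small_spec)
    shorter = copy.deepcopy(s)
    dropped = shorter.chains["A"].pop()
    prof = displacement_profile(s, "A", shorter, "A", core=list(SMALL_LOOPS),
                                core_is_exclusion=True)
    assert ("A", dropped.seq_num) in prof.unpaired
    assert len(prof) == small_spec.n_residues - 1


def test_displacement_profile_needs_core():
    from conftest import make_ca_chain
    a = make_ca_chain(1, 10)
    with pytest.raises(FitError):
        displacement_profile(a, "A", a, "A", core=[RegionSpec("c", 500, 600)])
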