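import copy
import dataclasses

import numpy as np
import pytest

from loopscape import (RegionSpec, classify_conformer, displacement_profile,
                       generate_conformer_pair, generate_structure,
                       loop_charge, per_loop_rmsd, pocket_geometry,
                       split_region)
from loopscape.errors import ConfigurationError, EmptySelectionError
from loopscape.loop_analysis import TSABGL_LOOPS
from loopscape.structure_io import AtomRecord, Residue, Structure

from conftest import SMALL_LOOPS, make_ca_chain, random_rotation


# ---------------------------------------------------------------------------
# per-loop r.m.s.d.


@pytest.mark.parametrize("mode", ["core-frame", "loop-local"])
def test_duplicated_structure_gives_zero_matrix(small_spec, mode):
    s, _ = generate_structure(small_spec)
    res = per_loop_rmsd([(s, "A"), (s, "A"), (s, "A")], SMALL_LOOPS, mode=mode)
    assert res.mode == mode
    for name, M in res.matrices.items():
        assert M.shape == (3, 3)
        np.testing.assert_allclose(M, 0.0, atol=1e-9)
        np.testing.assert_allclose(M, M.T)


@pytest.mark.parametrize("mode", ["core-frame", "loop-local"])
def test_swung_loop_dominates_both_modes(small_spec, mode):
    folded, straight, truth = generate_conformer_pair(small_spec)
    res = per_loop_rmsd([(folded, "A"), (straight, "A")], SMALL_LOOPS, mode=mode)
    summary = res.summary()
    flex_max = summary[truth.flexible_loop][1]
    for name, (lo, hi) in summary.items():
        if name != truth.flexible_loop:
            assert flex_max > hi


def _perturb_loop(s, region, sigma, rng):
    out = copy.deepcopy(s)
    for r in out.residues("A"):
        if region.contains(r.seq_num):
            for a in r.atoms:
                a.coords = a.coords + rng.normal(0, sigma, 3)
    return out


@pytest.mark.parametrize("seed", range(20))
def test_perturbed_loop_has_largest_rmsd(seed, small_spec):
    """An ensemble where one loop carries sigma=0.3 Å noise and the rest is
    rigid ranks that loop's max pairwise r.m.s.d. first."""
    base_spec = dataclasses.replace(small_spec, noise_sigma=0.0,
                                    swing_amplitude=0.0, seed=seed)
    s, _ = generate_structure(base_spec)
    rng = np.random.default_rng(seed + 1000)
    target = SMALL_LOOPS[2]
    ensemble = [(s, "A")] + [(_perturb_loop(s, target, 0.3, rng), "A")
                             for _ in range(2)]
    res = per_loop_rmsd(ensemble, SMALL_LOOPS, mode="core-frame")
    summary = res.summary()
    target_max = summary[target.name][1]
    assert all(target_max > hi for name, (lo, hi) in summary.items()
               if name != target.name)


def test_per_loop_rmsd_needs_two_chains(small_spec):
    s, _ = generate_structure(small_spec)
    with pytest.raises(ConfigurationError):
        per_loop_rmsd([(s, "A")], SMALL_LOOPS)
    with pytest.raises(ConfigurationError):
        per_loop_rmsd([(s, "A"), (s, "A")], SMALL_LOOPS, mode="banana")


def test_unresolvable_loop_names_the_chain(small_spec):
    s, _ = generate_structure(small_spec)
    bad = [RegionSpec("LX", 900, 950)]
    with pytest.raises(EmptySelectionError, match="LX"):
        per_loop_rmsd([(s, "A"), (s, "A")], bad)


# ---------------------------------------------------------------------------
# split_region


def test_split_region_published_sub_spans():
    l3 = RegionSpec("L3", 300, 325)
    n_term, c_term = split_region(l3, 310)
    assert (n_term.start, n_term.end) == (300, 310)
    assert (c_term.start, c_term.end) == (311, 325)
    assert len(n_term) == 11
    # recombination restores the original residue set
    assert len(n_term) + len(c_term) == len(l3)


def test_split_region_minimal_and_errors():
    a, b = split_region(RegionSpec("r", 1, 2), 1)
    assert (a.start, a.end, b.start, b.end) == (1, 1, 2, 2)
    with pytest.raises(ConfigurationError):
        split_region(RegionSpec("r", 1, 5), 5)
    with pytest.raises(ConfigurationError):
        split_region(RegionSpec("r", 1, 5), 0)


# ---------------------------------------------------------------------------
# conformer classification


def test_self_profile_is_reference_equal(small_spec):
    s, _ = generate_structure(small_spec)
    prof = displacement_profile(s, "A", s, "A", core=list(SMALL_LOOPS),
                                core_is_exclusion=True)
    c = classify_conformer(prof, SMALL_LOOPS[2], threshold=3.0)
    assert c.label == "reference-equal"
    assert c.max_disp == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_planted_swing_classified_and_localized(seed, small_spec):
    """The swung twin is labelled as the alternate conformer with maximum
    displacement at the planted residue and magnitude ~ the amplitude."""
    spec = dataclasses.replace(small_spec, seed=seed)
    folded, straight, truth = generate_conformer_pair(spec)
    prof = displacement_profile(folded, "A", straight, "A",
                                core=list(SMALL_LOOPS), core_is_exclusion=True)
    c = classify_conformer(prof, spec.flexible_span(), threshold=3.0,
                           alternate_label="straight")
    assert c.label == "straight"
    assert c.max_disp == pytest.approx(spec.swing_amplitude, abs=0.5)
    planted_peak = int(np.argmax(truth.planted_displacement)) + 1
    assert abs(c.argmax_residue[1] - planted_peak) <= 1


def test_classification_threshold_monotone(small_spec):
    folded, straight, _ = generate_conformer_pair(small_spec)
    prof = displacement_profile(folded, "A", straight, "A",
                                core=list(SMALL_LOOPS), core_is_exclusion=True)
    region = small_spec.flexible_span()
    labels = [classify_conformer(prof, region, threshold=t).label
              for t in (0.5, 2.0, 5.0, 8.0, 20.0)]
    # once reference-equal, raising the threshold never flips it back
    seen_equal = False
    for lab in labels:
        if lab == "reference-equal":
            seen_equal = True
        assert not (seen_equal and lab != "reference-equal")
    assert labels[-1] == "reference-equal"
    with pytest.raises(ConfigurationError):
        classify_conformer(prof, region, threshold=-1.0)


def test_classification_empty_region_errors(small_spec):
    s, _ = generate_structure(small_spec)
    prof = displacement_profile(s, "A", s, "A", core=list(SMALL_LOOPS),
                                core_is_exclusion=True)
    with pytest.raises(EmptySelectionError):
        classify_conformer(prof, RegionSpec("x", 900, 905))


# ---------------------------------------------------------------------------
# pocket geometry


def _loop_on_line(chain, nums, origin, direction, name="GLY", spacing=3.8):
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    residues = []
    for i, num in enumerate(nums):
        xyz = origin + spacing * i * direction
        r = Residue(chain, num, "", name)
        r.atoms.append(AtomRecord("CA", "C", xyz))
        residues.append(r)
    return residues


def _two_loop_structure(gap=5.0):
    s = Structure(id="toy")
    l2 = _loop_on_line("A", range(10, 16), [0, 0, 0], [1, 0, 0])
    l3 = _loop_on_line("A", range(30, 36), [0, gap, 0], [1, 0, 0])
    s.chains["A"] = sorted(l2 + l3, key=lambda r: r.seq_num)
    return s


def test_parallel_loops_min_distance():
    s = _two_loop_structure(gap=5.0)
    geo = pocket_geometry(s, "A", RegionSpec("L2", 10, 15),
                          RegionSpec("L3", 30, 35))
    assert geo.min_l2_l3 == pytest.approx(5.0)
    assert "L2-vs-L3" in geo.definition


def test_shared_atom_gives_zero_distance():
    s = _two_loop_structure(gap=0.0)
    geo = pocket_geometry(s, "A", RegionSpec("L2", 10, 15),
                          RegionSpec("L3", 30, 35))
    assert geo.min_l2_l3 == 0.0


def test_pocket_rim_pairs_metric():
    s = _two_loop_structure(gap=5.0)
    geo = pocket_geometry(s, "A", RegionSpec("L2", 10, 15),
                          RegionSpec("L3", 30, 35),
                          rim_pairs=[(10, 35), (15, 30)])
    # residue 10 at (0,0,0), residue 35 at (19,5,0)
    assert geo.entrance_width == pytest.approx(np.hypot(19, 5))
    assert geo.definition == "max-ca-dist:rim_pairs"


def test_pocket_metrics_rigid_invariance():
    s = _two_loop_structure(gap=5.0)
    moved = copy.deepcopy(s)
    rng = np.random.default_rng(12)
    R0, t0 = random_rotation(rng), rng.normal(0, 10, 3)
    for r in moved.residues("A"):
        for a in r.atoms:
            a.coords = R0 @ a.coords + t0
    l2, l3 = RegionSpec("L2", 10, 15), RegionSpec("L3", 30, 35)
    g1 = pocket_geometry(s, "A", l2, l3)
    g2 = pocket_geometry(moved, "A", l2, l3)
    assert g1.min_l2_l3 == pytest.approx(g2.min_l2_l3, abs=1e-9)
    assert g1.entrance_width == pytest.approx(g2.entrance_width, abs=1e-9)


def test_swing_widens_interloop_gap(small_spec):
    """The straight twin's L2-L3 gap differs from the folded twin's in the
    planted direction (the swing moves L3 radially away)."""
    folded, straight, _ = generate_conformer_pair(small_spec)
    l2, l3 = SMALL_LOOPS[1], SMALL_LOOPS[2]
    g_f = pocket_geometry(folded, "A", l2, l3)
    g_s = pocket_geometry(straight, "A", l2, l3)
    assert g_s.min_l2_l3 > g_f.min_l2_l3


# ---------------------------------------------------------------------------
# formal charge


def _chain_of(res_names, start=1):
    s = Structure(id="toy")
    s.chains["A"] = []
    for i, name in enumerate(res_names):
        r = Residue("A", start + i, "", name)
        r.atoms.append(AtomRecord("CA", "C", [float(i), 0, 0]))
        s.chains["A"].append(r)
    return s


@pytest.mark.parametrize("names,expected", [
    (["GLY"] * 5, 0),
    (["ASP", "GLU", "LYS", "ARG"], 0),
    (["ASP", "ASP", "GLU"], -3),
    (["ASP", "ASP", "ASP", "ASP", "LYS"], -3),
    (["HIS", "HIS", "GLY"], 0),
])
def test_loop_charge_from_structure(names, expected):
    s = _chain_of(names)
    assert loop_charge(s, RegionSpec("r", 1, len(names))) == expected


def test_loop_charge_from_sequence():
    assert loop_charge("DEKR", RegionSpec("r", 1, 4)) == 0
    assert loop_charge("DDE", RegionSpec("r", 1, 3)) == -3
    assert loop_charge("GDDDDKG", RegionSpec("r", 2, 6)) == -3
    # unknown types count zero
    assert loop_charge("DXXE", RegionSpec("r", 1, 4)) == -2


def test_tsabgl_loop_definitions_have_published_lengths():
    lengths = {rg.name: len(rg) for rg in TSABGL_LOOPS}
    assert lengths == {"L1": 16, "L2": 9, "L3": 26, "L4": 19}
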