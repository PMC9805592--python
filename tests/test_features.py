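import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rigid_transform
from grappi.errors import PssmError
from grappi.features import (FEATURE_BLOCKS, buried_surface_area,
                             buried_surface_area_map, conservation_score,
                             edge_strength, featurize, parse_pssm,
                             residue_charge, residue_polarity_onehot,
                             residue_type_onehot)
from grappi.fixtures import FixtureSpec, make_pssm, make_reference_complex
from grappi.graph import GraphBuildConfig, build_graph
from grappi.structure import Atom, CANONICAL_RESIDUES, Residue, Structure


# --- edge interaction strength ---------------------------------------------

def test_edge_strength_printed_endpoints():
    assert round(float(edge_strength(0.0)), 2) == 1.96
    assert float(edge_strength(100.0)) < 1e-15


def test_edge_strength_known_values():
    assert float(edge_strength(4.0)) == pytest.approx(1.0, abs=1e-12)
    # direct evaluation of tanh(-x/2 + 2) + 1 at the interface cutoff
    assert float(edge_strength(8.5)) == pytest.approx(0.0219739, abs=1e-6)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=20.0), st.floats(min_value=1e-6, max_value=1.0))
def test_edge_strength_strictly_decreasing_and_bounded(x, dx):
    lo, hi = float(edge_strength(x + dx)), float(edge_strength(x))
    assert lo < hi
    assert 0.0 < lo <= np.tanh(2) + 1


def test_edge_strength_rejects_negative_distance():
    with pytest.raises(ValueError):
        edge_strength(-0.5)


# --- per-residue lookups ----------------------------------------------------

def test_type_onehot_canonical_and_noncanonical():
    v = residue_type_onehot("ALA")
    assert v.sum() == 1 and v[CANONICAL_RESIDUES.index("ALA")] == 1
    with pytest.warns(UserWarning):
        assert residue_type_onehot("MSE").sum() == 0
    for name in CANONICAL_RESIDUES:
        assert set(residue_type_onehot(name)) <= {0.0, 1.0}


@pytest.mark.parametrize("name,charge", [
    ("LYS", 1.0), ("ARG", 1.0), ("GLU", -1.0), ("ASP", -1.0),
    ("HIS", 0.1), ("GLY", 0.0), ("XXX", 0.0),
])
def test_residue_charge_table(name, charge):
    assert residue_charge(name) == charge


def test_polarity_onehot_classes():
    # order: apolar, polar, positive, negative
    np.testing.assert_array_equal(residue_polarity_onehot("ASP"), [0, 0, 0, 1])
    np.testing.assert_array_equal(residue_polarity_onehot("SER"), [0, 1, 0, 0])
    np.testing.assert_array_equal(residue_polarity_onehot("LYS"), [0, 0, 1, 0])
    np.testing.assert_array_equal(residue_polarity_onehot("LEU"), [1, 0, 0, 0])
    for name in CANONICAL_RESIDUES:
        assert residue_polarity_onehot(name).sum() == 1


# --- buried surface area ----------------------------------------------------

def test_bsa_zero_for_distant_chains():
    s = Structure(id="far")
    s.chains["A"] = [Residue("A", 1, "", "ALA",
                             [Atom("CA", "C", (0, 0, 0)), Atom("CB", "C", (1.5, 0, 0))])]
    s.chains["B"] = [Residue("B", 1, "", "GLY", [Atom("CA", "C", (40, 0, 0))])]
    assert buried_surface_area(s, ("A", 1, "", "ALA")) == pytest.approx(0.0, abs=1e-3)


def test_bsa_positive_at_interface(ref_complex):
    bsa = buried_surface_area_map(ref_complex)
    interface_res = ref_complex.chains["A"][4]  # mid-chain, faces chain B
    assert bsa[interface_res.key] > 1.0
    assert all(v >= 0.0 for v in bsa.values())


def _sasa_oracle(coords, radii, which, probe=1.4, n_points=1000):
    """Independent Shrake-Rupley: Fibonacci sphere sampling at 10x density."""
    k = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    r_xy = np.sqrt(1.0 - z * z)
    sphere = np.stack([r_xy * np.cos(k * phi), r_xy * np.sin(k * phi), z], axis=1)
    total = 0.0
    for i in which:
        ri = radii[i] + probe
        points = coords[i] + ri * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            rj = radii[j] + probe
            accessible &= np.sum((points - coords[j]) ** 2, axis=1) > rj * rj
        total += accessible.mean() * 4.0 * np.pi * ri * ri
    return total


def test_bsa_matches_independent_point_sampling_oracle():
    """Single-atom 'residue' partially buried by a constructed blocker."""
    s = Structure(id="toy")
    s.chains["A"] = [Residue("A", 1, "", "GLY", [Atom("CA", "C", (0, 0, 0))])]
    s.chains["B"] = [Residue("B", 1, "", "GLY", [Atom("CA", "C", (4.0, 0, 0))])]
    bsa = buried_surface_area(s, ("A", 1, "", "GLY"))
    coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
    radii = np.array([1.7, 1.7])  # Bondi carbon
    free = 4.0 * np.pi * (1.7 + 1.4) ** 2  # isolated atom: full sphere
    complexed = _sasa_oracle(coords, radii, which=[0])
    # production sampling uses 100 points/atom: each point covers ~1.2 A^2
    # of this sphere, so agree within ~2 points' worth of area
    assert bsa == pytest.approx(free - complexed, abs=2.5)


def test_bsa_invariant_under_rigid_transform(ref_complex):
    rot, trans = random_rigid_transform(np.random.default_rng(5))
    moved = ref_complex.transform(rot, trans)
    b0 = buried_surface_area_map(ref_complex)
    b1 = buried_surface_area_map(moved)
    for key in b0:
        assert b1[key] == pytest.approx(b0[key], abs=1e-3)


# --- PSSM parsing and conservation ------------------------------------------

def test_pssm_round_trip(ref_complex, tmp_path):
    paths = make_pssm(ref_complex, seed=3, out_dir=tmp_path)
    for cid, path in paths.items():
        profile = parse_pssm(path, cid)
        assert profile.scores.shape == (len(ref_complex.chains[cid]), 20)
        assert np.all(profile.information_content > 0)


def test_pssm_missing_residue_row_is_an_error(ref_complex, tmp_path):
    (path,) = [make_pssm(ref_complex, seed=3, out_dir=tmp_path)["A"]]
    lines = path.read_text().splitlines()
    del lines[3]  # drop the row of residue 3
    path.write_text("\n".join(lines) + "\n")
    profile = parse_pssm(path, "A")
    with pytest.raises(PssmError, match="residue 3"):
        profile.row(3)


def test_pssm_code_mismatch_detected(ref_complex, tmp_path):
    from grappi.features import align_profile
    path = make_pssm(ref_complex, seed=3, out_dir=tmp_path)["A"]
    lines = path.read_text().splitlines()
    fields = lines[1].split("\t")
    fields[1] = "G" if fields[1] != "G" else "A"
    lines[1] = "\t".join(fields)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(PssmError, match="does not match"):
        align_profile(parse_pssm(path, "A"), ref_complex)


def test_pssm_malformed_row_reports_line(tmp_path):
    path = tmp_path / "bad.pssm"
    path.write_text("h\n1\tA\t1\t2\n")
    with pytest.raises(PssmError, match=":2"):
        parse_pssm(path, "A")


def test_conservation_is_own_column_readout(ref_complex, tmp_path):
    paths = make_pssm(ref_complex, seed=3, out_dir=tmp_path)
    profile = parse_pssm(paths["A"], "A")
    res = ref_complex.chains["A"][0]
    node = (res.chain_id, res.number, res.insertion_code, res.name)
    expected = profile.scores[profile.row(res.number),
                              CANONICAL_RESIDUES.index(res.name)]
    assert conservation_score(profile, node) == expected
    assert conservation_score(profile, node) in profile.scores[profile.row(res.number)]


# --- featurize assembly ------------------------------------------------------

def _profiles_for(structure, tmp_path):
    paths = make_pssm(structure, seed=9, out_dir=tmp_path)
    return {cid: parse_pssm(p, cid) for cid, p in paths.items()}


@pytest.mark.parametrize("enabled,width", [
    (("type", "charge", "polarity", "bsa"), 26),
    (("type", "charge", "polarity", "bsa", "pssm", "ic", "conservation"), 48),
    (("pssm",), 20),
])
def test_feature_width_bookkeeping(ref_complex, tmp_path, enabled, width):
    config = GraphBuildConfig(node_features=enabled)
    graph = build_graph(ref_complex, config)
    profiles = _profiles_for(ref_complex, tmp_path) if any(
        f in enabled for f in ("pssm", "ic", "conservation")) else None
    featurize(graph, ref_complex, profiles=profiles, config=config)
    assert graph.node_features.shape == (graph.n_nodes, width)
    assert len(graph.feature_names) == width
    assert sum(FEATURE_BLOCKS[b] for b in enabled) == width


def test_featurize_fills_edge_strengths(ref_graph):
    np.testing.assert_allclose(ref_graph.external_edge_feat,
                               edge_strength(ref_graph.external_edge_dist))
    np.testing.assert_allclose(ref_graph.internal_edge_feat,
                               edge_strength(ref_graph.internal_edge_dist))


def test_onehot_blocks_sum_to_one(ref_graph):
    type_block = ref_graph.node_features[:, :20]
    polarity_block = ref_graph.node_features[:, 21:25]
    assert np.all(np.isin(type_block.sum(axis=1), [0.0, 1.0]))
    assert np.all(np.isin(polarity_block.sum(axis=1), [0.0, 1.0]))


def test_pssm_enabled_without_profile_raises(ref_complex):
    config = GraphBuildConfig(node_features=("pssm",))
    graph = build_graph(ref_complex, config)
    with pytest.raises(PssmError, match="no profile"):
        featurize(graph, ref_complex, profiles=None, config=config)


def test_features_invariant_under_rigid_transform(ref_complex, ref_graph):
    rot, trans = random_rigid_transform(np.random.default_rng(17))
    moved = ref_complex.transform(rot, trans)
    g = build_graph(moved)
    featurize(g, moved)
    np.testing.assert_allclose(g.node_features, ref_graph.node_features, atol=1e-3)
    np.testing.assert_allclose(g.external_edge_feat, ref_graph.external_edge_feat,
                               atol=1e-6)
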