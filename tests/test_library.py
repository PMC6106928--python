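"""Conformer extraction, clustering, and library serialization."""

import dataclasses
import math

import numpy as np
import pytest

from nucleofit.fixtures import A_FORM_PRESET, FixtureSpec, generate_chain, strip
from nucleofit.geometry import circular_difference, wrap_angle
from nucleofit.library import (
    LibraryError,
    build_library,
    builtin_library,
    euclidean_angle_distance,
    extract_annotated_residues,
    k_medoids,
    load_library,
    mcq_distance,
    neural_gas,
    save_library,
)


class TestExtraction:
    def test_ten_mer_yields_eight_interior_records(self):
        chain = generate_chain(FixtureSpec(sequence="GCAUGCAUGC"))
        records = extract_annotated_residues([chain])
        # independent completeness scan: residues with a 5' phosphate and a
        # 3' neighbour are the only ones with all 12 torsions defined
        expected = sum(
            1 for i, res in enumerate(chain.residues)
            if "P" in res.atoms and i < len(chain) - 1)
        assert len(records) == expected == 8

    def test_backbone_only_chain_yields_nothing(self, helix12):
        assert extract_annotated_residues([strip(helix12, "nucleoside")]) == []

    def test_residue_missing_o2prime_excluded(self):
        chain = generate_chain(FixtureSpec(sequence="GCAUGCAUGC"))
        del chain.residues[4].atoms["O2'"]
        records = extract_annotated_residues([chain])
        assert len(records) == 7
        assert not any(chain.residues[4].label in r.id for r in records)

    def test_coordinates_are_in_canonical_frame(self, helix12):
        for conf in extract_annotated_residues([helix12]):
            assert np.allclose(conf.atom_coords["C4'"], 0.0, atol=1e-12)
            c3 = conf.atom_coords["C3'"]
            assert abs(c3[1]) < 1e-9 and abs(c3[2]) < 1e-9  # on +x axis
            assert abs(conf.atom_coords["C5'"][2]) < 1e-9   # in xy plane


class TestDistances:
    def test_wrap_aware_single_component(self):
        assert euclidean_angle_distance([179], [-179]) == pytest.approx(2.0)

    def test_identity(self):
        assert euclidean_angle_distance([10, 20], [10, 20]) == 0.0

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(5)
        u = rng.uniform(-180, 180, 6)
        v = rng.uniform(-180, 180, 6)
        expect = math.sqrt(sum(
            min(abs(a - b), 360 - abs(a - b)) ** 2 for a, b in zip(u, v)))
        assert euclidean_angle_distance(u, v) == pytest.approx(expect)

    def test_mcq_distance_delegates_to_circular_mean(self):
        assert mcq_distance([10, 0], [0, 0]) == pytest.approx(5.004, abs=1e-2)


def _planted_blobs(rng, centers, sigma, n_per):
    pts, labels = [], []
    for li, c in enumerate(centers):
        for _ in range(n_per):
            pts.append([wrap_angle(x + rng.normal(0, sigma)) for x in c])
            labels.append(li)
    return np.array(pts), labels


class TestNeuralGas:
    def test_identical_points_k1(self):
        pts = np.tile([30.0, -120.0], (8, 1))
        proto = neural_gas(pts, 1, seed=0)
        assert np.allclose([circular_difference(a, b)
                            for a, b in zip(proto[0], pts[0])], 0.0, atol=1e-6)

    @pytest.mark.parametrize("distance", ["euclidean", "mcq"])
    def test_planted_two_blob_recovery(self, distance):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            centers = [[-45.0, 60.0], [45.0, 150.0]]  # 90 deg apart, sigma 5
            pts, _ = _planted_blobs(rng, centers, 5.0, 25)
            protos = neural_gas(pts, 2, distance=distance, seed=seed)
            ok = all(
                min(max(circular_difference(p[d], c[d]) for d in range(2))
                    for p in protos) < 3.0
                for c in centers)
            hits += ok
        assert hits >= 9

    def test_k_equals_n_saturates_on_data_points(self):
        # with one prototype per sample and the annealing run long enough,
        # every prototype converges onto a distinct data point
        rng = np.random.default_rng(2)
        pts = rng.uniform(-180, 180, size=(5, 3))
        protos = neural_gas(pts, 5, seed=4, epochs=120)
        matched = set()
        for p in protos:
            dists = [euclidean_angle_distance(p, x) for x in pts]
            j = int(np.argmin(dists))
            assert dists[j] < 5.0
            matched.add(j)
        assert len(matched) == 5

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(LibraryError):
            neural_gas(np.zeros((3, 2)), 4)


class TestKMedoids:
    def test_three_points_on_line_brute_force(self):
        # total-distance-minimizing medoid of {0, 1, 10} is the middle point
        pts = np.array([[0.0], [1.0], [10.0]])
        costs = [sum(euclidean_angle_distance(pts[m], p) for p in pts)
                 for m in range(3)]
        assert int(np.argmin(costs)) == 1
        assert k_medoids(pts, 1, seed=0) == [1]

    def test_k_equals_n_zero_cost(self):
        pts = np.array([[0.0], [40.0], [90.0], [-90.0]])
        assert k_medoids(pts, 4, seed=1) == [0, 1, 2, 3]

    def test_planted_blobs_split_between_medoids(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            centers = [[-60.0, 0.0], [60.0, 120.0]]
            pts, labels = _planted_blobs(rng, centers, 5.0, 20)
            meds = k_medoids(pts, 2, seed=seed)
            assert {labels[m] for m in meds} == {0, 1}

    def test_local_minimum_no_single_swap_improves(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-180, 180, size=(12, 2))
        meds = k_medoids(pts, 3, seed=3)
        dmat = np.array([[euclidean_angle_distance(a, b) for b in pts] for a in pts])

        def cost(m):
            return dmat[:, m].min(axis=1).sum()

        base = cost(meds)
        for i in range(3):
            for h in range(12):
                if h in meds:
                    continue
                trial = sorted(meds[:i] + [h] + meds[i + 1:])
                assert cost(trial) >= base - 1e-9


class TestBuildLibrary:
    def test_degenerate_single_cluster_per_type(self, helix12):
        lib = build_library(extract_annotated_residues([helix12]),
                            k1=1, k2=1, seed=0)
        for t in "ACGU":
            assert len(lib.by_type(t)) == 1

    def test_planted_backbone_chi_classes_recovered(self, helix12):
        # 3 backbone classes x 2 chi classes planted on a real conformer's
        # coordinates; expect one prototype per class within 5 deg MCQ
        template = extract_annotated_residues([helix12])[0]
        rng = np.random.default_rng(42)
        backbones = [
            {"alpha": -60, "beta": 175, "gamma": 55, "delta": 80,
             "epsilon": -150, "zeta": -70},
            {"alpha": 160, "beta": -70, "gamma": 170, "delta": 145,
             "epsilon": -100, "zeta": 60},
            {"alpha": 50, "beta": 60, "gamma": -170, "delta": 85,
             "epsilon": 170, "zeta": 179},
        ]
        chis = [-160.0, 60.0]
        precursors = []
        planted = []
        for b_i, back in enumerate(backbones):
            for c_i, chi in enumerate(chis):
                planted.append((back, chi))
                for k in range(12):
                    tors = dict(template.torsions)
                    for name, val in back.items():
                        tors[name] = wrap_angle(val + rng.normal(0, 2.0))
                    tors["chi"] = wrap_angle(chi + rng.normal(0, 2.0))
                    precursors.append(dataclasses.replace(
                        template, id=f"planted-{b_i}-{c_i}-{k}", torsions=tors))
        lib = build_library(precursors, k1=3, k2=2, seed=0)
        protos = lib.by_type(template.base_type)
        assert len(protos) == 6
        for back, chi in planted:
            best = min(
                max(circular_difference(p.torsions[n], v)
                    for n, v in {**back, "chi": chi}.items())
                for p in protos)
            assert best < 5.0

    def test_deterministic_under_seed(self, helix12):
        pre = extract_annotated_residues([helix12])
        lib1 = build_library(pre, k1=2, k2=2, seed=7)
        lib2 = build_library(pre, k1=2, k2=2, seed=7)
        assert save_library(lib1) == save_library(lib2)

    def test_prototype_is_subcluster_medoid(self, helix12):
        # exhaustive check: no other member of the same (group, sub) cell has
        # a smaller total chi-distance than the stored prototype
        pre = extract_annotated_residues([helix12])
        lib = build_library(pre, k1=2, k2=2, seed=0)
        assert {c.base_type for c in lib.conformers} == set("ACGU")
        for proto in lib.conformers:
            cell = [c for c in pre if (c.base_type, c.group_id, c.sub_id)
                    == (proto.base_type, proto.group_id, proto.sub_id)]
            assert proto in cell

            def total(member):
                return sum(euclidean_angle_distance(
                    [member.torsions["chi"]], [o.torsions["chi"]]) for o in cell)

            assert all(total(proto) <= total(m) + 1e-9 for m in cell)

    def test_query_by_type_returns_only_that_type(self, helix_library):
        for t in "ACGU":
            assert all(c.base_type == t for c in helix_library.by_type(t))

    def test_missing_type_absent_with_library_still_valid(self):
        chain = generate_chain(FixtureSpec(sequence="GGGGGG"))
        lib = build_library(extract_annotated_residues([chain]), k1=1, k2=1)
        assert lib.by_type("A") == []
        assert len(lib.by_type("G")) >= 1

    def test_empty_precursors_rejected(self):
        with pytest.raises(LibraryError):
            build_library([])


class TestSerialization:
    def test_save_load_round_trip(self, helix_library):
        text = save_library(helix_library)
        back = load_library(text)
        assert back.name == helix_library.name
        assert back.distance == helix_library.distance
        assert len(back.conformers) == len(helix_library.conformers)
        for a, b in zip(helix_library.conformers, back.conformers):
            assert a.id == b.id and a.base_type == b.base_type
            for n in a.torsions:
                assert abs(a.torsions[n] - b.torsions[n]) < 5.1e-4
            for n in a.atom_coords:
                assert np.allclose(a.atom_coords[n], b.atom_coords[n], atol=5.1e-5)
        # second round trip is lossless byte for byte
        assert save_library(back) == save_library(load_library(save_library(back)))

    def test_truncated_file_names_schema_error(self, helix_library):
        text = save_library(helix_library)
        with pytest.raises(LibraryError, match="JSON"):
            load_library(text[: len(text) // 2])

    def test_missing_field_named(self, helix_library):
        import json
        doc = json.loads(save_library(helix_library))
        del doc["distance"]
        with pytest.raises(LibraryError, match="distance"):
            load_library(json.dumps(doc))

    def test_empty_library_rejected(self, helix_library):
        import json
        doc = json.loads(save_library(helix_library))
        doc["conformers"] = []
        with pytest.raises(LibraryError, match="empty"):
            load_library(json.dumps(doc))


class TestBuiltinLibrary:
    def test_covers_all_types_and_is_deterministic(self):
        lib = builtin_library()
        for t in "ACGU":
            assert len(lib.by_type(t)) >= 2  # several chi rotamers each
        assert save_library(lib) == save_library(builtin_library())
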