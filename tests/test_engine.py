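"""Fitting engine: candidate search, LJ scoring, and the remodel pipeline."""

import dataclasses
import math

import numpy as np
import pytest

from nucleofit import _chem
from nucleofit.engine import (
    EngineConfig,
    EngineError,
    compute_energies,
    find_candidates,
    lj_energy,
    prune_to_promising,
    remodel,
)
from nucleofit.evaluate import annotate_canonical_pairs, detect_clashes, inf_score
from nucleofit.fixtures import FixtureSpec, generate_chain, perturb, strip
from nucleofit.geometry import compute_torsions, wrap_angle
from nucleofit.library import ConformerLibrary, extract_annotated_residues
from nucleofit.structure import StructureError, parse_task_sequence, write_pdb

CFG = EngineConfig()


class TestLjEnergy:
    def test_zero_crossing_at_radius_sum(self):
        assert lj_energy(1.70 + 1.52, 1.70, 1.52, CFG) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth_at_sigma_times_sixth_root_of_two(self):
        sigma = 1.70 + 1.55
        assert lj_energy(2 ** (1 / 6) * sigma, 1.70, 1.55, CFG) == pytest.approx(-CFG.lj_epsilon)

    def test_hard_overlap_capped(self):
        assert lj_energy(0.1, 1.70, 1.70, CFG) == CFG.energy_cap

    def test_zero_beyond_cutoff(self):
        assert lj_energy(CFG.pair_cutoff + 0.01, 1.8, 1.8, CFG) == 0.0

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            lj_energy(0.0, 1.7, 1.7, CFG)


def _library_from(chain, **kw):
    from nucleofit.library import build_library
    return build_library(extract_annotated_residues([chain]), **kw)


class TestFindCandidates:
    def test_exact_backbone_match_ranks_first_with_zero_mcq(self, helix12, helix_library):
        profile = compute_torsions(helix12)
        idx = 5
        cands = find_candidates(helix12.residues[idx], idx, profile,
                                helix_library, "nucleoside", CFG)
        assert cands[0].match_mcq == pytest.approx(0.0, abs=1e-3)

    def test_terminal_residue_with_partial_angles(self, helix12, helix_library):
        profile = compute_torsions(helix12)
        cands = find_candidates(helix12.residues[0], 0, profile,
                                helix_library, "nucleoside", CFG)
        assert cands  # alpha undefined at the 5' end: no error, fewer angles

    def test_retention_window_drops_distant_conformers(self, helix12):
        # library of two conformers: one at MCQ ~0, one far beyond the window
        confs = extract_annotated_residues([helix12])
        near = next(c for c in confs if c.base_type == "G")
        far = dataclasses.replace(
            near, id="far",
            torsions={**near.torsions,
                      **{n: wrap_angle(near.torsions[n] + 40.0)
                         for n in ("alpha", "beta", "gamma", "delta",
                                   "epsilon", "zeta")}})
        lib = ConformerLibrary(name="two", distance="euclidean",
                               algorithm="neural_gas", conformers=[near, far])
        profile = compute_torsions(helix12)
        idx = next(i for i, r in enumerate(helix12.residues)
                   if r.base_type == "G" and 0 < i < len(helix12) - 1)
        cands = find_candidates(helix12.residues[idx], idx, profile, lib,
                                "nucleoside", CFG)
        assert [c.conformer.id for c in cands] == [near.id]

    def test_missing_base_type_rejected(self, helix12):
        confs = [c for c in extract_annotated_residues([helix12])
                 if c.base_type == "G"]
        lib = ConformerLibrary(name="gonly", distance="euclidean",
                               algorithm="neural_gas", conformers=confs)
        profile = compute_torsions(helix12)
        idx = next(i for i, r in enumerate(helix12.residues) if r.base_type == "A")
        with pytest.raises(EngineError, match="no conformer of type A"):
            find_candidates(helix12.residues[idx], idx, profile, lib,
                            "nucleoside", CFG)


class TestPruneToPromising:
    def test_under_limit_all_kept_sorted(self, helix12, helix_library):
        profile = compute_torsions(helix12)
        idx = 5
        cands = find_candidates(helix12.residues[idx], idx, profile,
                                helix_library, "nucleoside", CFG)
        pruned = prune_to_promising(helix12.residues[idx], cands,
                                    "nucleoside", CFG)
        assert len(pruned) == len(cands) <= CFG.max_candidates
        rmsds = [c.rebuild_rmsd for c in pruned]
        assert rmsds == sorted(rmsds)
        assert all(c.coords for c in pruned)

    def test_cap_at_max_candidates_matches_sort_oracle(self, helix12):
        # 15 synthetic chi variants of one conformer: distinct rebuild RMSDs
        confs = extract_annotated_residues([helix12])
        base = next(c for c in confs if c.base_type == "A")
        variants = [dataclasses.replace(
            base, id=f"v{k:02d}",
            torsions={**base.torsions,
                      "chi": wrap_angle(base.torsions["chi"] + 3.0 * k)})
            for k in range(15)]
        idx = next(i for i, r in enumerate(helix12.residues)
                   if r.base_type == "A" and 0 < i < len(helix12) - 1)
        res = helix12.residues[idx]
        cands = [type("C", (), {})() for _ in variants]
        from nucleofit.engine import Candidate
        cands = [Candidate(conformer=v, match_mcq=0.0) for v in variants]
        pruned = prune_to_promising(res, cands, "nucleobase", CFG)
        assert len(pruned) == CFG.max_candidates == 10
        # independent sort oracle over all 15 rebuilt RMSDs
        all_r = prune_to_promising(
            res, [Candidate(conformer=v, match_mcq=0.0) for v in variants],
            "nucleobase", dataclasses.replace(CFG, max_candidates=99))
        expect = sorted(c.rebuild_rmsd for c in all_r)[:10]
        assert [c.rebuild_rmsd for c in pruned] == pytest.approx(expect)

    def test_tie_breaks_by_mcq_then_id(self, helix12):
        from nucleofit.engine import Candidate
        confs = extract_annotated_residues([helix12])
        base = next(c for c in confs if c.base_type == "A")
        twin_a = dataclasses.replace(base, id="aa")
        twin_b = dataclasses.replace(base, id="bb")
        idx = next(i for i, r in enumerate(helix12.residues)
                   if r.base_type == "A" and 0 < i < len(helix12) - 1)
        pruned = prune_to_promising(
            helix12.residues[idx],
            [Candidate(conformer=twin_b, match_mcq=1.0),
             Candidate(conformer=twin_a, match_mcq=1.0)],
            "nucleobase", CFG)
        assert [c.conformer.id for c in pruned] == ["aa", "bb"]


class TestComputeEnergies:
    def test_pair_symmetry_and_cutoff(self, helix12, helix_library):
        task = parse_task_sequence("".join(
            c.upper() if i in (1, 2, 10) else c.lower()
            for i, c in enumerate(helix12.sequence)), helix12, "nucleobase")
        from nucleofit.structure import clean_and_validate
        cleaned, _ = clean_and_validate(helix12, task)
        profile = compute_torsions(cleaned)
        cands = {}
        for i in (1, 2, 10):
            found = find_candidates(cleaned.residues[i], i, profile,
                                    helix_library, "nucleobase", CFG)
            cands[i] = prune_to_promising(cleaned.residues[i], found,
                                          "nucleobase", CFG)
        tables = compute_energies(cleaned, cands, CFG)
        tables.validate_symmetry()
        # residues 1-2 are stacked neighbours: interactions exist
        assert any(k[0][0] == 1 and k[1][0] == 2 for k in tables.e_pair)
        # residues 2 and 10 are ~25 A apart along the helix: no entry stored
        assert not any({k[0][0], k[1][0]} == {2, 10} for k in tables.e_pair)

    def test_overlapping_candidate_scores_large_positive_e_fixed(self, duplex6):
        # two candidates with identical backbones: the native rotamer and a
        # chi-rotated one whose base collides with the Watson-Crick partner
        confs = extract_annotated_residues([duplex6])
        native = next(c for c in confs if f"/{duplex6.residues[2].label}" in c.id)
        clashing = dataclasses.replace(
            native, id="clashing",
            torsions={**native.torsions,
                      "chi": wrap_angle(native.torsions["chi"] + 160.0)})
        lib = ConformerLibrary(name="pairtest", distance="euclidean",
                               algorithm="neural_gas",
                               conformers=[native, clashing])
        seq = "".join(c.upper() if i == 2 else c.lower()
                      for i, c in enumerate(duplex6.sequence))
        task = parse_task_sequence(seq, duplex6, "nucleobase")
        from nucleofit.structure import clean_and_validate
        cleaned, _ = clean_and_validate(duplex6, task)
        profile = compute_torsions(cleaned)
        found = find_candidates(cleaned.residues[2], 2, profile, lib,
                                "nucleobase", CFG)
        cands = {2: prune_to_promising(cleaned.residues[2], found,
                                       "nucleobase", CFG)}
        tables = compute_energies(cleaned, cands, CFG)
        by_id = {cands[2][m].conformer.id: tables.e_fixed[(2, m)]
                 for m in range(len(cands[2]))}
        assert by_id["clashing"] > by_id[native.id] + 10.0


class TestRemodel:
    @pytest.mark.parametrize("mode", ["nucleoside", "nucleobase"])
    def test_self_recovery_round_trip(self, helix12, helix_library, mode):
        stripped = strip(helix12, mode)
        task = parse_task_sequence(helix12.sequence.upper(), stripped, mode)
        out, logbook = remodel(stripped, task, helix_library)
        devs = [np.linalg.norm(res.coord(n) - out.residues[i].coord(n))
                for i, res in enumerate(helix12.residues) for n in res.atoms]
        assert math.sqrt(np.mean(np.square(devs))) < 0.1
        assert len(detect_clashes(out)) == 0
        for i, (a, b) in enumerate(zip(stripped.residues, out.residues)):
            for name in _chem.FIXED_ATOMS[mode]:
                if name in a.atoms:
                    assert (a.coord(name) == b.coord(name)).all()

    def test_candidate_counts_monotone_through_pipeline(self, helix12, helix_library):
        stripped = strip(helix12, "nucleoside")
        task = parse_task_sequence(helix12.sequence.upper(), stripped, "nucleoside")
        _, logbook = remodel(stripped, task, helix_library)
        for i, n1 in logbook["steps"]["1_candidates"].items():
            assert logbook["steps"]["2_promising"][i] <= n1

    def test_clash_repair_restores_pairs(self, duplex6, duplex_library):
        bad = perturb(duplex6, 2, "chi", 160.0)
        assert len(detect_clashes(bad)) >= 1
        seq = "".join(c.upper() if i == 2 else c.lower()
                      for i, c in enumerate(bad.sequence))
        task = parse_task_sequence(seq, bad, "nucleobase")
        out, _ = remodel(bad, task, duplex_library)
        scope = {(2, n) for n in out.residues[2].atoms}
        assert len(detect_clashes(out, scope=scope)) == 0
        assert inf_score(annotate_canonical_pairs(duplex6),
                         annotate_canonical_pairs(out)) == pytest.approx(1.0)

    def test_deterministic_output_text(self, helix12, helix_library):
        stripped = strip(helix12, "nucleobase")
        task = parse_task_sequence(helix12.sequence.upper(), stripped, "nucleobase")
        out1, _ = remodel(stripped, task, helix_library)
        out2, _ = remodel(stripped, task, helix_library)
        assert write_pdb(out1) == write_pdb(out2)

    def test_validation_failure_propagates(self, helix12, helix_library):
        broken = strip(helix12, "nucleoside")
        del broken.residues[3].atoms["C4'"]
        task = parse_task_sequence(helix12.sequence.upper(), broken, "nucleoside")
        with pytest.raises(StructureError, match="C4'"):
            remodel(broken, task, helix_library)

    def test_minimize_flag_is_logged_noop(self, helix12, helix_library):
        stripped = strip(helix12, "nucleobase")
        task = parse_task_sequence(helix12.sequence.upper(), stripped,
                                   "nucleobase", minimize=True)
        out, logbook = remodel(stripped, task, helix_library)
        assert "skipped" in logbook["minimize"]
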