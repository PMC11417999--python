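import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sorbdock.core import Structure
from sorbdock.ion_sites import IonSite, IonSiteSet
from sorbdock.materials import build_carbon_sheet
from sorbdock.synthetic import (
    PlantedPocket,
    SyntheticSpec,
    make_protein,
    make_trajectory,
)
from sorbdock.traj_analysis import (
    PocketRecord,
    Trajectory,
    classify_ion_binding,
    classify_residue_type,
    classify_residue_types,
    contact_probability,
    identify_pockets,
    in_contact,
    pocket_occurrence_report,
    read_trajectory,
    rmsd_suite,
    select_chains,
    select_trajectory,
    write_trajectory,
)

from conftest import make_structure


def chains(structure, ids):
    return select_chains(structure, list(ids))


class TestInContact:
    @pytest.mark.parametrize("gap,expected", [
        (4.9, True),
        (5.0, True),   # boundary is inclusive
        (5.1, False),
    ])
    def test_cutoff_boundary(self, gap, expected):
        a = make_structure([[0, 0, 0]])
        b = make_structure([[0, 0, gap]])
        assert in_contact(a, b) is expected

    def test_hydrogens_ignored(self):
        a = make_structure([[0, 0, 0], [0, 0, 9.0]], elements=["H", "C"])
        b = make_structure([[0, 0, 2.0]])
        assert in_contact(a, b) is False

    def test_minimum_image_with_box(self):
        a = make_structure([[1.0, 5.0, 5.0]])
        b = make_structure([[99.0, 5.0, 5.0]])
        assert in_contact(a, b) is False
        assert in_contact(a, b, box=[100.0, 100.0, 100.0]) is True

    def test_empty_heavy_set_rejected(self):
        a = make_structure([[0, 0, 0]], elements=["H"])
        b = make_structure([[0, 0, 1]])
        with pytest.raises(ValueError):
            in_contact(a, b)


def contact_fixture(schedules, n_frames=3, equil=0):
    """Composite system with per-residue planted material contacts."""
    mat = build_carbon_sheet(4, 0.0, seed=0)
    spec = SyntheticSpec(
        n_chains=1, residues_per_chain=len(schedules), n_frames=n_frames,
        equilibration_frames=equil, seed=0,
        planted_contacts={i + 1: sched for i, sched in enumerate(schedules)},
    )
    prot = make_protein(spec)
    traj = make_trajectory(prot, mat, None, spec)
    return traj


class TestContactProbability:
    def test_two_residue_three_frame_closed_form(self):
        traj = contact_fixture([[True] * 3, [False] * 3])
        table = contact_probability(traj, chains(traj.structure, "A"),
                                    chains(traj.structure, "M"))
        assert table.aggregate_percent == pytest.approx(50.0)
        assert table.per_chain_mean_bound["A"] == pytest.approx(1.0)

    def test_all_residues_all_frames_is_100(self):
        traj = contact_fixture([[True] * 3, [True] * 3])
        table = contact_probability(traj, chains(traj.structure, "A"),
                                    chains(traj.structure, "M"))
        assert table.aggregate_percent == pytest.approx(100.0)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(8)
        schedules = [rng.random(6) < 0.5 for _ in range(5)]
        traj = contact_fixture(schedules, n_frames=6)
        table = contact_probability(traj, chains(traj.structure, "A"),
                                    chains(traj.structure, "M"))
        # independent recount straight from the coordinates
        s = traj.structure
        pmask = chains(s, "A") & s.heavy_mask
        mmask = chains(s, "M") & s.heavy_mask
        res_ids = sorted(set(s.res_id[pmask]))
        events = 0
        for f in range(traj.n_frames):
            mat = traj.coords[f][mmask]
            for rid in res_ids:
                ridx = pmask & (s.res_id == rid)
                d = np.linalg.norm(
                    traj.coords[f][ridx][:, None] - mat[None], axis=-1)
                if d.min() <= 5.0:
                    events += 1
        expected = 100.0 * events / (len(res_ids) * traj.n_frames)
        assert table.aggregate_percent == pytest.approx(expected)

    def test_invariant_under_global_rigid_transform(self):
        traj = contact_fixture([[True, False, True], [False] * 3])
        table0 = contact_probability(traj, chains(traj.structure, "A"),
                                     chains(traj.structure, "M"))
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        t = np.array([13.0, -6.0, 40.0])
        moved = Trajectory(
            structure=traj.structure,
            coords=traj.coords @ R.T + t,
            equilibration_frames=traj.equilibration_frames,
        )
        table1 = contact_probability(moved, chains(traj.structure, "A"),
                                     chains(traj.structure, "M"))
        assert table1.aggregate_percent == pytest.approx(
            table0.aggregate_percent)

    def test_equilibration_frames_excluded(self):
        # contacts only during the equilibration window must not count
        traj = contact_fixture([[True, True, False, False],
                                [False] * 4], n_frames=4, equil=2)
        table = contact_probability(traj, chains(traj.structure, "A"),
                                    chains(traj.structure, "M"))
        assert table.aggregate_percent == pytest.approx(0.0)

    def test_residue_class_breakdown_sums_to_100(self):
        mat = build_carbon_sheet(4, 0.0, seed=0)
        spec = SyntheticSpec(
            n_chains=1, residues_per_chain=4, n_frames=3,
            equilibration_frames=0, seed=0,
            residue_names={1: "LYS", 2: "GLU", 3: "SER", 4: "VAL"},
            planted_contacts={r: [True] * 3 for r in (1, 2, 3)},
        )
        prot = make_protein(spec)
        traj = make_trajectory(prot, mat, None, spec)
        table = contact_probability(traj, chains(traj.structure, "A"),
                                    chains(traj.structure, "M"))
        total = sum(table.residue_class_breakdown.values())
        assert total == pytest.approx(100.0)
        assert table.residue_class_breakdown["positive"] == pytest.approx(
            100.0 / 3)
        assert table.residue_class_breakdown["other"] == 0.0

    def test_empty_selection_rejected(self):
        traj = contact_fixture([[True] * 3])
        with pytest.raises(ValueError):
            contact_probability(traj, np.zeros(traj.structure.n_atoms, bool),
                                chains(traj.structure, "M"))


class TestResidueClasses:
    def test_representatives(self):
        assert classify_residue_type("LYS") == "positive"
        assert classify_residue_type("GLU") == "negative"
        assert classify_residue_type("GLN") == "polar"
        assert classify_residue_type("TRP") == "other"

    def test_partition_total_and_disjoint(self):
        from sorbdock.core import STANDARD_AMINO_ACIDS
        mapping = classify_residue_types(sorted(STANDARD_AMINO_ACIDS))
        assert set(mapping) == STANDARD_AMINO_ACIDS
        counts = {"positive": 0, "negative": 0, "polar": 0, "other": 0}
        for cls in mapping.values():
            counts[cls] += 1
        assert counts == {"positive": 3, "negative": 2, "polar": 4,
                          "other": 11}

    def test_nonstandard_goes_to_other(self):
        assert classify_residue_type("XYZ") == "other"


def rigid_traj(n_frames=5, translation=(0, 0, 2.0), rotation=None, seed=0,
               noise=0.0):
    spec = SyntheticSpec(
        n_chains=1, residues_per_chain=20, n_frames=n_frames,
        equilibration_frames=0, seed=seed, noise_sigma=noise,
        rigid_motion=(rotation if rotation is not None else np.eye(3),
                      translation),
    )
    prot = make_protein(spec)
    return make_trajectory(prot, None, None, spec)


class TestRMSDSuite:
    def test_identity_trajectory_is_zero_in_all_modes(self):
        traj = rigid_traj(translation=(0, 0, 0))
        for mode in ("align_wrt_initial", "no_alignment",
                     "no_alignment_wrt_average"):
            res = rmsd_suite(traj, mode)
            assert res.series == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_closed_form(self):
        traj = rigid_traj(translation=(0, 0, 2.0))
        no_align = rmsd_suite(traj, "no_alignment")
        np.testing.assert_allclose(no_align.series,
                                   2.0 * np.arange(5), atol=1e-9)
        aligned = rmsd_suite(traj, "align_wrt_initial")
        assert aligned.series == pytest.approx(0.0, abs=1e-8)

    def test_rigid_transform_aligns_to_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20, 20, 3)
            traj = rigid_traj(n_frames=3, translation=t, rotation=R)
            res = rmsd_suite(traj, "align_wrt_initial")
            assert res.series == pytest.approx(0.0, abs=1e-6)

    def test_optimal_superposition_never_exceeds_no_alignment(self):
        for seed in range(5):
            traj = rigid_traj(n_frames=6, translation=(0.5, 0, 1.0),
                              noise=0.4, seed=seed)
            m1 = rmsd_suite(traj, "align_wrt_initial")
            m2 = rmsd_suite(traj, "no_alignment")
            assert np.all(m1.series <= m2.series + 1e-9)

    def test_matches_scipy_superposition_oracle(self):
        rng = np.random.default_rng(42)
        ref = rng.normal(size=(50, 3)) * 8.0
        names = np.tile(["N", "CA", "C"], 17)[:50]
        s = Structure(np.arange(1, 51), names, ["C"] * 50,
                      np.repeat(np.arange(1, 18), 3)[:50], ["ALA"] * 50,
                      ["A"] * 50, ref)
        frames = [ref]
        for _ in range(4):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-15, 15, 3)
            frames.append(ref @ R.T + t + rng.normal(0, 0.3, ref.shape))
        traj = Trajectory(structure=s, coords=np.stack(frames))
        res = rmsd_suite(traj, "align_wrt_initial")
        for fi, frame in enumerate(frames):
            mob = frame - frame.mean(axis=0)
            tgt = ref - ref.mean(axis=0)
            _, rssd = Rotation.align_vectors(tgt, mob)
            assert res.series[fi] == pytest.approx(rssd / np.sqrt(50),
                                                   abs=1e-6)

    def test_material_fit_restores_shared_motion(self):
        """When the whole system drifts, superposing on the material first
        cancels the drift in the no-alignment RMSD (the carbon-system
        convention)."""
        rng = np.random.default_rng(1)
        prot = make_protein(SyntheticSpec(n_chains=1, residues_per_chain=10))
        mat = build_carbon_sheet(6, 0.0, seed=0)
        base = np.vstack([prot.coords, mat.structure.coords])
        n = len(base)
        s = Structure(
            np.arange(1, n + 1),
            np.concatenate([prot.atom_name, mat.structure.atom_name]),
            np.concatenate([prot.element, mat.structure.element]),
            np.concatenate([prot.res_id, mat.structure.res_id]),
            np.concatenate([prot.res_name, mat.structure.res_name]),
            np.concatenate([prot.chain_id, mat.structure.chain_id]),
            base)
        frames = [base] + [base + t for t in
                           ([5.0, 0, 0], [0, 7.0, 3.0], [2.0, 2.0, 9.0])]
        traj = Trajectory(structure=s, coords=np.stack(frames))
        drifting = rmsd_suite(traj, "no_alignment")
        assert drifting.series[1:].min() > 1.0
        fitted = rmsd_suite(traj, "no_alignment",
                            fit_selection=chains(s, "M"))
        assert fitted.series == pytest.approx(0.0, abs=1e-9)

    def test_empty_fit_selection_rejected(self):
        traj = rigid_traj()
        with pytest.raises(ValueError, match="fit_selection"):
            rmsd_suite(traj, "no_alignment",
                       fit_selection=np.zeros(traj.structure.n_atoms, bool))


def selection_oracle(pairs):
    """Hand enumeration of the lowest-summed-rank consensus."""
    n = len(pairs)
    best, best_key = None, None
    for i, (r, p) in enumerate(pairs):
        rank_r = 1 + sum(1 for rr, _ in pairs if rr < r)
        rank_p = 1 + sum(1 for _, pp in pairs if pp > p)
        key = (rank_r + rank_p, r, i)
        if best_key is None or key < best_key:
            best, best_key = i, key
    return best


class TestSelectTrajectory:
    def test_single_candidate(self):
        assert select_trajectory([(None, 40.0, 3.0)]) == 0

    def test_dominant_candidate_wins(self):
        cands = [(None, 30.0, 5.0), (None, 80.0, 2.0), (None, 50.0, 4.0)]
        assert select_trajectory(cands) == 1

    def test_crossing_ranks_hand_computed(self):
        # rmsd ranks: a=1 b=2 c=3; percent ranks: a=3 b=2 c=1 -> tie on sum,
        # broken by the lower RMSD
        cands = [(None, 10.0, 1.0), (None, 20.0, 2.0), (None, 30.0, 3.0)]
        assert select_trajectory(cands) == 0

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(100)
        for _ in range(300):
            n = int(rng.integers(1, 9))
            pairs = [(float(r), float(p))
                     for r, p in zip(rng.uniform(0, 5, n),
                                     rng.uniform(0, 100, n))]
            cands = [(None, p, r) for r, p in pairs]
            assert select_trajectory(cands) == selection_oracle(pairs)


def tiny_ion_system(protein_z=8.0, ion_positions=((0.0, 0.0, 4.0),)):
    """One protein CA, one material carbon at the origin, one scripted ion."""
    n_frames = len(ion_positions)
    base = np.array([[0.0, 0.0, protein_z], [0.0, 0.0, 0.0],
                     [0.0, 0.0, 0.0]])
    s = Structure([1, 2, 3], ["CA", "C", "CD"], ["C", "C", "Cd"],
                  [1, 1, 1], ["ALA", "CAR", "CD"], ["A", "M", "I"], base)
    frames = []
    for pos in ion_positions:
        f = base.copy()
        f[2] = pos
        frames.append(f)
    return Trajectory(structure=s, coords=np.stack(frames))


def run_modes(traj):
    return classify_ion_binding(
        traj, np.where(chains(traj.structure, "I"))[0],
        chains(traj.structure, "A"), chains(traj.structure, "M"))


class TestIonBindingModes:
    def test_protein_only_when_material_far(self):
        # ion 4 Å from the protein atom, ~26 Å from the material
        traj = tiny_ion_system(protein_z=30.0,
                               ion_positions=[(0, 0, 26.0)])
        series = run_modes(traj)
        assert list(series.modes.values.ravel()) == ["protein_only"]

    def test_bridging_when_both_within_cutoff(self):
        traj = tiny_ion_system(protein_z=8.0, ion_positions=[(0, 0, 4.0)])
        series = run_modes(traj)
        assert list(series.modes.values.ravel()) == ["protein_and_material"]

    def test_all_four_modes_and_percentages(self):
        traj = tiny_ion_system(protein_z=30.0, ion_positions=[
            (0, 0, 26.0),    # protein only
            (0, 0, 4.0),     # material only
            (50, 50, 50),    # unbound
            (50, 50, 50),    # unbound
        ])
        pct = run_modes(traj).percentages
        assert sum(pct.values()) == pytest.approx(100.0)
        assert pct["protein_only"] == pytest.approx(25.0)
        assert pct["material_only"] == pytest.approx(25.0)
        assert pct["unbound"] == pytest.approx(50.0)

    def test_planted_series_matches_hand_count(self):
        traj = tiny_ion_system(protein_z=10.0, ion_positions=[
            (0, 0, 7.0),    # protein only (3 to protein, 7 to material)
            (0, 0, 5.0),    # both (5 and 5, inclusive boundary)
            (0, 0, 2.0),    # material only (8 and 2)
            (0, 0, -30.0),  # unbound
        ])
        modes = list(run_modes(traj).modes.values.ravel())
        assert modes == ["protein_only", "protein_and_material",
                         "material_only", "unbound"]


def pocket_traj(occupancy, include_last=True, n_frames=100, equil=0,
                residues=(129, 130, 131), seed=5, noise=0.0):
    spec = SyntheticSpec(
        n_chains=2, residues_per_chain=162, n_frames=n_frames,
        equilibration_frames=equil, seed=seed, noise_sigma=noise,
        residue_names={129: "ASP", 130: "ASP", 131: "GLU"},
        planted_pockets=[PlantedPocket(0, list(residues), occupancy,
                                       include_last)],
    )
    prot = make_protein(spec)
    ions = IonSiteSet([IonSite(np.zeros(3), None, "Cd", "random")])
    return make_trajectory(prot, None, ions, spec)


def run_pockets(traj, **kwargs):
    return identify_pockets(
        traj, np.where(chains(traj.structure, "I"))[0],
        chains(traj.structure, "AB"), **kwargs)


class TestIdentifyPockets:
    def test_persistent_pocket_recovered_exactly(self):
        traj = pocket_traj(0.70)
        recs = run_pockets(traj)
        assert len(recs) == 1
        labels = sorted((c, r) for c, r, _ in recs[0].residues)
        assert labels == [("A", 129), ("A", 130), ("A", 131)]
        assert recs[0].occupancy == pytest.approx(0.70)
        assert recs[0].present_in_last_frame
        assert all(v >= 0.5 for v in
                   recs[0].per_residue_membership.values())

    def test_below_threshold_not_reported(self):
        traj = pocket_traj(0.59)
        assert run_pockets(traj) == []

    def test_exact_threshold_inclusive(self):
        traj = pocket_traj(0.60)
        assert len(run_pockets(traj)) == 1

    def test_absent_from_last_frame_not_reported(self):
        traj = pocket_traj(0.80, include_last=False)
        assert run_pockets(traj) == []

    def test_equilibration_frames_ignored(self):
        traj = pocket_traj(0.65, n_frames=100, equil=30)
        recs = run_pockets(traj)
        assert len(recs) == 1
        # corrupting the equilibration window must not change the result
        traj.coords[:30] += 500.0
        recs2 = run_pockets(traj)
        assert recs2[0].residues == recs[0].residues
        assert recs2[0].occupancy == recs[0].occupancy


class TestPocketOccurrenceReport:
    @staticmethod
    def record(residues, ion_id=1, species="Cd"):
        rs = frozenset(("A", rid, name) for rid, name in residues)
        return PocketRecord(ion_id=ion_id, residues=rs, occupancy=0.8,
                            present_in_last_frame=True,
                            per_residue_membership={k: 1.0 for k in rs},
                            species=species)

    def test_single_pocket_single_system(self):
        rep = pocket_occurrence_report({
            ("CM-pH7", "Cd"): [self.record([(129, "ASP"), (130, "ASP"),
                                            (131, "GLU")])],
        })
        assert rep.shape == (1, 1)
        assert rep.index[0] == "D129, D130, E131"
        assert rep.iloc[0, 0] == "+"

    def test_identical_sets_merge_into_one_row(self):
        rec = [self.record([(51, "GLU"), (53, "ASP"), (74, "GLU")])]
        rep = pocket_occurrence_report({
            ("CM-pH7", "Cd"): rec,
            ("AC1-pH7", "Cd"): [self.record([(51, "GLU"), (53, "ASP"),
                                             (74, "GLU")])],
        })
        assert rep.shape == (1, 2)
        assert (rep.loc["E51, D53, E74"] == "+").all()

    def test_superset_annotated_parenthetically(self):
        core = [(108, "GLU"), (114, "GLU")]
        rep = pocket_occurrence_report({
            ("CM-pH7", "Cd"): [self.record(core + [(91, "LYS")])],
            ("AC1-pH7", "Cd"): [self.record(core)],
            ("AC20-pH7", "Cd"): [self.record(core)],
        })
        assert list(rep.index) == ["E108, E114 (K91)"]
        assert rep.loc["E108, E114 (K91)", "CM-pH7/Cd"] == "+ (K91)"
        assert rep.loc["E108, E114 (K91)", "AC1-pH7/Cd"] == "+"


class TestTrajectoryIO:
    def test_multi_model_round_trip(self, tmp_path):
        traj = rigid_traj(n_frames=4)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path, equilibration_frames=1)
        assert back.n_frames == 4
        assert back.equilibration_frames == 1
        np.testing.assert_allclose(back.coords, traj.coords, atol=5.1e-4)

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="reader"):
            read_trajectory("x.dcd", format="dcd")

    def test_equilibration_must_be_less_than_frames(self):
        s = make_structure([[0, 0, 0]])
        with pytest.raises(ValueError):
            Trajectory(structure=s, coords=np.zeros((2, 1, 3)),
                       equilibration_frames=2)
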