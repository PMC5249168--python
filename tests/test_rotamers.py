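"""Rotamer library content and nearest-state assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rotamerlab import (assign_rotamer, assign_series, load_rotamer_library,
                        matches_within_tolerance)
from rotamerlab.rotamers import CHI_ATOMS, N_CHI
from rotamerlab.torsions import ChiTrajectory, ResidueId, circular_distance

EXPECTED_STATE_COUNTS = {
    "ARG": 34, "LYS": 27, "MET": 13, "GLN": 9, "GLU": 8, "HIS": 8,
    "ASN": 7, "ILE": 7, "TRP": 7, "ASP": 5, "LEU": 5, "PHE": 4, "TYR": 4,
    "SER": 3, "THR": 3, "VAL": 3, "CYS": 3, "PRO": 2,
}


class TestLibraryContent:
    def test_all_rotameric_types_present_with_published_counts(self, library):
        assert {r: library.n_states(r) for r in library.entries} == \
            EXPECTED_STATE_COUNTS

    def test_ala_and_gly_absent(self, library):
        assert "ALA" not in library
        assert "GLY" not in library

    def test_state_ids_contiguous_and_chi_counts_match_chemistry(self, library):
        for res in library.entries:
            states = library.states(res)
            assert [s.state_id for s in states] == list(range(1, len(states) + 1))
            assert all(s.n_chi == N_CHI[res] for s in states)

    def test_leucine_has_two_chi_angles(self, library):
        assert library.n_chi("LEU") == 2

    def test_modal_angles_in_reporting_interval(self, library):
        for res in library.entries:
            modal = library.modal_matrix(res)
            assert np.all((modal > -180.0) & (modal <= 180.0))

    def test_malformed_row_raises_naming_location(self, tmp_path):
        bad = tmp_path / "lib.tsv"
        bad.write_text("residue_type\tstate_id\tstate_name\tn_chi\tchi1\n"
                       "SER\tone\tp\t1\t64\n")
        with pytest.raises(ValueError, match="lib.tsv:2"):
            load_rotamer_library(bad)

    def test_missing_residue_type_raises(self, tmp_path):
        partial = tmp_path / "lib.tsv"
        partial.write_text("residue_type\tstate_id\tstate_name\tn_chi\tchi1\n"
                           "SER\t1\tp\t1\t64\n")
        with pytest.raises(ValueError, match="missing"):
            load_rotamer_library(partial)


class TestAssignment:
    def test_modal_vector_round_trips_to_own_state_across_library(self, library):
        for res in library.entries:
            for state in library.states(res):
                assert assign_rotamer(state.modal_chis, res, library) == \
                    state.state_id, f"{res} {state.state_name}"

    def test_wraparound_treats_179_and_minus_179_as_close(self, library):
        # SER t state is at 178; an angle of -179 is 3 deg away circularly
        assert assign_rotamer([-179.0], "SER", library) == 2

    def test_leucine_example_maps_to_mt_state(self, library):
        state = library.state("LEU", assign_rotamer([-65, 175], "LEU", library))
        assert state.modal_chis == (-65.0, 175.0)

    def test_unknown_residue_type_raises(self, library):
        with pytest.raises(KeyError, match="ALA"):
            assign_rotamer([60.0], "ALA", library)

    def test_symmetric_terminal_fold_equates_mirrored_ring_labelings(self, library):
        # PHE chi2 of 150 is the same physical conformation as -30
        assert assign_rotamer([-65, 150], "PHE", library) == \
            assign_rotamer([-65, -30], "PHE", library)
        # and the boundary itself: 92 vs -88
        assert assign_rotamer([62, 92], "PHE", library) == \
            assign_rotamer([62, -88], "PHE", library)

    @given(shift=st.sampled_from([-720, -360, 0, 360, 720]),
           jitter=st.floats(-15, 15))
    @settings(max_examples=40, deadline=None)
    def test_assignment_invariant_to_full_turns(self, library, shift, jitter):
        base = np.array([-65.0 + jitter, 175.0])
        shifted = base.copy()
        shifted[0] += shift
        assert assign_rotamer(base, "LEU", library) == \
            assign_rotamer(np.mod(shifted + 180, 360) - 180, "LEU", library)

    def test_series_assignment_preserves_length_and_state(self, library):
        rid = ResidueId("A", 1, "LEU")
        frames = np.tile([-65.0, 175.0], (3, 1))
        traj = ChiTrajectory(rid, "solution", "A1", frames)
        series = assign_series(traj, library)
        assert list(series.states) == [5, 5, 5]

    def test_empty_trajectory_gives_empty_series(self, library):
        traj = ChiTrajectory(ResidueId("A", 1, "LEU"), "solution", "A1",
                             np.empty((0, 2)))
        assert assign_series(traj, library).n_frames == 0


class TestToleranceMatch:
    def test_all_angles_within_tolerance_passes(self, library):
        state = library.state("MET", 6)  # ttt
        chis = np.array(state.modal_chis) + 29.0
        assert matches_within_tolerance(chis, state, 30.0)

    def test_single_angle_beyond_tolerance_fails(self, library):
        state = library.state("MET", 6)
        chis = np.array(state.modal_chis, dtype=float)
        chis[1] += 31.0
        assert not matches_within_tolerance(chis, state, 30.0)

    def test_wraparound_within_tolerance(self, library):
        state = library.state("SER", 2)  # t at 178
        # 170 vs modal 178 trivially close; -172 is 10 deg away circularly
        assert matches_within_tolerance([-172.0], state, 30.0)

    @given(tol=st.floats(0, 180))
    @settings(max_examples=25, deadline=None)
    def test_modal_vector_matches_its_state_at_any_tolerance(self, library, tol):
        state = library.state("GLN", 5)
        assert matches_within_tolerance(state.modal_chis, state, tol)


@given(a=st.floats(-180, 180), b=st.floats(-180, 180))
@settings(max_examples=50, deadline=None)
def test_circular_distance_symmetric_and_bounded(a, b):
    assert circular_distance(a, b) == pytest.approx(circular_distance(b, a))
    assert 0.0 <= circular_distance(a, b) <= 180.0


def test_single_well_trajectories_recover_generating_state(library):
    """With 3-SD-truncated noise at the default width every frame stays in
    its generating well; at SD 10 the two 40-deg-separated carboxyl wells
    of ASP/ASN leak a small fraction."""
    from rotamerlab import EnsembleSpec, generate_torsion_trajectory
    for res in library.entries:
        n = library.n_states(res)
        for state in (1, n):
            w = tuple(1.0 if i + 1 == state else 0.0 for i in range(n))
            spec = EnsembleSpec(res, w, noise_sd=6.0, n_frames=400, seed=7)
            series = assign_series(generate_torsion_trajectory(spec, library),
                                   library)
            frac = np.mean(series.states == state)
            assert frac == 1.0, f"{res} state {state}: {frac}"
    for res, floor in [("LEU", 0.99), ("GLN", 0.99), ("ASP", 0.97),
                       ("ASN", 0.97)]:
        n = library.n_states(res)
        w = tuple(1.0 if i == 0 else 0.0 for i in range(n))
        spec = EnsembleSpec(res, w, noise_sd=10.0, n_frames=2000, seed=11)
        series = assign_series(generate_torsion_trajectory(spec, library),
                               library)
        assert np.mean(series.states == 1) >= floor
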