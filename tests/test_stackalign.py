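import numpy as np
import pytest

from histostack.phantom import PhantomSpec, build_phantom_dataset, evaluate_recovery
from histostack.register2d import RegistrationParams, Transform2D
from histostack.stackalign import (
    build_target_set,
    initialize_state,
    revert_to_best,
    run_reconstruction,
    sweep,
)

FAST = RegistrationParams(iterations_per_scale=20, warm_iterations=10)


@pytest.fixture(scope="module")
def toy_state():
    """Tiny three-stain interleaved stack with everything 'already registered'."""
    spec = PhantomSpec(
        seed=5, grid_shape=(64, 64, 12), vessel_count=0,
        sampling_plan={"nissl": "1:3", "bielschowsky": "1:3", "parvalbumin": "1:3"},
        plan_offsets={"nissl": 0, "bielschowsky": 1, "parvalbumin": 2},
        distortion_amplitude=0.0, affine_jitter=(0.0, 0.0),
    )
    ds = build_phantom_dataset(spec)
    return ds, initialize_state(ds.blockface, ds.sections)


class TestBuildTargetSet:
    def test_first_slice_has_only_blockface(self, toy_state):
        _, state = toy_state
        targets = build_target_set(state, 0, "nissl", "forward", registered=set())
        assert len(targets) == 1 and targets[0].weight == 1.0

    def test_mid_stack_full_seven_targets_with_paper_weights(self, toy_state):
        _, state = toy_state
        registered = set(state.sections)
        targets = build_target_set(state, 6, "nissl", "forward", registered)
        weights = sorted((t.weight for t in targets), reverse=True)
        assert weights == [1.0, 0.5, 0.5, 0.25, 0.25, 0.25, 0.25]
        assert len(targets) == 7

    def test_window_rule_matches_exhaustive_enumeration(self, toy_state):
        _, state = toy_state
        # forward at z, upstream candidates are exactly keys with 0 < z-k <= 3
        for z in range(12):
            registered = {k for k in state.sections if k[0] < z}
            targets = build_target_set(state, z, "nissl", "forward", registered)
            allowed = [k for k in registered if 0 < z - k[0] <= 3]
            n_neighbor_images = sum(1 for t in targets if t.weight in (0.5, 0.25) and t.moving is None)
            same = [k for k in allowed if k[1] == "nissl"]
            expected = (1 if same else 0) + min(2, len(allowed) - (1 if same else 0))
            assert n_neighbor_images == expected

    def test_backward_direction_looks_downstream(self, toy_state):
        _, state = toy_state
        registered = {k for k in state.sections if k[0] > 6}
        targets = build_target_set(state, 6, "nissl", "backward", registered)
        assert len(targets) > 1  # neighbors found on the high-z side

    def test_missing_blockface_is_fatal(self, toy_state):
        _, state = toy_state
        with pytest.raises(ValueError, match="anchor"):
            build_target_set(state, 99, "nissl", "forward", set())


class TestSweep:
    def test_zero_distortion_stays_near_identity(self, toy_state):
        ds, _ = toy_state
        state = initialize_state(ds.blockface, ds.sections)
        sweep(state, "forward", FAST)
        disp = [np.abs(s.transform.displacement()).mean() for s in state.sections.values()]
        assert np.mean(disp) < 0.2

    def test_scores_never_below_presweep(self, toy_state):
        ds, _ = toy_state
        state = initialize_state(ds.blockface, ds.sections)
        before = {k: s.score for k, s in state.sections.items()}
        sweep(state, "forward", FAST)
        revert_to_best(state)
        for k, s in state.sections.items():
            assert s.best_score >= before[k] - 1e-12

    def test_invalid_direction_rejected(self, toy_state):
        ds, _ = toy_state
        state = initialize_state(ds.blockface, ds.sections)
        with pytest.raises(ValueError):
            sweep(state, "sideways", FAST)


class TestRunReconstruction:
    @pytest.fixture(scope="class")
    def recon(self):
        spec = PhantomSpec(
            seed=3, grid_shape=(64, 64, 10), vessel_count=0,
            sampling_plan={"nissl": "1:2", "bielschowsky": "1:2"},
            plan_offsets={"nissl": 0, "bielschowsky": 1},
            distortion_amplitude=6.0, affine_jitter=(1.0, 2.0),
        )
        ds = build_phantom_dataset(spec)
        state = run_reconstruction(ds.blockface, ds.sections, FAST, n_iterations=2)
        return ds, state

    def test_sweep_log_two_per_iteration(self, recon):
        _, state = recon
        assert state.sweep_log == ["forward", "backward"] * 2

    def test_recovery_improves_over_identity(self, recon):
        ds, state = recon
        rec = {k: s.best_transform for k, s in state.sections.items()}
        ev = evaluate_recovery(ds, rec)
        ident = evaluate_recovery(
            ds, {k: Transform2D.identity((64, 64)) for k in state.sections}
        )
        assert ev["mean"] < 0.5 * ident["mean"]

    def test_archive_monotone_in_trace(self, recon):
        _, state = recon
        best_seen = {}
        for _, _, key, score in state.trace:
            prev = best_seen.get(key, -np.inf)
            best_seen[key] = max(prev, score)
        for key, s in state.sections.items():
            assert s.best_score >= best_seen.get(key, -np.inf) - 1e-12

    def test_gap_bridged_when_stain_missing(self, recon):
        _, state = recon
        # nissl samples even slices only: odd slices carry no nissl section
        assert not any(k == (1, "nissl") for k in state.sections)
        assert (1, "bielschowsky") in state.sections
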