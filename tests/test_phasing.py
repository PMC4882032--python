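"""The LCA dynamic phasing model: one-period shift, phase locking,
initial-condition independence, and absence of intrinsic oscillation."""

import numpy as np
import pytest

from segevo.fly import make_fly_network
from segevo.grid import AxisGrid
from segevo.phasing import (
    Kymograph, PhasingConfig, RepressionMatrix,
    run_shift_protocol, measure_eve_shift, extract_phases, within_cell_view,
    mean_stripe_period, PR_GENES,
)

N = 200
X = AxisGrid(N).positions


def _stripes(centers, width=0.012):
    v = np.zeros(N)
    for c in centers:
        v += np.exp(-0.5 * ((X - c) / width) ** 2)
    return v


def _kymo(frames, times=None):
    frames = np.asarray(frames)
    times = np.arange(len(frames), dtype=float) if times is None else times
    zeros = np.zeros_like(frames)
    return Kymograph(times=times, x=X,
                     values={"eve": frames, "run": zeros, "h": zeros, "ftz": zeros})


@pytest.fixture(scope="module")
def fly_net():
    return make_fly_network()


@pytest.fixture(scope="module")
def fly_kymo(fly_net):
    rng = np.random.default_rng(0)
    init = {g: rng.uniform(0, 1, N) for g in ("run", "h", "ftz")}
    return run_shift_protocol(fly_net, RepressionMatrix.fly_default(), init)


class TestMeasureEveShift:
    def test_identical_frames_zero(self):
        frame = _stripes([0.4, 0.47, 0.54, 0.62, 0.7])
        assert measure_eve_shift(_kymo([frame, frame])) == 0.0

    def test_translation_by_one_period_measures_one(self):
        centers = np.array([0.42, 0.49, 0.555, 0.63, 0.71])
        period = float(np.mean(np.diff(centers)))
        first = _stripes(centers)
        last = _stripes(centers - period)
        assert measure_eve_shift(_kymo([first, last])) == pytest.approx(1.0, abs=0.05)

    def test_too_few_stripes_rejected(self):
        frame = _stripes([0.5])
        with pytest.raises(ValueError):
            measure_eve_shift(_kymo([frame, frame]))


class TestExtractPhases:
    @staticmethod
    def _sin_kymo(offsets, period=0.06):
        eve = 1.0 + np.sin(2 * np.pi * X / period)
        values = {"eve": np.array([eve])}
        for g, off in offsets.items():
            values[g] = np.array([1.0 + np.sin(2 * np.pi * (X - off * period) / period)])
        return Kymograph(times=np.array([0.0]), x=X, values=values)

    def test_known_sinusoid_offsets_recovered_within_one_bin(self):
        offsets = {"run": 0.25, "h": 0.5, "ftz": 0.8}
        kymo = self._sin_kymo(offsets)
        phases = extract_phases(kymo, period=0.06)
        one_bin = (1.0 / N) / 0.06
        assert phases["eve"] == pytest.approx(0.0, abs=one_bin)
        for g, off in offsets.items():
            assert phases[g] == pytest.approx(off, abs=one_bin + 1e-9)

    def test_uniform_profile_flagged_undefined(self):
        kymo = self._sin_kymo({"run": 0.25})
        kymo.values["h"] = np.ones((1, N))
        kymo.values["ftz"] = np.zeros((1, N))
        phases = extract_phases(kymo, period=0.06)
        assert phases["h"] is None and phases["ftz"] is None


class TestWithinCellView:
    def test_series_is_column_slice(self, fly_kymo):
        view = within_cell_view(fly_kymo, 140)
        for g in PR_GENES:
            assert np.array_equal(view[g], fly_kymo.values[g][:, 140])

    def test_static_kymograph_gives_constant_series(self):
        frame = _stripes([0.4, 0.5, 0.6])
        kymo = _kymo([frame, frame, frame])
        view = within_cell_view(kymo, 100)
        assert np.ptp(view["eve"]) == 0.0

    def test_eve_completes_one_cycle_at_a_mid_posterior_cell(self, fly_kymo):
        """The anterior passage of the pattern is one full temporal
        eve cycle when viewed within a single cell."""
        series = within_cell_view(fly_kymo, 135)["eve"]
        lo, hi = series.min(), series.max()
        assert hi - lo > 0.2  # the wave actually passes through
        thr = 0.5 * (hi + lo)
        crossings = np.sum(np.diff((series > thr).astype(int)) != 0)
        assert crossings in (1, 2, 3)  # up and down once (edges may clip)


class TestShiftProtocol:
    def test_shift_is_one_period(self, fly_kymo):
        assert measure_eve_shift(fly_kymo) == pytest.approx(1.0, abs=0.1)

    def test_initial_condition_independence(self, fly_net):
        """Two arbitrary non-negative initial pair-rule states converge to
        identical phase offsets (within one bin)."""
        period = mean_stripe_period(fly_net)
        one_bin = (1.0 / N) / period
        phases = []
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            init = {g: rng.uniform(0, 1, N) for g in ("run", "h", "ftz")}
            kymo = run_shift_protocol(fly_net, RepressionMatrix.fly_default(), init)
            phases.append(extract_phases(kymo))
        for g in ("run", "h", "ftz"):
            d = abs(phases[0][g] - phases[1][g])
            assert min(d, 1 - d) <= one_bin

    def test_fly_phase_order_emerges(self, fly_kymo):
        phases = extract_phases(fly_kymo)
        assert 0 < phases["run"] < phases["h"] < phases["ftz"] < 1

    def test_zero_matrix_gives_uniform_output(self, fly_net):
        rng = np.random.default_rng(3)
        init = {g: rng.uniform(0, 1, N) for g in ("run", "h", "ftz")}
        kymo = run_shift_protocol(fly_net, RepressionMatrix.zero(), init)
        final = kymo.frame(len(kymo.times) - 1)
        for g in ("run", "h", "ftz"):
            assert np.ptp(final[g]) < 1e-3

    def test_no_intrinsic_oscillation_with_frozen_gradients(self, fly_net):
        """With the gradients never moving, the system relaxes to a fixed
        point: eve is slaved to the gap genes, so nothing can cycle."""
        cfg = PhasingConfig(shift_total=0.0, shift_duration=1e-9,
                            relax_duration=120.0)
        rng = np.random.default_rng(5)
        init = {g: rng.uniform(0, 1, N) for g in ("run", "h", "ftz")}
        kymo = run_shift_protocol(fly_net, RepressionMatrix.fly_default(), init, cfg)
        last, prev = kymo.frame(len(kymo.times) - 1), kymo.frame(len(kymo.times) - 2)
        for g in PR_GENES:
            assert np.abs(last[g] - prev[g]).max() < 1e-5

    def test_permuting_strengths_permutes_phase_order(self, fly_net):
        """Swapping the run and h rows/columns of the repression matrix
        swaps their recovered phase offsets."""
        base = RepressionMatrix.fly_default()
        perm = np.array([0, 2, 1, 3])
        swapped = RepressionMatrix(base.strengths[np.ix_(perm, perm)])
        rng = np.random.default_rng(4)
        init = {g: rng.uniform(0, 1, N) for g in ("run", "h", "ftz")}
        a = extract_phases(run_shift_protocol(fly_net, base, init))
        b = extract_phases(run_shift_protocol(fly_net, swapped, init))
        assert b["run"] == pytest.approx(a["h"], abs=0.05)
        assert b["h"] == pytest.approx(a["run"], abs=0.05)

    def test_eve_row_must_be_zero(self):
        s = np.zeros((4, 4))
        s[0, 1] = 1.0
        with pytest.raises(ValueError):
            RepressionMatrix(s)
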