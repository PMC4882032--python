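"""Steady-state relaxation: closed forms, fixed-point consistency,
boundedness, locality, and the knockout contract."""

import numpy as np
import pytest

from segevo.grid import AxisGrid
from segevo.kernels import Term, UNIFORM, evaluate_kernel
from segevo.maternal import build_maternal
from segevo.network import Network, knockout, GENE_ORDER, MODULE_GENE
from segevo.fly import make_fly_network, default_network_dict
from segevo.io import network_from_dict
from segevo.solver import steady_state
from segevo.phenotype import call_stripes


def _uniform_production_network(p=0.8, gamma=2.0):
    """All kernels: constant production p, decay gamma, no regulation."""
    doc = default_network_dict()
    for name, k in doc["kernels"].items():
        k["max_rate"] = p
        k["decay"] = gamma
        k["activators"] = [["UNIFORM", 1e-3, 2]]  # saturating: act ~ 1
        k["repressors"] = []
        k["evolvable"] = []
    return network_from_dict(doc)


class TestClosedForms:
    def test_zero_rates_give_zero_profiles(self, fly):
        net = fly.copy()
        for k in net.kernels.values():
            k.max_rate = 0.0
        ss = steady_state(net)
        for m in net.solved_modules:
            assert np.all(ss[m].values == 0.0)

    def test_constant_production_reaches_p_over_gamma(self):
        p, gamma = 0.8, 2.0
        ss = steady_state(_uniform_production_network(p, gamma))
        act = (1.0 / 1e-3) ** 2 / (1.0 + (1.0 / 1e-3) ** 2)
        for m in ("Kr", "eve2", "ftz4zebra"):
            assert ss[m].values == pytest.approx(p * act / gamma, rel=1e-4)


class TestFixedPointProperties:
    def test_residual_below_tolerance_everywhere(self, fly, fly_ss):
        """Plugging the returned steady state back into the kernel law gives
        |production - decay*level| < 1e-6 at every bin for every module."""
        n = fly.grid.n_bins
        levels = {g: fly_ss[g].values for g in GENE_ORDER if g in fly_ss}
        worst = 0.0
        for m in fly.solved_modules:
            k = fly.kernels[m]
            out = fly_ss[m].values
            for i in range(0, n, 3):
                local = {g: levels[g][i] for g in levels}
                local[UNIFORM] = fly.uniform_activator
                resid = abs(evaluate_kernel(k, local) - k.decay * out[i])
                worst = max(worst, resid)
        assert worst < 1e-6

    def test_levels_bounded_by_max_rate_over_decay(self, fly, fly_ss):
        for m in fly.solved_modules:
            k = fly.kernels[m]
            assert fly_ss[m].values.max() <= k.max_rate / k.decay + 1e-9

    def test_locality_permutation(self, fly):
        """No spatial coupling: each bin depends only on its own maternal
        levels, so reversing the maternal input reverses the output."""
        net = fly.copy()
        for g in ("bcd", "cad", "tll", "hkb"):
            prof = net.maternal.profile(g)
            prof.values = prof.values[::-1].copy()
        net.maternal.params = None
        rev = steady_state(net)
        fwd = steady_state(fly)
        for m in ("Kr", "kni", "eve37", "eve"):
            assert np.allclose(rev[m].values, fwd[m].values[::-1], atol=1e-9)


class TestFlyPattern:
    def test_gap_domain_order_matches_fly(self, fly, fly_ss):
        x = fly.grid.positions
        argmax = {m: x[fly_ss[m].values.argmax()] for m in
                  ("hb_ant", "Kr", "kni", "gt_post", "hb_post")}
        assert (argmax["hb_ant"] < argmax["Kr"] < argmax["kni"]
                < argmax["gt_post"] < argmax["hb_post"])

    def test_convergence_error_reports_residual(self, fly):
        from segevo.solver import ConvergenceError
        with pytest.raises(ConvergenceError, match="residual"):
            steady_state(fly, max_steps=3)


class TestKnockout:
    def test_gt_knockout_eve5_bounded_by_tll(self, fly):
        ss = steady_state(knockout(fly, "gt"))
        x = fly.grid.positions
        post = [s for s in call_stripes(ss["eve5"], fly.grid) if s.center > 0.5]
        assert post, "posterior eve5 expression expected"
        right = max(s.right for s in post)
        wt_right = 0.66
        tll_on = x[ss["tll"].values >= 0.3 * ss["tll"].values.max()].min()
        assert right > wt_right  # expanded posteriorly
        assert right < tll_on    # but stays anterior of the tll domain

    def test_hb_knockout_posterior_stripes_move_little(self, fly, fly_ss):
        """Posterior boundaries of stripes 6 and 7 expand by less than
        0.15 EL in an hb null: tll supplies backup posterior repression."""
        ss = steady_state(knockout(fly, "hb"))
        for m in ("eve37", "eve46"):
            wt = call_stripes(fly_ss[m], fly.grid).stripes[-1].right
            ko = call_stripes(ss[m], fly.grid).stripes[-1].right
            assert 0 <= ko - wt < 0.15

    def test_knockout_of_silent_module_is_noop(self, fly):
        once = knockout(fly, "eve5")
        twice = knockout(once, "eve5")
        a, b = steady_state(once), steady_state(twice)
        for m in once.solved_modules:
            assert np.array_equal(a[m].values, b[m].values)

    def test_unknown_id_rejected(self, fly):
        with pytest.raises(KeyError):
            knockout(fly, "nonexistent")

    def test_original_untouched(self, fly):
        before = fly.kernels["gt_post"].max_rate
        knockout(fly, "gt_post")
        assert fly.kernels["gt_post"].max_rate == before
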