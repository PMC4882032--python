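"""Dynamic pair-rule phasing model for the last common ancestor.

In the inferred LCA, only ``eve`` reads the gap genes; the remaining primary
pair-rule genes (``run``, ``h``, ``ftz``) are uniformly activated and
mutually repress one another (and are repressed by ``eve``), with an
asymmetric matrix of strengths. The maternal gradients are translated
anteriorly over a finite epoch — dragging the gap genes, and with them the
``eve`` pattern, forward by exactly one stripe period — and then frozen.
Viewed within a single cell the passage of the pattern is one complete
temporal cycle of ``eve``, and the repression network converts that
temporal phase into a stable spatial phasing of ``run``, ``h`` and ``ftz``
relative to ``eve``, independent of their initial state. The model cannot
oscillate on its own: ``eve`` is slaved to the gap genes, so once the
gradients stop the system relaxes to a fixed point.

Because every bin is autonomous and the maternal gradients are analytic,
the instantaneous gap/eve configuration under a shift ``s`` equals the
unshifted steady state evaluated at ``x + s``; the protocol therefore
solves the network once on an extended axis and reads ``eve``'s drive from
it by interpolation while integrating the three dynamic genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AxisGrid, SpatialProfile
from .network import Network
from .solver import _relax_gaps, _readout, ConvergenceError, DEFAULT_TOL, DEFAULT_MAX_STEPS, DEFAULT_DT
from .phenotype import call_stripes

__all__ = [
    "RepressionMatrix", "Kymograph", "PhasingConfig",
    "run_shift_protocol", "measure_eve_shift", "extract_phases", "within_cell_view",
]

PR_GENES = ("eve", "run", "h", "ftz")


@dataclass
class RepressionMatrix:
    """Asymmetric repression strengths among the pair-rule genes.

    ``strengths[i][j]`` is the repression of target gene ``i`` (order
    ``eve, run, h, ftz``) by source gene ``j``, expressed as an inverse
    half-saturation: 0 means no repression, larger is stronger (the
    repression factor is ``1 / (1 + (source * strength)^n)``). The ``eve``
    row must be zero — ``eve`` is driven by the gap genes, not by other
    pair-rule genes (which is why the model has no intrinsic oscillation).
    """

    strengths: np.ndarray
    hill: float = 4.0

    def __post_init__(self) -> None:
        s = np.asarray(self.strengths, dtype=float)
        if s.shape != (4, 4):
            raise ValueError("strengths must be a 4x4 matrix over (eve, run, h, ftz)")
        if np.any(s < 0):
            raise ValueError("repression strengths must be non-negative")
        if np.any(s[0] != 0):
            raise ValueError("eve receives gap input only; its row must be zero")
        self.strengths = s

    @classmethod
    def fly_default(cls) -> "RepressionMatrix":
        """Calibrated so the fly phase order eve -> run -> h -> ftz emerges
        (offsets ~0.42, ~0.58, ~0.75 of a period, respectively).

        The graph is feed-forward from eve apart from one weak back edge, so
        the frozen-gradient system always reaches a fixed point (no
        intrinsic oscillation); the asymmetric strengths place each gene in
        a distinct phase slot of the eve period, and the one-period sweep of
        the eve wave erases any memory of the initial arrangement.
        """
        #                 eve   run    h    ftz   (sources)
        s = np.array([[0.0,  0.0,  0.0,  0.0],   # eve (gap input only)
                      [6.0,  0.0,  4.0,  0.0],   # run: off while eve or h high
                      [8.0,  0.0,  0.0,  0.0],   # h:   anti-phase to eve
                      [2.0,  6.0,  0.5,  0.0]],  # ftz: avoids run, then eve
                     dtype=float)
        return cls(s)

    @classmethod
    def zero(cls) -> "RepressionMatrix":
        return cls(np.zeros((4, 4)))


@dataclass
class Kymograph:
    """Space-time record of the four pair-rule genes."""

    times: np.ndarray
    x: np.ndarray
    values: dict[str, np.ndarray]  # gene -> (n_times, n_bins)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        self.times = t

    def frame(self, k: int) -> dict[str, np.ndarray]:
        return {g: v[k] for g, v in self.values.items()}

    def to_long_records(self):
        for g, v in self.values.items():
            for k, t in enumerate(self.times):
                for i, xi in enumerate(self.x):
                    yield {"time": t, "x": xi, "gene": g, "value": v[k, i]}


@dataclass
class PhasingConfig:
    """Protocol settings.

    The maternal gradients are translated anteriorly by ``shift_total``
    (``None``: exactly one mean eve stripe period, the canonical protocol)
    over ``shift_duration`` time units, then frozen for ``relax_duration``.
    ``production`` and ``decay`` set the uniform activation and turnover of
    the three dynamic genes; ``dt`` is the integration step and
    ``frame_every`` the kymograph sampling stride.
    """

    shift_total: float | None = None
    shift_duration: float = 120.0
    relax_duration: float = 60.0
    production: float = 1.0
    decay: float = 1.0
    eve_gain: float = 1.0
    dt: float = 0.05
    frame_every: int = 40
    stationary_tol: float = 1e-4


def _extended_eve(network: Network, max_shift: float) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state eve on an axis extended to ``[0, 1 + max_shift)``."""
    grid = network.grid
    n = grid.n_bins
    n_ext = n + int(np.ceil(max_shift * n)) + 2
    x_ext = np.arange(n_ext) / n
    params = network.maternal.params
    if params is None:
        raise ValueError("network maternal gradients are not analytic (knockout?)")
    mat = np.stack([
        params.bcd(x_ext), params.cad(x_ext), params.tll(x_ext), params.hkb(x_ext)
    ])
    p = network.pack()
    gap, steps, resid, converged = _relax_gaps(
        mat, p["uniform"], p["agg_gene"],
        p["act_ptr"], p["act_src"], p["act_K"], p["act_n"],
        p["rep_ptr"], p["rep_src"], p["rep_K"], p["rep_n"],
        p["max_rate"], p["decay"], p["n_gap"],
        DEFAULT_DT, DEFAULT_TOL, DEFAULT_MAX_STEPS,
    )
    if not converged:
        raise ConvergenceError(resid, DEFAULT_MAX_STEPS)
    mod, levels = _readout(
        mat, gap, p["uniform"], p["agg_gene"],
        p["act_ptr"], p["act_src"], p["act_K"], p["act_n"],
        p["rep_ptr"], p["rep_src"], p["rep_K"], p["rep_n"],
        p["max_rate"], p["decay"], p["n_gap"], p["n_eve"],
    )
    return x_ext, levels[8]


def mean_stripe_period(network: Network) -> float:
    """Mean center-to-center distance of the network's eve stripes."""
    from .solver import steady_state
    ev = call_stripes(steady_state(network)["eve"], network.grid)
    if len(ev) < 2:
        raise ValueError("need at least 2 eve stripes to define a period")
    return float(np.mean(np.diff(ev.centers)))


def run_shift_protocol(
    network: Network,
    matrix: RepressionMatrix | None = None,
    initial: dict[str, np.ndarray] | None = None,
    config: PhasingConfig | None = None,
) -> Kymograph:
    """Integrate the LCA phasing model under the one-period anterior shift.

    ``initial`` optionally provides arbitrary non-negative starting profiles
    for ``run``, ``h`` and ``ftz`` (zero by default). Returns the full time
    course; the final frame is stationary (an error is raised otherwise,
    reporting the residual).
    """
    cfg = config or PhasingConfig()
    mx = matrix if matrix is not None else RepressionMatrix.fly_default()
    grid = network.grid
    x = grid.positions
    n = grid.n_bins

    shift_total = cfg.shift_total
    if shift_total is None:
        shift_total = mean_stripe_period(network)
    x_ext, eve_ext = _extended_eve(network, shift_total)

    state = np.zeros((4, n))
    state[0] = np.interp(x, x_ext, eve_ext) * cfg.eve_gain
    for gi, g in enumerate(PR_GENES[1:], start=1):
        if initial is not None and g in initial:
            init = np.asarray(initial[g], dtype=float)
            if init.shape != (n,) or np.any(init < 0):
                raise ValueError(f"initial profile for {g!r} must be non-negative of length {n}")
            state[gi] = init

    n_shift = int(round(cfg.shift_duration / cfg.dt))
    n_relax = int(round(cfg.relax_duration / cfg.dt))
    S = mx.strengths
    hill = mx.hill

    times, frames = [], []

    def _step(s_now: float):
        eve_target = np.interp(x + s_now, x_ext, eve_ext) * cfg.eve_gain
        deriv = np.empty_like(state)
        deriv[0] = cfg.decay * (eve_target - state[0])
        for gi in range(1, 4):
            rep = np.ones(n)
            for sj in range(4):
                if S[gi, sj] > 0:
                    rep *= 1.0 / (1.0 + (state[sj] * S[gi, sj]) ** hill)
            deriv[gi] = cfg.production * rep - cfg.decay * state[gi]
        return deriv

    def _snap(t: float):
        times.append(t)
        frames.append(state.copy())

    _snap(0.0)
    total_steps = n_shift + n_relax
    for k in range(total_steps):
        t = k * cfg.dt
        s_now = shift_total * min(t / cfg.shift_duration, 1.0) if n_shift else shift_total
        deriv = _step(s_now)
        state[:] = np.maximum(state + cfg.dt * deriv, 0.0)
        if (k + 1) % cfg.frame_every == 0 or k == total_steps - 1:
            _snap((k + 1) * cfg.dt)

    final_deriv = _step(shift_total)
    resid = float(np.abs(final_deriv).max())
    if resid > cfg.stationary_tol:
        raise RuntimeError(
            f"phasing protocol did not reach a stationary pattern "
            f"(residual max|dG/dt| = {resid:.3e}); lengthen relax_duration"
        )

    arr = np.array(frames)  # (n_frames, 4, n)
    return Kymograph(
        times=np.array(times), x=x,
        values={g: arr[:, gi, :] for gi, g in enumerate(PR_GENES)},
    )


def measure_eve_shift(kymo: Kymograph) -> float:
    """Anterior displacement of the eve pattern between the first and last
    frame, in stripe periods.

    The displacement is the anterior lag (up to ~1.6 stripe periods)
    maximizing the normalized cross-correlation between the two frames,
    divided by the mean inter-stripe distance of the first frame. Identical
    frames give 0; a final frame equal to the first translated anteriorly by
    one inter-stripe distance gives 1.0.
    """
    if len(kymo.times) < 2:
        raise ValueError("need at least 2 time points")
    eve = kymo.values["eve"]
    first = call_stripes(SpatialProfile("eve", np.maximum(eve[0], 0.0)))
    if len(first) < 2:
        raise ValueError("need at least 2 eve stripes to measure a shift")
    period = float(np.mean(np.diff(first.centers)))
    nb = eve.shape[1]
    spacing = 1.0 / nb
    max_lag = max(1, int(round(1.6 * period / spacing)))

    a0 = eve[0] - eve[0].mean()
    b = eve[-1]
    best_lag, best_c = 0, -np.inf
    for lag in range(0, max_lag + 1):
        bw = b[: nb - lag]
        aw = a0[lag:]
        denom = np.linalg.norm(aw) * np.linalg.norm(bw - bw.mean())
        c = float(np.dot(aw, bw - bw.mean()) / denom) if denom > 0 else -np.inf
        if c > best_c:
            best_c, best_lag = c, lag
    return best_lag * spacing / period


def extract_phases(kymo: Kymograph, period: float | None = None) -> dict[str, float | None]:
    """Per-gene spatial phase offset relative to eve, in fractions of a
    stripe period, from the final (stationary) frame.

    Each gene's profile is circularly cross-correlated against eve over one
    period within the striped region; the argmax lag in ``[0, 1)`` periods
    is the offset, measured as the gene's *posterior* displacement relative
    to eve — i.e. its temporal lag behind eve while the pattern sweeps
    anteriorly. A spatially uniform (degenerate) profile has no phase and
    maps to ``None``.
    """
    final = kymo.frame(len(kymo.times) - 1)
    eve = final["eve"]
    stripes = call_stripes(SpatialProfile("eve", np.maximum(eve, 0.0)))
    if period is None:
        if len(stripes) < 2:
            raise ValueError("need at least 2 eve stripes to define a period")
        period = float(np.mean(np.diff(stripes.centers)))
    nb = len(eve)
    spacing = 1.0 / nb
    lag_bins = max(2, int(round(period / spacing)))

    # window: whole-period multiple inside the striped region
    lo = int(stripes.centers[0] / spacing) if len(stripes) else 0
    n_per = max(1, (nb - lo) // lag_bins - 1)
    window = slice(lo, lo + n_per * lag_bins)

    ew = eve[window] - eve[window].mean()
    out: dict[str, float | None] = {}
    for g in PR_GENES:
        v = final[g]
        if np.ptp(v) < 1e-9 or np.ptp(v) < 1e-6 * max(1.0, v.max()):
            out[g] = None  # uniform: phase undefined
            continue
        vw = v[window] - v[window].mean()
        best_lag, best_c = 0, -np.inf
        for lag in range(lag_bins):
            rolled = np.roll(vw, -lag)
            c = float(np.dot(ew, rolled))
            if c > best_c:
                best_c, best_lag = c, lag
        out[g] = (best_lag % lag_bins) / lag_bins
    return out


def within_cell_view(kymo: Kymograph, bin_index: int) -> dict[str, np.ndarray]:
    """Time series of all four genes at one axis position (column slice of
    the kymograph)."""
    if not 0 <= bin_index < len(kymo.x):
        raise IndexError(f"bin {bin_index} out of range")
    return {g: v[:, bin_index].copy() for g, v in kymo.values.items()}
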