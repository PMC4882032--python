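"""The scalar objective (negative fitness, minimized) driving evolution
toward the mosquito gap configuration.

The objective is a sum of four non-negative components:

* ``f_gap`` — squared deviation of the posterior ``hb`` and ``gt`` profiles
  from the target set, over a posterior window;
* ``f_eve_ant`` — squared deviation of the ``eve`` profile from the fly
  pattern anterior of ``x_cut``;
* ``penalty_count`` — a large constant per missing ``eve`` stripe below the
  viability minimum of 7 (counting the unsimulated stripe 1);
* ``penalty_alt`` — a large constant per ``eve``/``ftz`` alternation
  violation (only when the network includes ``ftz``).

Profile terms compare max-normalized shapes, so they measure position, not
amplitude. The one exception is an elimination target (identically zero,
e.g. posterior ``gt`` in the mosquito): a shape comparison against zero is
ill-posed, so the profile is normalized by a fixed reference scale instead,
giving evolution a smooth gradient toward loss. The penalty constants are
large enough that a missing stripe always outweighs any achievable profile
deviation (soft-lexicographic constraints, as viability demands).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import AxisGrid, SpatialProfile
from .network import Network
from .fly import TargetSet
from .phenotype import (
    StripeTable, call_stripes, count_eve_stripes, check_alternation,
    DEFAULT_THRESHOLD_FRAC, DEFAULT_MIN_WIDTH_BINS,
)
from .solver import solve_profiles, ConvergenceError

__all__ = ["FitnessConfig", "FitnessReport", "profile_deviation", "evaluate_fitness", "WORST_TOTAL"]

logger = logging.getLogger(__name__)

#: total assigned when the steady state cannot be computed at all
WORST_TOTAL = 1e12


@dataclass
class FitnessConfig:
    """Weights, windows and constants of the objective.

    ``post_window_start`` bounds the posterior window (fractions of embryo
    length) over which the gap targets are scored; ``gt_ref_scale`` is the
    fixed normalization used for an elimination target (defaults to the fly
    posterior ``gt`` amplitude); the penalty constants are deliberately
    large (constraints, not trade-offs).
    """

    post_window_start: float = 0.60
    gt_ref_scale: float = 0.75
    w_gap: float = 1.0
    w_eve: float = 1.0
    c_count: float = 1000.0
    c_alt: float = 1000.0
    min_eve_total: int = 7
    counting_convention: bool = True
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    min_width_bins: int = DEFAULT_MIN_WIDTH_BINS
    norm_floor: float = 0.05


@dataclass
class FitnessReport:
    """Component breakdown of one network's objective value."""

    f_gap: float
    f_eve_ant: float
    penalty_count: float
    penalty_alt: float
    total: float
    eve_count: int = 0
    alternation_ok: bool = True
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "f_gap": self.f_gap, "f_eve_ant": self.f_eve_ant,
            "penalty_count": self.penalty_count, "penalty_alt": self.penalty_alt,
            "total": self.total, "eve_count": self.eve_count,
            "alternation_ok": self.alternation_ok, "converged": self.converged,
        }


def profile_deviation(
    p: SpatialProfile,
    target: SpatialProfile,
    window: slice | tuple[int, int] | np.ndarray | None = None,
    p_scale: float | None = None,
    t_scale: float | None = None,
    norm_floor: float = 0.0,
) -> float:
    """Sum over ``window`` of squared differences of max-normalized profiles.

    ``window`` is a bin range (slice, ``(start, stop)`` pair, or boolean
    mask); ``None`` means the whole axis. ``p_scale`` / ``t_scale`` override
    the normalization (used with a fixed reference scale for elimination
    targets); by default each profile is scaled by its own maximum, with
    maxima at or below ``norm_floor`` treated as absent (zero shape).
    """
    if len(p) != len(target):
        raise ValueError(
            f"profiles are not on the same grid ({len(p)} vs {len(target)} bins)"
        )
    if window is None:
        window = slice(None)
    elif isinstance(window, tuple):
        window = slice(*window)

    def _norm(prof: SpatialProfile, scale: float | None) -> np.ndarray:
        v = prof.values[window]
        if scale is None:
            # normalize by the maximum inside the window: the comparison is
            # about shape/position there, not about expression elsewhere
            m = float(v.max()) if len(v) else 0.0
            if m <= norm_floor or m == 0.0:
                return np.zeros_like(v)
            return v / m
        return v / scale

    d = _norm(p, p_scale) - _norm(target, t_scale)
    return float(np.sum(d * d))


def evaluate_fitness(
    network: Network,
    targets: TargetSet,
    config: FitnessConfig | None = None,
    profiles: dict[str, SpatialProfile] | None = None,
) -> FitnessReport:
    """Score ``network`` against ``targets``.

    Computes the steady state (unless precomputed ``profiles`` are given),
    calls stripes on the summed ``eve`` (and ``ftz``) profile, and assembles
    the four objective components. A steady-state failure is not an
    exception here: it yields the worst possible fitness with a logged
    warning, so an evolutionary run simply discards that mutant.
    """
    cfg = config or FitnessConfig()
    if profiles is None:
        try:
            profiles, _ = solve_profiles(network)
        except ConvergenceError as err:
            logger.warning("steady state failed during fitness evaluation: %s", err)
            return FitnessReport(
                f_gap=0.0, f_eve_ant=0.0, penalty_count=0.0, penalty_alt=0.0,
                total=WORST_TOTAL, converged=False,
            )

    grid = network.grid
    n = grid.n_bins
    post = slice(int(np.ceil(cfg.post_window_start * n)), n)
    ant = slice(0, int(np.floor(targets.x_cut * n)))

    # posterior gap deviation: hb by shape, gt against a fixed reference if
    # the target calls for elimination
    f_gap = cfg.w_gap * profile_deviation(
        profiles["hb"], targets.hb_post_target, post, norm_floor=cfg.norm_floor
    )
    if targets.gt_post_target.max <= cfg.norm_floor:
        f_gap += cfg.w_gap * profile_deviation(
            profiles["gt"], targets.gt_post_target, post,
            p_scale=cfg.gt_ref_scale, t_scale=1.0,
        )
    else:
        f_gap += cfg.w_gap * profile_deviation(
            profiles["gt"], targets.gt_post_target, post, norm_floor=cfg.norm_floor
        )

    f_eve_ant = cfg.w_eve * profile_deviation(
        profiles["eve"], targets.eve_anterior_target, ant, norm_floor=cfg.norm_floor
    )

    eve_table = call_stripes(
        profiles["eve"], grid,
        threshold_frac=cfg.threshold_frac, min_width_bins=cfg.min_width_bins,
        counting_convention=cfg.counting_convention,
    )
    eve_count = count_eve_stripes(eve_table)
    penalty_count = cfg.c_count * max(0, cfg.min_eve_total - eve_count)

    penalty_alt = 0.0
    alternation_ok = True
    if network.include_ftz:
        ftz_table = call_stripes(
            profiles["ftz"], grid,
            threshold_frac=cfg.threshold_frac, min_width_bins=cfg.min_width_bins,
        )
        violations = _count_alternation_violations(eve_table, ftz_table)
        alternation_ok = violations == 0
        penalty_alt = cfg.c_alt * violations

    total = f_gap + f_eve_ant + penalty_count + penalty_alt
    return FitnessReport(
        f_gap=float(f_gap), f_eve_ant=float(f_eve_ant),
        penalty_count=float(penalty_count), penalty_alt=float(penalty_alt),
        total=float(total), eve_count=int(eve_count),
        alternation_ok=bool(alternation_ok),
    )


def _count_alternation_violations(eve_table: StripeTable, ftz_table: StripeTable) -> int:
    merged = sorted(
        [(s.center, "eve") for s in eve_table] + [(s.center, "ftz") for s in ftz_table]
    )
    return sum(1 for (c0, g0), (c1, g1) in zip(merged, merged[1:]) if g0 == g1)
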