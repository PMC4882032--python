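"""Factory for the idealized Drosophila starting network and the synthetic
target profiles that drive the evolutionary runs.

The default parameterization (shipped as ``data/fly_default.json``) was
calibrated once so that the steady state reproduces the canonical fly
phenotype: the gap domain order anterior-hb, Kr, kni, posterior-gt,
posterior-hb; six simulated ``eve`` stripes (2-7; stripe 1 is not modeled);
and, with ``ftz`` included, seven ``ftz`` stripes strictly alternating with
``eve``.

The mosquito target is synthetic (no quantitative Anopheles profiles are
deposited anywhere): the posterior ``hb`` bump translated anteriorly by a
configurable fraction of embryo length, posterior ``gt`` absent, and the
fly's own anterior ``eve`` pattern below a cut position ``x_cut``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .grid import AxisGrid, SpatialProfile
from .network import Network
from . import io as _io
from .solver import steady_state

__all__ = ["make_fly_network", "make_targets", "make_fly_targets", "TargetSet", "TargetConfig"]

_DEFAULT_PARAMS_FILE = "fly_default.json"

#: The ftz-as-primary variant replaces the zebra element's eve input with the
#: gap-gene delimitation of a hypothetical stand-alone ftz stripe-4 module,
#: and raises the gap-driven ftz modules to full strength so they, not the
#: zebra element, carry the seven-stripe pattern.
_PRIMARY_OVERRIDES = {
    "ftz4zebra": {
        "activators": [["UNIFORM", 0.2, 2]],
        "repressors": [["hb", 0.05, 8], ["Kr", 0.45, 4], ["kni", 0.5, 4], ["gt", 0.1, 4], ["tll", 0.1, 4]],
        "evolvable": ["max_rate", "rep:hb:K", "rep:Kr:K", "rep:kni:K", "rep:gt:K", "rep:tll:K"],
    },
}
_PRIMARY_RATES = {"ftz15": 1.0, "ftz27": 1.0, "ftz36": 1.0, "ftz4zebra": 1.0}


def default_network_dict() -> dict:
    """The shipped fly parameter document (deep copy, safe to edit)."""
    text = resources.files("segevo.data").joinpath(_DEFAULT_PARAMS_FILE).read_text()
    return json.loads(text)


def make_fly_network(
    grid: AxisGrid | None = None,
    config: dict | None = None,
    include_ftz: bool | None = None,
    ftz_mode: str = "secondary",
) -> Network:
    """Build the calibrated Drosophila starting network.

    Parameters
    ----------
    grid
        Spatial axis; must match the calibrated 200-bin default if given.
    config
        Optional overrides, ``{module: {param_name: value}}`` with parameter
        names as in :meth:`segevo.kernels.KernelSpec.param_names`.
    include_ftz
        Override the shipped ``include_ftz`` flag.
    ftz_mode
        ``"secondary"`` (default): the zebra element is repressed by ``eve``
        only, slaving posterior ``ftz`` to ``eve``. ``"primary"``: the zebra
        element is replaced by a purely gap-delimited stripe-4 module, making
        ``ftz`` a primary pair-rule gene (the configuration whose evolution
        toward the mosquito pattern fails).
    """
    doc = default_network_dict()
    if grid is not None:
        doc["grid"]["n_bins"] = grid.n_bins
    if include_ftz is not None:
        doc["include_ftz"] = include_ftz
    if ftz_mode not in ("secondary", "primary"):
        raise ValueError(f"ftz_mode must be 'secondary' or 'primary', got {ftz_mode!r}")
    if ftz_mode == "primary":
        for name, patch in _PRIMARY_OVERRIDES.items():
            doc["kernels"][name].update(patch)
        for name, rate in _PRIMARY_RATES.items():
            doc["kernels"][name]["max_rate"] = rate

    net = _io.network_from_dict(doc)

    if config:
        missing = []
        for module, params in config.items():
            if module not in net.kernels:
                missing.append(module)
                continue
            for pname, value in params.items():
                try:
                    net.kernels[module].set_param(pname, value)
                except KeyError:
                    missing.append(f"{module}.{pname}")
        if missing:
            raise ValueError(f"config names unknown kernels/parameters: {missing}")
    return net


@dataclass
class TargetConfig:
    """Geometry of the evolutionary target profiles.

    ``hb_shift`` is the anterior translation (fraction of embryo length)
    applied to the fly's posterior ``hb`` bump to produce the mosquito-like
    target; ``x_cut`` bounds the window over which the anterior ``eve``
    pattern is constrained to remain fly-like.
    """

    hb_shift: float = 0.08
    x_cut: float = 0.50


@dataclass
class TargetSet:
    """Profiles the fitness function scores a network against."""

    hb_post_target: SpatialProfile
    gt_post_target: SpatialProfile
    eve_anterior_target: SpatialProfile
    x_cut: float

    def anterior_bins(self, grid: AxisGrid) -> int:
        """Number of bins in the anterior eve window, ``floor(x_cut * n_bins)``."""
        return int(np.floor(self.x_cut * grid.n_bins))


def _shift_anterior(values: np.ndarray, grid: AxisGrid, shift: float) -> np.ndarray:
    """Translate a sampled profile anteriorly by ``shift`` (zero-filled at the
    posterior edge)."""
    x = grid.positions
    return np.interp(x + shift, x, values, right=0.0)


def make_targets(
    grid: AxisGrid | None = None,
    config: TargetConfig | None = None,
    fly: Network | None = None,
) -> TargetSet:
    """Mosquito-like target set.

    Posterior ``hb`` is the fly bump moved anteriorly by ``config.hb_shift``;
    posterior ``gt`` is identically zero (assumed absent / non-patterning in
    the mosquito); the anterior ``eve`` target is the fly steady state, to be
    compared only for ``x < x_cut``.
    """
    cfg = config or TargetConfig()
    net = fly if fly is not None else make_fly_network(grid)
    grid = net.grid
    if not 0.0 <= cfg.hb_shift < 1.0:
        raise ValueError(f"hb_shift must be within the axis, got {cfg.hb_shift}")
    ss = steady_state(net)
    mask = grid.positions >= cfg.x_cut
    return TargetSet(
        hb_post_target=SpatialProfile(
            "hb_post", _shift_anterior(ss["hb"].values, grid, cfg.hb_shift) * mask
        ),
        gt_post_target=SpatialProfile("gt_post", np.zeros(grid.n_bins)),
        eve_anterior_target=ss["eve"].copy(),
        x_cut=cfg.x_cut,
    )


def make_fly_targets(
    grid: AxisGrid | None = None,
    config: TargetConfig | None = None,
    fly: Network | None = None,
) -> TargetSet:
    """Target set for the reverse (LCA back to Drosophila) experiment: the
    fly's own posterior ``hb`` and ``gt`` profiles and anterior ``eve``."""
    cfg = config or TargetConfig()
    net = fly if fly is not None else make_fly_network(grid)
    ss = steady_state(net)
    mask = net.grid.positions >= cfg.x_cut
    return TargetSet(
        hb_post_target=SpatialProfile("hb_post", ss["hb"].values * mask),
        gt_post_target=SpatialProfile("gt_post", ss["gt"].values * mask),
        eve_anterior_target=ss["eve"].copy(),
        x_cut=cfg.x_cut,
    )
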