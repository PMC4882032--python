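"""Maternal positional-information gradients.

Four frozen inputs provide all positional information in the model:

* ``bcd`` — anterior exponential gradient (Bicoid); frozen throughout
  evolution.
* ``cad`` — posterior gradient (Caudal), modeled as uniform expression
  repressed by ``bcd``, hence monotonically rising toward the posterior.
* ``tll`` — terminal sigmoid (Tailless) confined to the posterior cap.
* ``hkb`` — terminal sigmoid (Huckebein) posterior to the ``tll`` onset.

The gradients are analytic functions of axis position so they can be
evaluated at arbitrary (including shifted or out-of-grid) positions; the
dynamic phasing protocol exploits this to translate the whole coordinate
system anteriorly in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .grid import AxisGrid, SpatialProfile

__all__ = ["MaternalParams", "MaternalSet", "build_maternal", "MATERNAL_GENES"]

MATERNAL_GENES = ("bcd", "cad", "tll", "hkb")

MAX_SHIFT = 0.3


@dataclass(frozen=True)
class MaternalParams:
    """Shape parameters of the analytic gradient family.

    ``bcd_lambda`` is the Bicoid exponential length scale (fractions of embryo
    length); ``cad_k`` the Bicoid level half-repressing Caudal; ``tll_x`` /
    ``hkb_x`` the sigmoid midpoints and ``tll_w`` / ``hkb_w`` their widths.
    """

    bcd_lambda: float = 0.15
    cad_k: float = 0.01
    cad_n: float = 2.0
    tll_x: float = 0.86
    tll_w: float = 0.022
    hkb_x: float = 0.95
    hkb_w: float = 0.01

    def bcd(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-np.asarray(x, dtype=float) / self.bcd_lambda)

    def cad(self, x: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 + (self.bcd(x) / self.cad_k) ** self.cad_n)

    def tll(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-(x - self.tll_x) / self.tll_w))

    def hkb(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-(x - self.hkb_x) / self.hkb_w))

    def evaluate(self, x: np.ndarray, shift: float = 0.0) -> dict[str, np.ndarray]:
        """All four gradients at positions ``x``, translated anteriorly.

        A positive ``shift`` moves every feature toward the anterior: the
        gradient value seen at ``x`` is the unshifted value at ``x + shift``.
        """
        xs = np.asarray(x, dtype=float) + shift
        return {
            "bcd": np.asarray(self.bcd(xs)),
            "cad": np.asarray(self.cad(xs)),
            "tll": np.asarray(self.tll(xs)),
            "hkb": np.asarray(self.hkb(xs)),
        }

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MaternalSet:
    """The four maternal profiles sampled on a grid, plus their generator.

    The profiles are frozen: the evolutionary algorithm never mutates them
    (``bcd`` explicitly so, per the model's assumptions). ``params`` is kept
    so the analytic form can be re-evaluated off-grid; it is ``None`` after a
    maternal knockout, which zeroes the sampled profile.
    """

    bcd: SpatialProfile
    cad: SpatialProfile
    tll: SpatialProfile
    hkb: SpatialProfile
    frozen: bool = True
    params: MaternalParams | None = None
    shift: float = 0.0

    def profile(self, gene: str) -> SpatialProfile:
        if gene not in MATERNAL_GENES:
            raise KeyError(f"unknown maternal gene {gene!r}")
        return getattr(self, gene)

    def as_array(self) -> np.ndarray:
        """Stacked ``(4, n_bins)`` array in canonical order bcd, cad, tll, hkb."""
        return np.stack([getattr(self, g).values for g in MATERNAL_GENES])

    def copy(self) -> "MaternalSet":
        return MaternalSet(
            self.bcd.copy(), self.cad.copy(), self.tll.copy(), self.hkb.copy(),
            frozen=self.frozen, params=self.params, shift=self.shift,
        )


def build_maternal(
    grid: AxisGrid,
    shift: float = 0.0,
    params: MaternalParams | None = None,
) -> MaternalSet:
    """Sample the maternal gradients on ``grid``.

    Parameters
    ----------
    grid
        Spatial axis.
    shift
        Anterior translation of all four gradients, as a fraction of embryo
        length, in ``[0, 0.3]``. ``shift = 0`` is the default fly
        configuration; nonzero shifts drive the gap genes (and with them the
        ``eve`` pattern) forward, which the dynamic phasing protocol uses.
    params
        Gradient shape parameters; defaults reproduce the calibrated fly
        configuration.
    """
    if not 0.0 <= shift <= MAX_SHIFT:
        raise ValueError(f"shift must be in [0, {MAX_SHIFT}], got {shift}")
    p = params or MaternalParams()
    levels = p.evaluate(grid.positions, shift=shift)
    return MaternalSet(
        bcd=SpatialProfile("bcd", levels["bcd"]),
        cad=SpatialProfile("cad", levels["cad"]),
        tll=SpatialProfile("tll", levels["tll"]),
        hkb=SpatialProfile("hkb", levels["hkb"]),
        frozen=True,
        params=p,
        shift=shift,
    )
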