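"""The gene-regulatory network container.

A :class:`Network` bundles the frozen maternal gradient set, one kernel per
gap-gene domain and per pair-rule module, the level of the generic uniform
activator, and the registry of evolvable parameters. The kernel set and the
interaction topology are fixed at construction; evolution only rescales
numerical parameter values (and may drive a module's ``max_rate`` to zero,
its elimination).

Genes versus modules
--------------------
Repression acts at the level of *gene products*, which sum the outputs of the
modules transcribing them: ``hb = hb_ant + hb_post``, ``gt = gt_ant +
gt_post``, ``eve = eve2 + eve37 + eve46 + eve5`` and ``ftz`` the sum of its
four modules. Kernels therefore name genes (or maternal gradients) as
regulators, never individual modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AxisGrid, SpatialProfile
from .kernels import KernelSpec, UNIFORM, N_MIN, N_MAX
from .maternal import MaternalSet, MATERNAL_GENES

__all__ = [
    "Network", "ParamRegistry", "knockout",
    "GAP_MODULES", "EVE_MODULES", "FTZ_MODULES", "MODULE_GENE", "GENE_ORDER",
]

GAP_MODULES = ("hb_ant", "hb_post", "Kr", "kni", "gt_ant", "gt_post")
EVE_MODULES = ("eve2", "eve37", "eve46", "eve5")
FTZ_MODULES = ("ftz15", "ftz27", "ftz36", "ftz4zebra")

MODULE_GENE = {
    "hb_ant": "hb", "hb_post": "hb", "Kr": "Kr", "kni": "kni",
    "gt_ant": "gt", "gt_post": "gt",
    "eve2": "eve", "eve37": "eve", "eve46": "eve", "eve5": "eve",
    "ftz15": "ftz", "ftz27": "ftz", "ftz36": "ftz", "ftz4zebra": "ftz",
}

#: Canonical order of the per-bin level array used by the solver.
GENE_ORDER = ("bcd", "cad", "tll", "hkb", "hb", "Kr", "kni", "gt", "eve", "ftz")

_GENE_INDEX = {g: i for i, g in enumerate(GENE_ORDER)}

# bounds for parameter clamping during mutation
_BOUNDS = {"max_rate": (0.0, 5.0), "K": (1e-3, 50.0), "n": (N_MIN, N_MAX)}


@dataclass
class ParamRegistry:
    """Flat view of every kernel parameter of a network.

    ``entries[i]`` is ``(module, param_name)``; ``evolvable`` marks the
    parameters the mutation operator may touch; ``lo``/``hi`` are clamp
    bounds applied after each multiplicative perturbation.
    """

    entries: list[tuple[str, str]]
    evolvable: np.ndarray  # bool
    lo: np.ndarray
    hi: np.ndarray

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def evolvable_indices(self) -> np.ndarray:
        return np.flatnonzero(self.evolvable)

    def index_of(self, module: str, param: str) -> int:
        return self.entries.index((module, param))


class Network:
    """Maternal inputs plus the full, fixed kernel set.

    Parameters
    ----------
    maternal
        Frozen gradient set sampled on ``grid``.
    kernels
        One :class:`~segevo.kernels.KernelSpec` per module; must cover all
        six gap modules and the four ``eve`` modules, plus the four ``ftz``
        modules when ``include_ftz``.
    uniform_activator
        Level of the generic spatially uniform activator seen by kernels
        with a ``UNIFORM`` activator term.
    include_ftz
        Whether the ``ftz`` modules participate in the simulated phenotype.
    """

    def __init__(
        self,
        grid: AxisGrid,
        maternal: MaternalSet,
        kernels: dict[str, KernelSpec],
        uniform_activator: float = 1.0,
        include_ftz: bool = True,
        loss_threshold: float = 0.05,
    ):
        required = GAP_MODULES + EVE_MODULES + (FTZ_MODULES if include_ftz else ())
        missing = [m for m in required if m not in kernels]
        if missing:
            raise ValueError(f"missing kernels for modules: {missing}")
        unknown = [m for m in kernels if m not in MODULE_GENE]
        if unknown:
            raise ValueError(f"unknown module names: {unknown}")
        for name, k in kernels.items():
            if k.target != name:
                raise ValueError(f"kernel registered as {name!r} targets {k.target!r}")
            bad = k.regulators() - set(GENE_ORDER)
            if bad:
                raise ValueError(f"kernel {name!r} names unknown regulators {sorted(bad)}")
        if not uniform_activator >= 0:
            raise ValueError("uniform_activator must be >= 0")

        self.grid = grid
        self.maternal = maternal
        self.kernels = {m: kernels[m] for m in MODULE_GENE if m in kernels}  # canonical order
        self.uniform_activator = float(uniform_activator)
        self.include_ftz = bool(include_ftz)
        self.loss_threshold = float(loss_threshold)
        self._registry: ParamRegistry | None = None

    # -- registries ---------------------------------------------------------

    @property
    def module_names(self) -> list[str]:
        return list(self.kernels)

    @property
    def solved_modules(self) -> list[str]:
        """Modules the solver integrates, in solve order (gaps, eve, ftz)."""
        mods = list(GAP_MODULES) + list(EVE_MODULES)
        if self.include_ftz:
            mods += list(FTZ_MODULES)
        return mods

    def registry(self) -> ParamRegistry:
        if self._registry is None:
            entries, evolv, lo, hi = [], [], [], []
            for mname, k in self.kernels.items():
                for pname in k.param_names():
                    entries.append((mname, pname))
                    evolv.append(pname in k.evolvable)
                    kind = "max_rate" if pname == "max_rate" else pname.rsplit(":", 1)[1]
                    b = _BOUNDS[kind]
                    lo.append(b[0])
                    hi.append(b[1])
            self._registry = ParamRegistry(
                entries, np.array(evolv, dtype=bool),
                np.array(lo), np.array(hi),
            )
        return self._registry

    def param_vector(self) -> np.ndarray:
        reg = self.registry()
        return np.array([self.kernels[m].get_param(p) for m, p in reg.entries])

    def set_param_vector(self, values: np.ndarray) -> None:
        reg = self.registry()
        if len(values) != len(reg):
            raise ValueError("parameter vector length mismatch")
        for (m, p), v in zip(reg.entries, values):
            self.kernels[m].set_param(p, v)

    @property
    def n_active_modules(self) -> int:
        return sum(1 for m in self.solved_modules if not self.kernels[m].eliminated)

    def copy(self) -> "Network":
        net = Network(
            grid=self.grid,
            maternal=self.maternal.copy(),
            kernels={m: k.copy() for m, k in self.kernels.items()},
            uniform_activator=self.uniform_activator,
            include_ftz=self.include_ftz,
            loss_threshold=self.loss_threshold,
        )
        return net

    # -- solver packing -----------------------------------------------------

    def pack(self) -> dict[str, np.ndarray | float]:
        """Flatten the kernel set into arrays consumed by the compiled solver."""
        mods = self.solved_modules
        agg_gene = np.array([_GENE_INDEX[MODULE_GENE[m]] for m in mods], dtype=np.int64)
        act_ptr, act_src, act_K, act_n = [0], [], [], []
        rep_ptr, rep_src, rep_K, rep_n = [0], [], [], []
        max_rate, decay = [], []
        for m in mods:
            k = self.kernels[m]
            for t in k.activator_terms:
                act_src.append(-1 if t.regulator == UNIFORM else _GENE_INDEX[t.regulator])
                act_K.append(t.K)
                act_n.append(t.n)
            act_ptr.append(len(act_src))
            for t in k.repressor_terms:
                rep_src.append(_GENE_INDEX[t.regulator])
                rep_K.append(t.K)
                rep_n.append(t.n)
            rep_ptr.append(len(rep_src))
            max_rate.append(k.max_rate)
            decay.append(k.decay)
        return dict(
            maternal=self.maternal.as_array(),
            uniform=self.uniform_activator,
            agg_gene=agg_gene,
            act_ptr=np.array(act_ptr, dtype=np.int64),
            act_src=np.array(act_src, dtype=np.int64),
            act_K=np.array(act_K, dtype=float),
            act_n=np.array(act_n, dtype=float),
            rep_ptr=np.array(rep_ptr, dtype=np.int64),
            rep_src=np.array(rep_src, dtype=np.int64),
            rep_K=np.array(rep_K, dtype=float),
            rep_n=np.array(rep_n, dtype=float),
            max_rate=np.array(max_rate, dtype=float),
            decay=np.array(decay, dtype=float),
            n_gap=len(GAP_MODULES),
            n_eve=len(EVE_MODULES),
        )


def knockout(network: Network, target: str) -> Network:
    """Null mutant: copy of ``network`` with ``target`` silenced.

    ``target`` may be a module (its ``max_rate`` is zeroed), a zygotic gene
    (all of its modules are zeroed) or a maternal gradient (its profile is
    zeroed). The original network is untouched.
    """
    net = network.copy()
    if target in net.kernels:
        net.kernels[target].max_rate = 0.0
    elif target in ("hb", "Kr", "kni", "gt", "eve", "ftz"):
        for m, g in MODULE_GENE.items():
            if g == target and m in net.kernels:
                net.kernels[m].max_rate = 0.0
    elif target in MATERNAL_GENES:
        prof = net.maternal.profile(target)
        prof.values = np.zeros_like(prof.values)
        net.maternal.params = None  # analytic form no longer matches
    else:
        raise KeyError(f"unknown gene or module id {target!r}")
    return net
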