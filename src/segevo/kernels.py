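"""Transcriptional interaction kernels.

Each gap gene and each pair-rule regulatory module (enhancer) is modeled by
one *kernel*: a map from the local levels of its regulators to a production
rate,

    rate = max_rate * activation * prod_r 1 / (1 + (R_r / K_r)^n_r)

with a saturating Hill activation factor in [0, 1] (product over activator
terms) and one multiplicative Hill repression factor per repressor. All
positional information enters through repression; activators are either
spatially uniform or broad maternal gradients and serve only to gate overall
expression. Expression decays linearly, so a kernel's steady-state output is
bounded by ``max_rate / decay``.

The kernel set of a network is fixed at construction. Evolution changes only
the numerical parameter values registered as evolvable; it never adds new
kernels or new inputs to existing kernels. A kernel whose ``max_rate`` is
driven to zero is *eliminated* (standing in for enhancer loss) but stays in
the registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["Term", "KernelSpec", "evaluate_kernel", "UNIFORM", "N_MIN", "N_MAX"]

#: Pseudo-regulator name for the generic spatially uniform activator.
UNIFORM = "UNIFORM"

N_MIN, N_MAX = 1.0, 8.0


@dataclass
class Term:
    """One Hill term: regulator id, half-saturation ``K``, cooperativity ``n``."""

    regulator: str
    K: float
    n: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"half-saturation for {self.regulator!r} must be > 0, got {self.K}")
        if not N_MIN <= self.n <= N_MAX:
            raise ValueError(
                f"cooperativity for {self.regulator!r} must be in [{N_MIN:g}, {N_MAX:g}], got {self.n}"
            )


@dataclass
class KernelSpec:
    """Regulation law of one transcriptional module.

    Parameters addressable for mutation are named ``"max_rate"``,
    ``"act:<reg>:K"``, ``"act:<reg>:n"``, ``"rep:<reg>:K"`` and
    ``"rep:<reg>:n"``; ``evolvable`` lists the subset open to the
    evolutionary algorithm.
    """

    target: str
    max_rate: float
    activator_terms: list[Term] = field(default_factory=list)
    repressor_terms: list[Term] = field(default_factory=list)
    decay: float = 1.0
    evolvable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.max_rate < 0:
            raise ValueError(f"{self.target}: max_rate must be >= 0, got {self.max_rate}")
        if not self.decay > 0:
            raise ValueError(f"{self.target}: decay must be > 0, got {self.decay}")
        for name in self.evolvable:
            if name not in self.param_names():
                raise ValueError(f"{self.target}: evolvable parameter {name!r} does not exist")

    # -- parameter registry -------------------------------------------------

    def param_names(self) -> list[str]:
        names = ["max_rate"]
        names += [f"act:{t.regulator}:{p}" for t in self.activator_terms for p in ("K", "n")]
        names += [f"rep:{t.regulator}:{p}" for t in self.repressor_terms for p in ("K", "n")]
        return names

    def _locate(self, name: str) -> tuple[object, str]:
        if name == "max_rate":
            return self, "max_rate"
        kind, reg, attr = name.split(":")
        terms = self.activator_terms if kind == "act" else self.repressor_terms
        for t in terms:
            if t.regulator == reg:
                return t, attr
        raise KeyError(f"{self.target}: no parameter {name!r}")

    def get_param(self, name: str) -> float:
        obj, attr = self._locate(name)
        return float(getattr(obj, attr))

    def set_param(self, name: str, value: float) -> None:
        obj, attr = self._locate(name)
        setattr(obj, attr, float(value))

    def regulators(self) -> set[str]:
        regs = {t.regulator for t in self.repressor_terms}
        regs |= {t.regulator for t in self.activator_terms if t.regulator != UNIFORM}
        return regs

    @property
    def eliminated(self) -> bool:
        return self.max_rate == 0.0

    def copy(self) -> "KernelSpec":
        return KernelSpec(
            target=self.target,
            max_rate=self.max_rate,
            activator_terms=[Term(t.regulator, t.K, t.n) for t in self.activator_terms],
            repressor_terms=[Term(t.regulator, t.K, t.n) for t in self.repressor_terms],
            decay=self.decay,
            evolvable=set(self.evolvable),
        )


def _hill_act(level: float, K: float, n: float) -> float:
    r = (level / K) ** n
    return r / (1.0 + r)


def evaluate_kernel(kernel: KernelSpec, local_levels: Mapping[str, float]) -> float:
    """Production rate of ``kernel`` given local regulator levels.

    Scalar reference implementation of the kernel law (the relaxation solver
    uses a compiled equivalent). The rate is non-decreasing in every
    activator level, non-increasing in every repressor level, and bounded in
    ``[0, max_rate]``.

    Raises
    ------
    KeyError
        If a regulator named by the kernel is missing from ``local_levels``.
    ValueError
        If any supplied level is negative.
    """
    for name, level in local_levels.items():
        if level < 0:
            raise ValueError(f"negative level for regulator {name!r}: {level}")

    def _level(reg: str) -> float:
        if reg not in local_levels:
            raise KeyError(f"kernel {kernel.target!r}: regulator {reg!r} missing from levels")
        return float(local_levels[reg])

    act = 1.0
    for t in kernel.activator_terms:
        if t.regulator == UNIFORM:
            level = float(local_levels.get(UNIFORM, 1.0))
        else:
            level = _level(t.regulator)
        act *= _hill_act(level, t.K, t.n)

    rep = 1.0
    for t in kernel.repressor_terms:
        rep *= 1.0 / (1.0 + (_level(t.regulator) / t.K) ** t.n)

    return kernel.max_rate * act * rep
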