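"""Serialization of networks, profiles and run artifacts.

All on-disk formats are structured text: networks and configurations as
JSON, expression profiles and kymographs as TSV, trajectory logs as
line-delimited JSON. Round-trips preserve every parameter exactly (floats
are written with full ``repr`` precision).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import AxisGrid, SpatialProfile
from .kernels import KernelSpec, Term
from .maternal import MaternalParams, build_maternal
from .network import Network

__all__ = [
    "network_to_dict", "network_from_dict", "save_network", "load_network",
    "export_profiles", "import_profiles", "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

_TOP_KEYS = {
    "schema_version", "grid", "maternal", "uniform_activator",
    "include_ftz", "loss_threshold", "kernels",
}
_KERNEL_KEYS = {"max_rate", "decay", "activators", "repressors", "evolvable"}


def network_to_dict(network: Network) -> dict:
    if network.maternal.params is None:
        raise ValueError(
            "network has a zeroed maternal profile (knockout); only networks "
            "with analytic maternal gradients are serializable"
        )
    kernels = {}
    for name, k in network.kernels.items():
        kernels[name] = {
            "max_rate": k.max_rate,
            "decay": k.decay,
            "activators": [[t.regulator, t.K, t.n] for t in k.activator_terms],
            "repressors": [[t.regulator, t.K, t.n] for t in k.repressor_terms],
            "evolvable": sorted(k.evolvable),
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "grid": {"n_bins": network.grid.n_bins},
        "maternal": {
            "params": network.maternal.params.to_dict(),
            "shift": network.maternal.shift,
        },
        "uniform_activator": network.uniform_activator,
        "include_ftz": network.include_ftz,
        "loss_threshold": network.loss_threshold,
        "kernels": kernels,
    }


def _migrate_v0(doc: dict) -> dict:
    """Schema 0 stored Hill terms as {regulator, K, hill} mappings."""
    doc = dict(doc)
    kernels = {}
    for name, k in doc.get("kernels", {}).items():
        k = dict(k)
        for side in ("activators", "repressors"):
            terms = []
            for t in k.get(side, []):
                if isinstance(t, Mapping):
                    terms.append([t["regulator"], t["K"], t["hill"]])
                else:
                    terms.append(list(t))
            k[side] = terms
        kernels[name] = k
    doc["kernels"] = kernels
    doc["schema_version"] = SCHEMA_VERSION
    return doc


def network_from_dict(doc: Mapping) -> Network:
    version = doc.get("schema_version")
    if version == 0:
        warnings.warn(
            "loading legacy schema version 0 network document; migrating",
            UserWarning, stacklevel=2,
        )
        doc = _migrate_v0(dict(doc))
        version = SCHEMA_VERSION
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version!r}")

    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown field(s) in network document: {sorted(unknown)}")
    for req in ("grid", "maternal", "kernels"):
        if req not in doc:
            raise ValueError(f"network document missing required field {req!r}")

    grid = AxisGrid(int(doc["grid"]["n_bins"]))
    mat_doc = doc["maternal"]
    maternal = build_maternal(
        grid,
        shift=float(mat_doc.get("shift", 0.0)),
        params=MaternalParams(**mat_doc["params"]),
    )

    kernels = {}
    for name, kd in doc["kernels"].items():
        unknown = set(kd) - _KERNEL_KEYS
        if unknown:
            raise ValueError(f"kernel {name!r}: unknown field(s) {sorted(unknown)}")
        kernels[name] = KernelSpec(
            target=name,
            max_rate=float(kd["max_rate"]),
            decay=float(kd.get("decay", 1.0)),
            activator_terms=[Term(r, float(K), float(n)) for r, K, n in kd.get("activators", [])],
            repressor_terms=[Term(r, float(K), float(n)) for r, K, n in kd.get("repressors", [])],
            evolvable=set(kd.get("evolvable", [])),
        )

    return Network(
        grid=grid,
        maternal=maternal,
        kernels=kernels,
        uniform_activator=float(doc.get("uniform_activator", 1.0)),
        include_ftz=bool(doc.get("include_ftz", True)),
        loss_threshold=float(doc.get("loss_threshold", 0.05)),
    )


def save_network(network: Network, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(network_to_dict(network), indent=1))
    return path


def load_network(path: str | Path) -> Network:
    doc = json.loads(Path(path).read_text())
    return network_from_dict(doc)


def export_profiles(
    profiles: Mapping[str, SpatialProfile] | Iterable[SpatialProfile],
    path: str | Path,
    grid: AxisGrid | None = None,
) -> Path:
    """Write profiles as TSV: an ``x`` column then one column per gene/module,
    one row per bin, full float precision."""
    if isinstance(profiles, Mapping):
        profs = list(profiles.values())
    else:
        profs = list(profiles)
    lengths = {len(p) for p in profs}
    if len(lengths) > 1:
        raise ValueError("profiles are not on a common grid")
    n = lengths.pop() if lengths else 0  # no profiles: header-only file
    x = (grid or AxisGrid(max(n, 50))).positions[:n] if n else np.array([])
    frame = pd.DataFrame({"x": x})
    for p in profs:
        frame[p.gene] = p.values
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def import_profiles(path: str | Path) -> dict[str, SpatialProfile]:
    frame = pd.read_csv(path, sep="\t")
    return {
        c: SpatialProfile(c, frame[c].to_numpy(dtype=float))
        for c in frame.columns if c != "x"
    }
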