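"""Network geometry and connectivity.

Four one-dimensional layers: 200 pyramidal (PY), 40 interneuron (IN),
40 thalamocortical relay (TC) and 40 reticular (RE) cells.  Every
projection has a receptor type, a total synaptic conductance per target
cell and a connection radius.  Radii are interpreted on the target layer's
own index scale by default: a source cell at fine index i is mapped to the
target grid by the centered affine map

    x = (i + 0.5) * n_tgt / n_src - 0.5

and connects to every target j with |x - j| <= radius (open boundaries,
no wrap-around; no self-connections within a layer).  A config switch
selects the alternative source-scale interpretation.

The total conductance of a projection is divided by each target's own
in-degree, so boundary cells receive the same total drive as interior
cells.

The miniature-EPSP drive that seeds each slow-oscillation cycle is a
Poisson process per cortical cell onto the PY-PY / PY-IN AMPA pathway,
gated by the engine (re-armed 100 ms after an SO cycle terminates, removed
once the next cycle initiates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .synapses import Receptor

__all__ = [
    "Layer",
    "LayerGeometry",
    "Projection",
    "MiniDrive",
    "NetworkModel",
    "PROJECTIONS",
    "build_network",
    "connection_windows",
    "mini_drive_step",
]


class Layer(str, Enum):
    PY = "PY"
    IN = "IN"
    TC = "TC"
    RE = "RE"


@dataclass(frozen=True)
class LayerGeometry:
    layer: Layer
    n_cells: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.n_cells)


@dataclass(frozen=True)
class Projection:
    source: Layer
    target: Layer
    receptor: Receptor
    g_total: float        # uS, divided across each target's in-degree
    radius: int
    depression_U: float = 0.0   # 0 = undepressed

    @property
    def depressed(self) -> bool:
        return self.depression_U > 0.0


#: the complete projection set with conductances and connecting radii.
#: Short-term depression applies to intracortical AMPA and GABA_A only.
PROJECTIONS: tuple[Projection, ...] = (
    Projection(Layer.PY, Layer.PY, Receptor.AMPA, 0.025, 11, 0.07),
    Projection(Layer.PY, Layer.PY, Receptor.NMDA, 0.0019, 11),
    Projection(Layer.PY, Layer.IN, Receptor.AMPA, 0.055, 3, 0.07),
    Projection(Layer.PY, Layer.IN, Receptor.NMDA, 0.001, 3),
    Projection(Layer.IN, Layer.PY, Receptor.GABA_A, 0.055, 11, 0.073),
    Projection(Layer.TC, Layer.RE, Receptor.AMPA, 0.1, 17),
    Projection(Layer.RE, Layer.TC, Receptor.GABA_A, 0.05, 17),
    Projection(Layer.RE, Layer.TC, Receptor.GABA_B, 0.02, 17),
    Projection(Layer.RE, Layer.RE, Receptor.GABA_A, 0.05, 11),
    Projection(Layer.TC, Layer.PY, Receptor.AMPA, 0.01, 21),
    Projection(Layer.TC, Layer.IN, Receptor.AMPA, 0.01, 5),
    Projection(Layer.PY, Layer.TC, Receptor.AMPA, 0.003, 21),
    Projection(Layer.PY, Layer.RE, Receptor.AMPA, 0.0015, 17),
)


@dataclass
class MiniDrive:
    """Poisson miniature-EPSP drive parameters (calibration constants)."""

    rate: float = 9.0          # Hz per cortical target cell
    g_mini: float = 0.015      # uS, AMPA-kinetics conductance per target
    rearm_delay_ms: float = 100.0   # delay after SO termination
    termination_silence_ms: float = 50.0  # all-PY silence defining SO end
    enabled: bool = True


def source_positions(n_src: int, n_tgt: int) -> np.ndarray:
    """Coordinates of source cells on the target layer's index scale."""
    return (np.arange(n_src) + 0.5) * (n_tgt / n_src) - 0.5


def connection_windows(
    n_src: int, n_tgt: int, radius: float, radius_scale: str = "target"
) -> tuple[np.ndarray, np.ndarray]:
    """(lo, hi) inclusive source-index bounds for every target cell.

    ``radius_scale='target'`` measures the radius in target-grid units
    (default); ``'source'`` measures it in source-grid units.
    """
    eps = 1e-9
    if radius_scale == "target":
        x = source_positions(n_src, n_tgt)           # src on target scale
        lo = np.empty(n_tgt, dtype=np.int64)
        hi = np.empty(n_tgt, dtype=np.int64)
        for j in range(n_tgt):
            ok = np.abs(x - j) <= radius + eps
            idx = np.flatnonzero(ok)
            lo[j], hi[j] = (idx[0], idx[-1]) if len(idx) else (0, -1)
        return lo, hi
    elif radius_scale == "source":
        y = source_positions(n_tgt, n_src)           # tgt on source scale
        i = np.arange(n_src)
        lo = np.empty(n_tgt, dtype=np.int64)
        hi = np.empty(n_tgt, dtype=np.int64)
        for j in range(n_tgt):
            ok = np.abs(i - y[j]) <= radius + eps
            idx = np.flatnonzero(ok)
            lo[j], hi[j] = (idx[0], idx[-1]) if len(idx) else (0, -1)
        return lo, hi
    raise ValueError(f"unknown radius_scale {radius_scale!r}")


@dataclass
class ProjectionWiring:
    projection: Projection
    lo: np.ndarray            # inclusive source window per target
    hi: np.ndarray
    in_degree: np.ndarray     # connections per target (self excluded)
    g_per_conn: np.ndarray    # g_total / in_degree (0 where in_degree = 0)

    @property
    def self_connected(self) -> bool:
        return self.projection.source == self.projection.target

    def pairs(self):
        """Yield (source, target) index pairs — test/inspection oracle."""
        for j in range(len(self.lo)):
            for i in range(self.lo[j], self.hi[j] + 1):
                if self.self_connected and i == j:
                    continue
                yield i, j

    def n_connections(self) -> int:
        return int(self.in_degree.sum())


@dataclass
class NetworkModel:
    layers: dict[Layer, LayerGeometry]
    wiring: dict[tuple[Layer, Layer, Receptor], ProjectionWiring]
    mini: MiniDrive = field(default_factory=MiniDrive)
    radius_scale: str = "target"

    def layer_size(self, layer: Layer) -> int:
        return self.layers[layer].n_cells

    def describe(self) -> str:
        """Delimited-text dump of the geometry and adjacency windows."""
        lines = ["layer\tn_cells"]
        for g in self.layers.values():
            lines.append(f"{g.layer.value}\t{g.n_cells}")
        lines.append("source\ttarget\treceptor\tg_total_uS\tradius\tconnections")
        for key, w in self.wiring.items():
            p = w.projection
            lines.append(
                f"{p.source.value}\t{p.target.value}\t{p.receptor.value}"
                f"\t{p.g_total}\t{p.radius}\t{w.n_connections()}"
            )
        return "\n".join(lines)


def build_network(
    n: int = 40,
    *,
    g_py_tc: float = 0.003,
    g_py_re: float = 0.0015,
    radius_scale: str = "target",
    g_normalization: str = "indegree",
    pypy_radius_coarse: bool = False,
    g_scale: dict | None = None,
    mini: MiniDrive | None = None,
    enforce_ratio: bool = True,
    n_py: int | None = None,
) -> NetworkModel:
    """Construct the four-layer network (PY layer has 5N cells).

    ``g_py_tc`` / ``g_py_re`` override the corticothalamic conductances
    (the slow-spindle preset flips their balance).
    """
    if n < 1:
        raise ValueError("layer size must be >= 1")
    npy = 5 * n if n_py is None else n_py
    if enforce_ratio and npy != 5 * n:
        raise ValueError("PY layer must have 5N cells")
    sizes = {Layer.PY: npy, Layer.IN: n, Layer.TC: n, Layer.RE: n}
    layers = {lay: LayerGeometry(lay, sz) for lay, sz in sizes.items()}

    g_scale = g_scale or {}
    wiring: dict[tuple[Layer, Layer, Receptor], ProjectionWiring] = {}
    for proj in PROJECTIONS:
        g_total = proj.g_total
        key = f"{proj.source.value}->{proj.target.value}:{proj.receptor.value}"
        g_total *= g_scale.get(key, 1.0)
        if (proj.source, proj.target) == (Layer.PY, Layer.TC):
            g_total = g_py_tc
        elif (proj.source, proj.target) == (Layer.PY, Layer.RE):
            g_total = g_py_re
        proj = Projection(proj.source, proj.target, proj.receptor,
                          g_total, proj.radius, proj.depression_U)
        n_src = sizes[proj.source]
        n_tgt = sizes[proj.target]
        radius = proj.radius
        if (pypy_radius_coarse
                and (proj.source, proj.target) == (Layer.PY, Layer.PY)):
            # the intracortical radius read on the N=40 grid
            radius = proj.radius * npy / n
        lo, hi = connection_windows(n_src, n_tgt, radius, radius_scale)
        deg = (hi - lo + 1).clip(min=0).astype(np.int64)
        if proj.source == proj.target:
            inside = (lo <= np.arange(n_tgt)) & (np.arange(n_tgt) <= hi)
            deg = deg - inside.astype(np.int64)
        if g_normalization == "indegree":
            g_per = np.where(deg > 0, g_total / np.maximum(deg, 1), 0.0)
        elif g_normalization == "per_connection":
            g_per = np.where(deg > 0, g_total, 0.0)
        else:
            raise ValueError(f"unknown g_normalization {g_normalization!r}")
        wiring[(proj.source, proj.target, proj.receptor)] = ProjectionWiring(
            proj, lo, hi, deg, g_per
        )
    return NetworkModel(layers=layers, wiring=wiring,
                        mini=mini or MiniDrive(), radius_scale=radius_scale)


def mini_drive_step(
    rng: np.random.Generator,
    dt_ms: float,
    n_targets: int,
    rate_hz: float,
    gate_open: bool,
) -> np.ndarray:
    """Poisson miniature-release counts for one interval of ``dt_ms``.

    Returns an integer array of event counts per target cell; all zeros
    while the gate is closed or the rate is zero.
    """
    if not gate_open or rate_hz <= 0.0:
        return np.zeros(n_targets, dtype=np.int64)
    lam = rate_hz * dt_ms * 1e-3
    return rng.poisson(lam, size=n_targets)
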