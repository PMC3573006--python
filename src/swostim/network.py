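"""Lattice network construction.

Excitatory and inhibitory neurons are placed at random on a 2D lattice with
periodic (toroidal) boundaries.  Every neuron receives excitatory synapses
from all excitatory neurons in its 5x5 neighborhood and inhibitory synapses
from all inhibitory neurons in its 3x3 neighborhood (no self-connections).
Izhikevich parameters and per-edge conductance increments are jittered with
a 5% coefficient of variation around their population means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import NeuronParams, SynapseKinetics

__all__ = [
    "LatticeNetwork",
    "build_lattice",
    "sample_parameters",
    "subregion_indices",
    "save_network",
    "load_network",
]

# default regular-spiking (excitatory) and fast-spiking (inhibitory)
# Izhikevich constants
EXC_ABCD = (0.02, 0.2, -65.0, 8.0)
INH_ABCD = (0.1, 0.2, -65.0, 2.0)


@dataclass
class LatticeNetwork:
    """A 2D lattice of spiking neurons with local E/I connectivity.

    Edge arrays are (pre, post) index pairs; ``w_exc``/``w_inh`` are the
    per-edge conductance increments delivered to the postsynaptic neuron on a
    presynaptic spike (AMPA+NMDA for excitatory, GABA_A+GABA_B for
    inhibitory).
    """

    n_rows: int
    n_cols: int
    is_excitatory: np.ndarray  # (n,) bool
    exc_edges: np.ndarray  # (m_e, 2) int — pre, post
    inh_edges: np.ndarray  # (m_i, 2) int
    w_exc: np.ndarray  # (m_e,)
    w_inh: np.ndarray  # (m_i,)
    abcd: np.ndarray  # (n, 4) per-neuron Izhikevich constants
    rng_seed: int
    exc_radius: int = 2  # 5x5 neighborhood
    inh_radius: int = 1  # 3x3 neighborhood
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)

    @property
    def n_neurons(self) -> int:
        return self.n_rows * self.n_cols

    def site(self, index: int) -> tuple[int, int]:
        """(row, col) of a neuron index (row-major)."""
        return divmod(index, self.n_cols)

    def column_of(self) -> np.ndarray:
        """Column index of every neuron."""
        return np.arange(self.n_neurons) % self.n_cols


def _neighborhood(i: int, n_rows: int, n_cols: int, radius: int) -> list[int]:
    """Indices in the (2r+1)x(2r+1) square around neuron i, torus wrap,
    excluding i itself."""
    r0, c0 = divmod(i, n_cols)
    out = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr == 0 and dc == 0:
                continue
            out.append(((r0 + dr) % n_rows) * n_cols + (c0 + dc) % n_cols)
    return out


def build_lattice(
    n_rows: int = 30,
    n_cols: int = 30,
    frac_inhibitory: float = 0.2,
    seed: int = 0,
    *,
    exc_radius: int = 2,
    inh_radius: int = 1,
    kinetics: SynapseKinetics | None = None,
) -> LatticeNetwork:
    """Build the lattice topology and assign cell types at random.

    Weights and per-neuron parameters are set to their population means;
    call :func:`sample_parameters` to apply the 5% jitter.
    """
    if n_rows < 2 * exc_radius + 1 or n_cols < 2 * exc_radius + 1:
        raise ValueError(
            f"lattice {n_rows}x{n_cols} smaller than the "
            f"{2 * exc_radius + 1}x{2 * exc_radius + 1} excitatory neighborhood"
        )
    if not (0.0 < frac_inhibitory < 1.0):
        raise ValueError("frac_inhibitory must be in (0, 1)")
    kin = kinetics if kinetics is not None else SynapseKinetics()
    n = n_rows * n_cols
    rng = np.random.default_rng(seed)

    n_inh = int(round(frac_inhibitory * n))
    is_exc = np.ones(n, dtype=bool)
    is_exc[rng.choice(n, size=n_inh, replace=False)] = False

    exc_edges, inh_edges = [], []
    for post in range(n):
        for pre in _neighborhood(post, n_rows, n_cols, exc_radius):
            if is_exc[pre]:
                exc_edges.append((pre, post))
        for pre in _neighborhood(post, n_rows, n_cols, inh_radius):
            if not is_exc[pre]:
                inh_edges.append((pre, post))

    exc_edges = np.array(exc_edges, dtype=np.int64).reshape(-1, 2)
    inh_edges = np.array(inh_edges, dtype=np.int64).reshape(-1, 2)

    abcd = np.where(
        is_exc[:, None], np.array(EXC_ABCD)[None, :], np.array(INH_ABCD)[None, :]
    )
    return LatticeNetwork(
        n_rows=n_rows,
        n_cols=n_cols,
        is_excitatory=is_exc,
        exc_edges=exc_edges,
        inh_edges=inh_edges,
        w_exc=np.full(len(exc_edges), kin.w_exc_mean),
        w_inh=np.full(len(inh_edges), kin.w_inh_mean),
        abcd=abcd,
        rng_seed=seed,
        exc_radius=exc_radius,
        inh_radius=inh_radius,
        kinetics=kin,
    )


def sample_parameters(net: LatticeNetwork, cv: float = 0.05, seed: int | None = None) -> LatticeNetwork:
    """Jitter per-neuron Izhikevich constants and per-edge weights in place.

    Each value is redrawn Normal(mean, cv*|mean|); weights that would come
    out non-positive are redrawn (truncation by rejection, so all w > 0).
    Deterministic given ``seed`` (defaults to the network's build seed + 1).
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = np.random.default_rng(net.rng_seed + 1 if seed is None else seed)
    kin = net.kinetics

    means = np.where(
        net.is_excitatory[:, None], np.array(EXC_ABCD)[None, :], np.array(INH_ABCD)[None, :]
    )
    net.abcd = means * (1.0 + cv * rng.standard_normal(means.shape))

    def draw_weights(mean: float, m: int) -> np.ndarray:
        w = rng.normal(mean, cv * mean, size=m)
        bad = w <= 0
        while bad.any():  # rejection keeps every increment strictly positive
            w[bad] = rng.normal(mean, cv * mean, size=int(bad.sum()))
            bad = w <= 0
        return w

    net.w_exc = draw_weights(kin.w_exc_mean, len(net.exc_edges))
    net.w_inh = draw_weights(kin.w_inh_mean, len(net.inh_edges))
    return net


def subregion_indices(net: LatticeNetwork, k: int = 4, size: int = 11) -> list[np.ndarray]:
    """Non-overlapping size x size blocks of neuron indices.

    Default: four 11x11 arrays centered in the four lattice quadrants; their
    per-block LFPs play the role of separate EEG electrodes.
    """
    if size > min(net.n_rows, net.n_cols):
        raise ValueError("block size exceeds lattice dimensions")
    if k < 1:
        raise ValueError("k must be >= 1")

    if k == 1:
        centers = [(net.n_rows // 2, net.n_cols // 2)]
    elif k == 4:
        centers = [
            (net.n_rows // 4, net.n_cols // 4),
            (net.n_rows // 4, 3 * net.n_cols // 4),
            (3 * net.n_rows // 4, net.n_cols // 4),
            (3 * net.n_rows // 4, 3 * net.n_cols // 4),
        ]
    else:
        # one block per column strip, centered vertically
        if k * size > net.n_cols:
            raise ValueError("cannot place blocks without overlap")
        centers = [
            (net.n_rows // 2, int((j + 0.5) * net.n_cols / k)) for j in range(k)
        ]

    blocks = []
    for r0, c0 in centers:
        rows = (np.arange(size) + r0 - size // 2) % net.n_rows
        cols = (np.arange(size) + c0 - size // 2) % net.n_cols
        blocks.append((rows[:, None] * net.n_cols + cols[None, :]).ravel())

    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if np.intersect1d(blocks[i], blocks[j]).size:
                raise ValueError("subregion blocks overlap; reduce size or k")
    return blocks


def save_network(net: LatticeNetwork, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Write the network as two delimited tables (nodes and edges)."""
    n = net.n_neurons
    nodes = pd.DataFrame(
        {
            "id": np.arange(n),
            "row": np.arange(n) // net.n_cols,
            "col": np.arange(n) % net.n_cols,
            "type": np.where(net.is_excitatory, "E", "I"),
            "a": net.abcd[:, 0],
            "b": net.abcd[:, 1],
            "c": net.abcd[:, 2],
            "d": net.abcd[:, 3],
        }
    )
    edges = pd.DataFrame(
        {
            "pre": np.concatenate([net.exc_edges[:, 0], net.inh_edges[:, 0]]),
            "post": np.concatenate([net.exc_edges[:, 1], net.inh_edges[:, 1]]),
            "class": ["E"] * len(net.exc_edges) + ["I"] * len(net.inh_edges),
            "weight": np.concatenate([net.w_exc, net.w_inh]),
        }
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)


def load_network(
    nodes_path: str | Path,
    edges_path: str | Path,
    kinetics: SynapseKinetics | None = None,
) -> LatticeNetwork:
    """Rebuild a :class:`LatticeNetwork` from the two-table export."""
    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t")
    n_rows = int(nodes["row"].max()) + 1
    n_cols = int(nodes["col"].max()) + 1
    is_exc = (nodes.sort_values("id")["type"] == "E").to_numpy()
    e_mask = edges["class"] == "E"
    return LatticeNetwork(
        n_rows=n_rows,
        n_cols=n_cols,
        is_excitatory=is_exc,
        exc_edges=edges.loc[e_mask, ["pre", "post"]].to_numpy(dtype=np.int64),
        inh_edges=edges.loc[~e_mask, ["pre", "post"]].to_numpy(dtype=np.int64),
        w_exc=edges.loc[e_mask, "weight"].to_numpy(),
        w_inh=edges.loc[~e_mask, "weight"].to_numpy(),
        abcd=nodes.sort_values("id")[["a", "b", "c", "d"]].to_numpy(),
        rng_seed=-1,
        kinetics=kinetics if kinetics is not None else SynapseKinetics(),
    )
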