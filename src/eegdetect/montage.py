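"""Electrode layout and montage definitions for 16-channel 10-20 EEG.

The reference configuration uses 16 scalp electrodes of the International
10-20 System, read out either referentially (unipolar) or as the 16-channel
longitudinal bipolar "double banana" chains.  Phase-reversal analysis needs,
for every bipolar channel, a fixed list of exactly six neighbouring bipolar
channels; the default table is the six nearest channels by the distance
between channel midpoints on the standard planar 10-20 projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

# Planar projection of the 10-20 positions (unit head circle, x: left->right,
# y: back->front).  Midline electrodes are listed for completeness but are not
# part of the 16-channel reference montage.
ELECTRODE_XY: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.51), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.51), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.00), "C3": (-0.50, 0.00), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.00), "T4": (1.00, 0.00),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.51), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.51), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

#: 16 unipolar channels of the reference configuration.
DEFAULT_UNIPOLAR: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T3", "T4", "T5", "T6", "P3", "P4", "O1", "O2",
)

#: Longitudinal bipolar chains ("double banana"), 16 anode-cathode pairs.
DEFAULT_BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
)

#: The four longitudinal chains, as electrode sequences.
CHAINS: tuple[tuple[str, ...], ...] = (
    ("Fp1", "F7", "T3", "T5", "O1"),
    ("Fp2", "F8", "T4", "T6", "O2"),
    ("Fp1", "F3", "C3", "P3", "O1"),
    ("Fp2", "F4", "C4", "P4", "O2"),
)

#: Electrodes interior to a chain, i.e. positions at which a discharge
#: produces a phase reversal between two bipolar channels of the same chain.
INTERIOR_ELECTRODES: tuple[str, ...] = (
    "F7", "T3", "T5", "F8", "T4", "T6", "F3", "C3", "P3", "F4", "C4", "P4",
)

# Electrodes closer than this on the planar layout are considered adjacent
# when building the scalp adjacency graph used for spatial field spread.
_ADJACENCY_RADIUS = 0.75


def bipolar_label(anode: str, cathode: str) -> str:
    return f"{anode}-{cathode}"


def _pair_midpoint(pair: tuple[str, str]) -> np.ndarray:
    a = np.asarray(ELECTRODE_XY[pair[0]])
    b = np.asarray(ELECTRODE_XY[pair[1]])
    return (a + b) / 2.0


def default_neighbor_graph(
    pairs: tuple[tuple[str, str], ...] = DEFAULT_BIPOLAR_PAIRS,
    n_neighbors: int = 6,
) -> dict[str, tuple[str, ...]]:
    """Six nearest bipolar channels per channel, by midpoint distance.

    Distance ties are broken by channel order, so the table is deterministic.
    """
    labels = [bipolar_label(*p) for p in pairs]
    mids = np.array([_pair_midpoint(p) for p in pairs])
    graph: dict[str, tuple[str, ...]] = {}
    for i, lab in enumerate(labels):
        d = np.linalg.norm(mids - mids[i], axis=1)
        d[i] = np.inf
        order = np.argsort(d, kind="stable")[:n_neighbors]
        graph[lab] = tuple(labels[j] for j in order)
    return graph


def electrode_adjacency(labels: tuple[str, ...] = DEFAULT_UNIPOLAR) -> nx.Graph:
    """Scalp adjacency graph: electrodes within the adjacency radius."""
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            pa, pb = np.asarray(ELECTRODE_XY[a]), np.asarray(ELECTRODE_XY[b])
            if np.linalg.norm(pa - pb) <= _ADJACENCY_RADIUS:
                g.add_edge(a, b)
    return g


def electrode_hops(focus: str, labels: tuple[str, ...] = DEFAULT_UNIPOLAR) -> dict[str, int]:
    """Graph distance (hops) from a focus electrode to every electrode."""
    g = electrode_adjacency(labels)
    if focus not in g:
        raise ValueError(f"unknown electrode {focus!r}")
    return dict(nx.single_source_shortest_path_length(g, focus))


@dataclass(frozen=True)
class MontageSpec:
    """A 16-channel montage: unipolar list, bipolar pairs, neighbour table.

    ``neighbor_graph`` maps each bipolar channel label to exactly six
    neighbouring bipolar channel labels, used by the phase-reversal features.
    """

    kind: str = "bipolar"
    unipolar_channels: tuple[str, ...] = DEFAULT_UNIPOLAR
    bipolar_pairs: tuple[tuple[str, str], ...] = DEFAULT_BIPOLAR_PAIRS
    neighbor_graph: dict[str, tuple[str, ...]] = field(default_factory=default_neighbor_graph)

    def __post_init__(self) -> None:
        if self.kind not in ("unipolar", "bipolar"):
            raise ValueError(f"montage kind must be unipolar or bipolar, got {self.kind!r}")
        if len(set(self.unipolar_channels)) != len(self.unipolar_channels):
            raise ValueError("duplicate unipolar channel labels")
        for lab, nbrs in self.neighbor_graph.items():
            if len(nbrs) != 6:
                raise ValueError(f"neighbor list of {lab!r} has length {len(nbrs)}, expected 6")

    @property
    def bipolar_labels(self) -> tuple[str, ...]:
        return tuple(bipolar_label(*p) for p in self.bipolar_pairs)

    def chain_of(self, label: str) -> tuple[str, ...]:
        """The electrode chain containing a bipolar channel."""
        a, b = label.split("-")
        for chain in CHAINS:
            for i in range(len(chain) - 1):
                if chain[i] == a and chain[i + 1] == b:
                    return chain
        raise KeyError(f"bipolar channel {label!r} is not on a default chain")

    def chain_neighbors(self, label: str) -> tuple[str | None, str | None]:
        """Previous and next bipolar channels along the chain (None at ends)."""
        a, b = label.split("-")
        chain = self.chain_of(label)
        i = chain.index(a)
        prev_lab = bipolar_label(chain[i - 1], a) if i > 0 else None
        next_lab = bipolar_label(b, chain[i + 2]) if i + 2 < len(chain) else None
        return prev_lab, next_lab

    def channels_sharing_electrode(self, label: str) -> dict[str, str]:
        """Other bipolar channels sharing an electrode with ``label``.

        Returns a mapping other-channel-label -> shared electrode.
        """
        mine = set(label.split("-"))
        out: dict[str, str] = {}
        for other in self.bipolar_labels:
            if other == label:
                continue
            shared = mine & set(other.split("-"))
            if shared:
                out[other] = sorted(shared)[0]
        return out


def default_montage(kind: str = "bipolar") -> MontageSpec:
    return MontageSpec(kind=kind)
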