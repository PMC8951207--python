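"""Electrode montages for the 10-20 system.

The 20 canonical scalp sites (FP1 ... O2) define the nodes of the functional
brain network.  A montage also carries a symmetric nearest-neighbour relation
used by the Hjorth surface-Laplacian spatial filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

CANONICAL_20: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

# Idealized nearest-neighbour adjacency on the 10-20 grid (Hjorth filter).
_DEFAULT_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "FP1": ("FP2", "F7", "F3", "Fz"),
    "FP2": ("FP1", "Fz", "F4", "F8"),
    "F7": ("FP1", "F3", "T7"),
    "F3": ("FP1", "F7", "Fz", "C3"),
    "Fz": ("FP1", "FP2", "F3", "F4", "Cz"),
    "F4": ("FP2", "Fz", "F8", "C4"),
    "F8": ("FP2", "F4", "T8"),
    "T7": ("F7", "C3", "T5"),
    "C3": ("F3", "T7", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "Cz", "T8", "P4"),
    "T8": ("F8", "C4", "T6"),
    "T5": ("T7", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4", "Oz"),
    "P4": ("C4", "Pz", "T6", "O2"),
    "T6": ("T8", "P4", "O2"),
    "O1": ("T5", "P3", "Oz"),
    "Oz": ("O1", "Pz", "O2"),
    "O2": ("T6", "P4", "Oz"),
}


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus a symmetric neighbour relation.

    Parameters
    ----------
    labels
        Channel names, in the row order of any :class:`~plinet.preprocess.Recording`
        that uses this montage.
    neighbors
        Map ``label -> adjacent labels``.  Must be symmetric and reference only
        known labels.
    """

    labels: tuple[str, ...]
    neighbors: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __init__(self, labels: Sequence[str], neighbors: Mapping[str, Sequence[str]] | None = None):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels in montage")
        nb = {lab: frozenset(neighbors.get(lab, ())) for lab in labels} if neighbors else {lab: frozenset() for lab in labels}
        known = set(labels)
        for lab, ns in nb.items():
            unknown = ns - known
            if unknown:
                raise ValueError(f"neighbors of {lab} reference unknown labels: {sorted(unknown)}")
            if lab in ns:
                raise ValueError(f"channel {lab} listed as its own neighbor")
            for other in ns:
                if lab not in nb[other]:
                    raise ValueError(f"neighbor relation not symmetric: {lab} -> {other}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "neighbors", nb)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def subset(self, labels: Sequence[str]) -> "Montage":
        """Montage restricted to `labels`, keeping intra-subset adjacency."""
        keep = set(labels)
        missing = keep - set(self.labels)
        if missing:
            raise KeyError(f"labels not in montage: {sorted(missing)}")
        nb = {lab: tuple(n for n in self.neighbors[lab] if n in keep) for lab in labels}
        return Montage(tuple(labels), nb)


def default_montage() -> Montage:
    """The 20 canonical 10-20 electrodes with idealized Hjorth adjacency."""
    return Montage(CANONICAL_20, _DEFAULT_NEIGHBORS)
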