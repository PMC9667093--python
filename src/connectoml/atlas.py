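"""Node parcellation ("atlas") descriptions.

A connectome analysis needs a fixed node set and a grouping of nodes into
functional subnetworks (modules).  The default atlas mirrors a 160-node
functional parcellation split into six subnetworks (cerebellum,
sensorimotor, occipital, cingulo-opercular, default, frontal-parietal);
per-subnetwork node counts are configurable because published parcellations
differ slightly in how regions are apportioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default subnetwork names and their share of nodes, in module-id order.
DEFAULT_SUBNETWORKS: tuple[tuple[str, float], ...] = (
    ("cerebellum", 18 / 160),
    ("sensorimotor", 33 / 160),
    ("occipital", 22 / 160),
    ("cingulo-opercular", 32 / 160),
    ("default", 34 / 160),
    ("frontal-parietal", 21 / 160),
)


@dataclass(frozen=True)
class AtlasSpec:
    """A node set partitioned into contiguous subnetworks.

    Parameters
    ----------
    n_nodes:
        Total number of nodes (>= 3).
    subnetwork_of:
        1-based subnetwork id per node, contiguous ids starting at 1.
    subnetwork_names:
        One name per subnetwork id.
    labels:
        One human-readable label per node.
    """

    n_nodes: int
    subnetwork_of: tuple[int, ...]
    subnetwork_names: tuple[str, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("an atlas needs at least 3 nodes")
        if len(self.subnetwork_of) != self.n_nodes:
            raise ValueError("subnetwork_of must assign every node")
        ids = sorted(set(self.subnetwork_of))
        if ids != list(range(1, len(self.subnetwork_names) + 1)):
            raise ValueError("subnetwork ids must be contiguous from 1 and all used")
        if self.labels and len(self.labels) != self.n_nodes:
            raise ValueError("labels must match n_nodes")
        if not self.labels:
            names = self.subnetwork_names
            object.__setattr__(
                self,
                "labels",
                tuple(
                    f"{names[s - 1]}_{i + 1:03d}"
                    for i, s in enumerate(self.subnetwork_of)
                ),
            )

    @property
    def n_subnetworks(self) -> int:
        return len(self.subnetwork_names)

    def nodes_in(self, subnetwork: str | int) -> np.ndarray:
        """0-based node indices belonging to a subnetwork (by name or id)."""
        if isinstance(subnetwork, str):
            subnetwork = self.subnetwork_names.index(subnetwork) + 1
        return np.flatnonzero(np.asarray(self.subnetwork_of) == subnetwork)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: node id (1-based), label, subnetwork name."""
        return pd.DataFrame(
            {
                "node": np.arange(1, self.n_nodes + 1),
                "label": list(self.labels),
                "subnetwork": [
                    self.subnetwork_names[s - 1] for s in self.subnetwork_of
                ],
            }
        )


def default_atlas(n_nodes: int = 160) -> AtlasSpec:
    """Atlas with six subnetworks in the default proportions.

    Node counts per subnetwork are the proportional shares of ``n_nodes``
    rounded by largest remainder so they always sum to ``n_nodes``.
    """
    names = tuple(name for name, _ in DEFAULT_SUBNETWORKS)
    shares = np.array([w for _, w in DEFAULT_SUBNETWORKS])
    raw = shares * n_nodes
    counts = np.floor(raw).astype(int)
    remainder = n_nodes - counts.sum()
    for idx in np.argsort(raw - counts)[::-1][:remainder]:
        counts[idx] += 1
    counts = np.maximum(counts, 1)
    # largest-remainder can in principle starve a module at tiny n; rebalance.
    while counts.sum() > n_nodes:
        counts[np.argmax(counts)] -= 1
    membership: list[int] = []
    for module_id, c in enumerate(counts, start=1):
        membership.extend([module_id] * c)
    return AtlasSpec(
        n_nodes=n_nodes,
        subnetwork_of=tuple(membership[:n_nodes]),
        subnetwork_names=names,
    )
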