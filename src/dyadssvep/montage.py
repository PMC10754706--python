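"""24-channel 10-20 montage, scalp regions, and the electrode neighbor graph.

The recording montage is a 24-electrode 10-20 cap referenced at FCz, with
mastoids M1/M2 carried as ordinary channels.  Scalp regions (central,
frontal, occipital, parietal, temporal) partition the 22 non-mastoid
electrodes and drive the region-level statistics; the neighbor graph over
the same 22 electrodes defines spatial adjacency for cluster-based
permutation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Channel order of the 24-electrode cap.
CHANNELS: tuple[str, ...] = (
    "C3", "C4", "CPz", "Cz", "AFz", "F3", "F4", "F7", "F8", "Fp1", "Fp2",
    "Fz", "M1", "M2", "O1", "O2", "POz", "P3", "P4", "P7", "P8", "Pz",
    "T7", "T8",
)

MASTOIDS: tuple[str, ...] = ("M1", "M2")

#: Scalp regions partitioning the 22 non-mastoid electrodes.
REGIONS: dict[str, tuple[str, ...]] = {
    "central": ("C3", "C4", "CPz", "Cz"),
    "frontal": ("AFz", "F3", "F4", "F7", "F8", "Fp1", "Fp2", "Fz"),
    "occipital": ("O1", "O2", "POz"),
    "parietal": ("P3", "P4", "P7", "P8", "Pz"),
    "temporal": ("T7", "T8"),
}

#: Infant central-occipital-parietal channel set (condition-difference ROI).
COP_CHANNELS: tuple[str, ...] = (
    "CPz", "Cz", "O1", "O2", "POz", "P3", "P4", "P7", "P8", "Pz",
)

#: Mother central-frontal-parietal channel set (condition-difference ROI).
CFP_CHANNELS: tuple[str, ...] = (
    "C3", "C4", "CPz", "Cz", "AFz", "F3", "F4", "Fz", "P3", "P4", "Pz",
)

#: Distance threshold (unit-sphere chord length) for electrode adjacency.
#: Chosen so the median neighbor count over the 22 scalp electrodes is 4-6.
DEFAULT_NEIGHBOR_THRESHOLD = 0.8


@dataclass(frozen=True)
class Montage:
    """Electrode labels, template positions, regions and neighbor graph.

    Positions live on the unit sphere (template head, unitless).  The
    neighbor graph is symmetric, has no self-edges, and is defined only
    over the non-mastoid electrodes.
    """

    labels: tuple[str, ...]
    positions: dict[str, np.ndarray]
    reference_label: str
    region_map: dict[str, tuple[str, ...]]
    neighbors: dict[str, frozenset[str]]
    neighbor_threshold: float = DEFAULT_NEIGHBOR_THRESHOLD
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {ch: i for i, ch in enumerate(self.labels)}
        )

    @property
    def scalp_labels(self) -> tuple[str, ...]:
        """Non-mastoid electrodes, in montage order."""
        return tuple(ch for ch in self.labels if ch not in MASTOIDS)

    def index(self, label: str) -> int:
        return self._index[label]

    def indices(self, labels) -> np.ndarray:
        return np.array([self._index[ch] for ch in labels], dtype=int)

    def adjacency_matrix(self, labels=None) -> np.ndarray:
        """Boolean adjacency over ``labels`` (default: scalp electrodes)."""
        labels = tuple(labels) if labels is not None else self.scalp_labels
        n = len(labels)
        adj = np.zeros((n, n), dtype=bool)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j and b in self.neighbors.get(a, frozenset()):
                    adj[i, j] = True
        return adj


def _template_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            tmpl = mne.channels.make_standard_montage("standard_1020")
        except ValueError:  # pragma: no cover - newer template name
            tmpl = mne.channels.make_standard_montage("colin27_1020")
    pos3d = tmpl.get_positions()["ch_pos"]
    out = {}
    for ch in CHANNELS:
        p = np.asarray(pos3d[ch], dtype=float)
        out[ch] = p / np.linalg.norm(p)  # project to unit sphere
    return out


def build_montage(
    layout_name: str = "smarting24",
    neighbor_threshold: float = DEFAULT_NEIGHBOR_THRESHOLD,
) -> Montage:
    """Build the 24-channel 10-20 montage with regions and neighbor graph.

    Parameters
    ----------
    layout_name
        Only ``"smarting24"`` (the 24-electrode mobile cap) is supported.
    neighbor_threshold
        Euclidean distance cutoff on unit-sphere template positions below
        which two scalp electrodes count as neighbors.
    """
    if layout_name != "smarting24":
        raise ConfigurationError(f"unknown montage layout: {layout_name!r}")
    if neighbor_threshold <= 0:
        raise ConfigurationError("neighbor_threshold must be positive")

    positions = _template_positions()
    scalp = [ch for ch in CHANNELS if ch not in MASTOIDS]
    pts = np.array([positions[ch] for ch in scalp])
    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    adj = (dist < neighbor_threshold) & (dist > 0)
    neighbors = {
        ch: frozenset(scalp[j] for j in np.flatnonzero(adj[i]))
        for i, ch in enumerate(scalp)
    }
    return Montage(
        labels=CHANNELS,
        positions=positions,
        reference_label="FCz",
        region_map=dict(REGIONS),
        neighbors=neighbors,
        neighbor_threshold=neighbor_threshold,
    )
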