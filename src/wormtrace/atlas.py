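"""Model atlas of identifiable head neuron classes.

The atlas is a small editable table of approximate normalized positions
(x = anterior, y = dorsal, z = left) for the neuron classes the
identification step can label: the backward-locomotion group (AVA, AVE,
AIB, RIM pairs and the VA/DA motor neurons) and the forward-locomotion
group (AVB, RIB, RME, RID, RIS, DB). Coordinates are expressed in the
body frame anchored on the seed six (AVA/AVE/AIB candidates): on load the
table is normalized so the seed-six centroid sits at the origin and their
mean pairwise distance is 1, matching how observed positions are
normalized before assignment.

The shipped positions are synthetic approximations laid out to respect the
qualitative arrangement (bilateral symmetry, anteroposterior order,
dorsal-side majority); they are meant to be replaced by a user-calibrated
table for real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

SEED_CLASSES = ("AVAL", "AVAR", "AVEL", "AVER", "AIBL", "AIBR")
GROUP_VALUES = ("backward", "forward", "other")


@dataclass
class AtlasNeuron:
    class_name: str
    position: np.ndarray  # (x, y, z) normalized body-frame coordinates
    group: str
    side: str  # "L", "R" or "none"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite atlas position for {self.class_name}")
        if self.group not in GROUP_VALUES:
            raise ValueError(f"unknown group {self.group!r}")


def _normalize(neurons: list[AtlasNeuron]) -> list[AtlasNeuron]:
    """Anchor the table on the seed six: centroid 0, mean pair distance 1."""
    by_name = {a.class_name: a for a in neurons}
    missing = [c for c in SEED_CLASSES if c not in by_name]
    if missing:
        raise ValueError(f"atlas lacks seed classes {missing}")
    seed_pos = np.array([by_name[c].position for c in SEED_CLASSES])
    origin = seed_pos.mean(axis=0)
    scale = np.mean([np.linalg.norm(a - b) for a, b in combinations(seed_pos, 2)])
    return [
        AtlasNeuron(a.class_name, (a.position - origin) / scale, a.group, a.side)
        for a in neurons
    ]


def load_atlas(path, normalize: bool = True) -> list[AtlasNeuron]:
    """Load an atlas CSV with columns (class_name, x, y, z, group, side)."""
    df = pd.read_csv(path)
    required = {"class_name", "x", "y", "z", "group", "side"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"atlas CSV missing columns {sorted(missing)}")
    if df["class_name"].duplicated().any():
        dupes = df.loc[df["class_name"].duplicated(), "class_name"].tolist()
        raise ValueError(f"duplicate atlas class names {dupes}")
    neurons = [
        AtlasNeuron(r.class_name, np.array([r.x, r.y, r.z]), r.group, str(r.side))
        for r in df.itertuples()
    ]
    return _normalize(neurons) if normalize else neurons


def save_atlas(neurons: list[AtlasNeuron], path) -> None:
    pd.DataFrame(
        [(a.class_name, *a.position, a.group, a.side) for a in neurons],
        columns=["class_name", "x", "y", "z", "group", "side"],
    ).to_csv(path, index=False)


def default_atlas() -> list[AtlasNeuron]:
    """The atlas shipped with the package (normalized)."""
    with resources.files("wormtrace.data").joinpath("atlas.csv").open() as fh:
        return load_atlas(fh)
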