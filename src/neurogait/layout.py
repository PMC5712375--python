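"""Bundled International 10/10 montage.

The coordinate table (``data/electrodes_1010.tsv``) gives unit-sphere
positions for the 31 recorded electrodes.  It was derived from the standard
10/05 template montage shipped with MNE-Python: the template head positions
were least-squares sphere-fitted, projected to the unit sphere, and rotated
so that Cz is exactly the vertex (0, 0, 1) and the midline lies in the y-z
plane with +y anterior.  The original study does not publish digitized
positions, so this idealized spherical montage is an explicit modelling
choice; only relative inter-electrode distances enter the analysis (through
the Laplacian weights), which are insensitive to the overall scale.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .core import ElectrodeLayout

__all__ = ["ANALYSIS_ELECTRODES", "standard_1010_layout"]

#: The nine electrodes over the sensorimotor leg area used for features.
ANALYSIS_ELECTRODES: tuple[str, ...] = (
    "Fz", "FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2", "Pz",
)


def standard_1010_layout() -> ElectrodeLayout:
    """The 31-electrode 10/10 montage with its 9-electrode analysis subset."""
    ref = resources.files("neurogait.data").joinpath("electrodes_1010.tsv")
    names: list[str] = []
    coords: list[list[float]] = []
    with ref.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == ["name", "x", "y", "z"]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            names.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
    arr = np.asarray(coords)
    # re-normalize against text round-off so the unit-norm invariant is exact
    arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    return ElectrodeLayout(names=names, coords=arr, feature_subset=list(ANALYSIS_ELECTRODES))
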