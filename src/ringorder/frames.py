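"""Core container for a single water configuration.

All coordinates are in Angstrom, in an orthorhombic periodic box anchored at
the origin.  Every water is an oxygen plus exactly two hydrogens; virtual
sites of 4- and 5-site water models are stripped by the readers before a
frame is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WaterFrame"]

# covalent O-H bounds used for sanity checking input geometries (Angstrom)
OH_MIN = 0.8
OH_MAX = 1.2


@dataclass
class WaterFrame:
    """One configuration of waters in an orthorhombic periodic box.

    Parameters
    ----------
    oxygen_positions : (n, 3) float array, Angstrom
    hydrogen_positions : (n, 2, 3) float array, Angstrom; may contain NaN
        when hydrogens have not been assigned yet (bare oxygen lattices).
    box : (3,) float array, orthorhombic edge lengths in Angstrom
    frame_index : index of this frame within its source trajectory
    """

    oxygen_positions: np.ndarray
    hydrogen_positions: np.ndarray
    box: np.ndarray
    frame_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.oxygen_positions = np.asarray(self.oxygen_positions, dtype=float)
        self.hydrogen_positions = np.asarray(self.hydrogen_positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.oxygen_positions.ndim != 2 or self.oxygen_positions.shape[1] != 3:
            raise ValueError("oxygen_positions must be (n, 3)")
        n = self.oxygen_positions.shape[0]
        if self.hydrogen_positions.shape != (n, 2, 3):
            raise ValueError("hydrogen_positions must be (n, 2, 3)")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be 3 positive orthorhombic edge lengths")

    @property
    def n_waters(self) -> int:
        return self.oxygen_positions.shape[0]

    @property
    def has_hydrogens(self) -> bool:
        return not np.isnan(self.hydrogen_positions).any()

    def validate_covalent_geometry(self) -> None:
        """Check every O-H covalent distance lies in [0.8, 1.2] Angstrom."""
        if not self.has_hydrogens:
            raise ValueError("frame has unset hydrogens")
        d = self.hydrogen_positions - self.oxygen_positions[:, None, :]
        # covalent partners are never split across the periodic wall on input
        # we generate; for read-in files apply minimum image to be safe
        d -= self.box * np.round(d / self.box)
        r = np.linalg.norm(d, axis=2)
        bad = np.where((r < OH_MIN) | (r > OH_MAX))
        if bad[0].size:
            i = int(bad[0][0])
            raise ValueError(
                f"water {i} has O-H distance {r[bad][0]:.3f} A outside "
                f"[{OH_MIN}, {OH_MAX}] A"
            )

    def wrapped(self) -> "WaterFrame":
        """Return a copy with oxygens wrapped into the box.

        Each water is moved rigidly (hydrogens follow their oxygen) so the
        covalent geometry is untouched.
        """
        shift = -np.floor(self.oxygen_positions / self.box) * self.box
        return WaterFrame(
            self.oxygen_positions + shift,
            self.hydrogen_positions + shift[:, None, :],
            self.box.copy(),
            frame_index=self.frame_index,
            metadata=dict(self.metadata),
        )

    def copy(self) -> "WaterFrame":
        return WaterFrame(
            self.oxygen_positions.copy(),
            self.hydrogen_positions.copy(),
            self.box.copy(),
            frame_index=self.frame_index,
            metadata=dict(self.metadata),
        )
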