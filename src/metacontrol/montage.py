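"""Equidistant 60-channel scalp montage on the unit sphere.

The recording cap emulated here is a 60-electrode equidistant layout labelled
with extended 10-10-style names (including the older PO1/PO2 positions).
Positions are parameterized by two angles per electrode: an anterior-posterior
angle ``lambda`` (degrees, positive toward the nasion, 0 at the vertex ring)
and a lateral angle ``mu`` (degrees, positive toward the right ear).  The
mapping to unit-sphere coordinates (x right, y anterior, z up) is

    x = sin(mu),  y = cos(mu) sin(lambda),  z = cos(mu) cos(lambda)

which puts Cz at the vertex and keeps every electrode at unit radius, as the
spherical-spline CSD estimator requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "default_montage"]

# (name, lambda_deg anterior+, mu_deg right+)
_LAYOUT: list[tuple[str, float, float]] = [
    # midline, front to back
    ("Fpz", 72, 0), ("Fz", 36, 0), ("FCz", 18, 0), ("Cz", 0, 0),
    ("CPz", -18, 0), ("Pz", -36, 0), ("POz", -54, 0), ("Oz", -72, 0),
    # prefrontal / anterior-frontal
    ("Fp1", 72, -18), ("Fp2", 72, 18),
    ("AF3", 54, -15), ("AF4", 54, 15),
    # frontal row
    ("F7", 36, -54), ("F8", 36, 54),
    ("F5", 36, -42), ("F6", 36, 42),
    ("F3", 36, -28), ("F4", 36, 28),
    ("F1", 36, -14), ("F2", 36, 14),
    # fronto-central / fronto-temporal row
    ("FT7", 18, -63), ("FT8", 18, 63),
    ("FC5", 18, -48), ("FC6", 18, 48),
    ("FC3", 18, -32), ("FC4", 18, 32),
    ("FC1", 18, -16), ("FC2", 18, 16),
    # central row
    ("T7", 0, -72), ("T8", 0, 72),
    ("C5", 0, -54), ("C6", 0, 54),
    ("C3", 0, -36), ("C4", 0, 36),
    ("C1", 0, -18), ("C2", 0, 18),
    # centro-parietal / temporo-parietal row
    ("TP7", -18, -63), ("TP8", -18, 63),
    ("CP5", -18, -48), ("CP6", -18, 48),
    ("CP3", -18, -32), ("CP4", -18, 32),
    ("CP1", -18, -16), ("CP2", -18, 16),
    # parietal row
    ("P7", -36, -54), ("P8", -36, 54),
    ("P5", -36, -42), ("P6", -36, 42),
    ("P3", -36, -28), ("P4", -36, 28),
    ("P1", -36, -14), ("P2", -36, 14),
    # inferior parietal (sub-inion extension of the cap)
    ("P9", -43, -68), ("P10", -43, 68),
    # parieto-occipital
    ("PO1", -54, -10), ("PO2", -54, 10),
    ("PO7", -54, -36), ("PO8", -54, 36),
    # occipital
    ("O1", -72, -18), ("O2", -72, 18),
]


@dataclass(frozen=True)
class Montage:
    """Named electrode set with unit-sphere 3D coordinates.

    Parameters
    ----------
    names : tuple of str
        Unique channel names.
    positions : ndarray, shape (n_channels, 3)
        Cartesian coordinates; every row has unit norm.
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.positions, float)
        if pos.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode coordinates must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], int)

    def cosine_angles(self) -> np.ndarray:
        """Pairwise cosines of inter-electrode angles (the CSD kernel argument)."""
        c = self.positions @ self.positions.T
        return np.clip(c, -1.0, 1.0)

    def geodesic_distances(self) -> np.ndarray:
        """Pairwise great-circle distances in radians on the unit sphere."""
        return np.arccos(self.cosine_angles())


def default_montage() -> Montage:
    """Build the default 60-channel equidistant montage.

    Includes every electrode referenced by the standard component windows
    (P7/P8/P9/P10, Cz, Pz, PO1/PO2) and by the feature-selection outputs.
    """
    names = tuple(e[0] for e in _LAYOUT)
    lam = np.radians([e[1] for e in _LAYOUT])
    mu = np.radians([e[2] for e in _LAYOUT])
    pos = np.column_stack([
        np.sin(mu),
        np.cos(mu) * np.sin(lam),
        np.cos(mu) * np.cos(lam),
    ])
    # renormalize to guard against rounding
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(names=names, positions=pos)
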