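"""Electrode montages.

A montage is an ordered set of named electrode positions.  The built-in
layouts mirror a rodent implantation scheme in which cortical screw
electrodes are placed over regions homologous to the human 10-20 system;
coordinates are schematic anteroposterior / lateral positions in
millimetres relative to bregma (positive AP = anterior, positive L =
right).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "generate_montage"]

# Schematic rat-skull AP/L coordinates (mm) for the 19 analysis channels,
# ordered as the human 10-20 labels they are homologous to.
_LAYOUT_19: list[tuple[str, float, float]] = [
    ("Fp1", 5.0, -1.5),
    ("Fp2", 5.0, 1.5),
    ("F7", 3.5, -4.0),
    ("F3", 3.0, -2.0),
    ("Fz", 3.0, 0.0),
    ("F4", 3.0, 2.0),
    ("F8", 3.5, 4.0),
    ("T3", 0.0, -5.0),
    ("C3", 0.0, -2.5),
    ("Cz", 0.0, 0.0),
    ("C4", 0.0, 2.5),
    ("T4", 0.0, 5.0),
    ("T5", -3.5, -4.5),
    ("P3", -3.0, -2.0),
    ("Pz", -3.0, 0.0),
    ("P4", -3.0, 2.0),
    ("T6", -3.5, 4.5),
    ("O1", -6.0, -1.5),
    ("O2", -6.0, 1.5),
]

# The full implant adds two mastoid-homologue leads.
_LAYOUT_21 = _LAYOUT_19 + [("A1", -1.0, -6.0), ("A2", -1.0, 6.0)]


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels and their 2-D coordinates in millimetres."""

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.channel_names) < 2:
            raise ValueError("a montage needs at least 2 channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if pos.shape[0] != len(self.channel_names) or pos.ndim != 2:
            raise ValueError("positions must be (n_channels, 2 or 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def generate_montage(n_channels: int = 19) -> Montage:
    """Return a named electrode layout.

    ``n_channels`` of 19 or 21 gives the built-in rat layout homologous to
    the human 10-20 set (19 analysis channels; 21 adds the two
    mastoid-homologue leads).  Any other positive count >= 2 yields a
    generic circular layout with labels ``ch01..chNN``.
    """
    if n_channels < 2:
        raise ValueError(f"n_channels must be >= 2, got {n_channels}")
    if n_channels in (19, 21):
        layout = _LAYOUT_19 if n_channels == 19 else _LAYOUT_21
        names = tuple(name for name, _, _ in layout)
        pos = np.array([[ap, lat] for _, ap, lat in layout])
        return Montage(names, pos)
    ang = 2 * np.pi * np.arange(n_channels) / n_channels
    pos = 5.0 * np.column_stack([np.cos(ang), np.sin(ang)])
    names = tuple(f"ch{i + 1:02d}" for i in range(n_channels))
    return Montage(names, pos)
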