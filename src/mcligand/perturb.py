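"""Local rigid-body enrichment of screened conformers.

Each survivor of the QP screen is expanded into 25 rigid variants: the
original, rotations of {+/-5, +/-10, +/-15} degrees about each principal axis
through the centroid (18), and translations of +/-0.3 A along each map axis
(6).  Rotations and translations are applied one at a time (no products),
keeping the expansion factor small.  Axis choice (principal vs map axes) and
step sizes are configurable.
"""

from __future__ import annotations

import numpy as np

from .ligand import Conformer
from .sampling import principal_axes, rotate_about_centroid

__all__ = ["perturb"]

ROTATION_DEGREES = (5.0, 10.0, 15.0)
TRANSLATION_STEP = 0.3


def perturb(conformers, rotation_degrees=ROTATION_DEGREES,
            translation_step: float = TRANSLATION_STEP) -> list[Conformer]:
    """Original + 18 rotations + 6 translations per input conformer."""
    conformers = list(conformers)
    if not conformers:
        raise ValueError("no conformers to perturb")
    out: list[Conformer] = []
    for conf in conformers:
        if conf.n_atoms < 3:
            raise ValueError("degenerate geometry (< 3 atoms)")
        out.append(conf)
        axes = principal_axes(conf.coords)
        for axis in axes:
            for deg in rotation_degrees:
                for sign in (1.0, -1.0):
                    coords = rotate_about_centroid(conf.coords, axis,
                                                   sign * deg)
                    out.append(conf.with_coords(coords))
        for dim in range(3):
            for sign in (1.0, -1.0):
                shift = np.zeros(3)
                shift[dim] = sign * translation_step
                out.append(conf.with_coords(conf.coords + shift))
    return out
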