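"""Unit conventions and conversion constants.

Internal units are fixed throughout the package:

* length      — micrometre (um)
* time        — millisecond (ms)
* velocity    — um/ms  (numerically equal to mm/s)
* flow rate   — um^3/ms internally; reported as nL/s or uL/min

All conversions between these and the reporting units live here so that
every module agrees on the same constants.
"""

from __future__ import annotations

import math

#: 1 uL = 1 mm^3 = 1e9 um^3; 1 min = 60000 ms.
UM3_PER_MS_TO_UL_PER_MIN = 60_000.0 / 1e9

#: 1 nL = 1e6 um^3; 1 s = 1000 ms.
UM3_PER_MS_TO_NL_PER_S = 1000.0 / 1e6

TWO_PI = 2.0 * math.pi


def poiseuille_flow_rate(v_max: float, a: float, b: float | None = None) -> float:
    """Volumetric flow rate of an elliptic-paraboloid profile, in um^3/ms.

    Integrating ``v_max * (1 - y'^2/a^2 - z'^2/b^2)`` over the ellipse where
    the profile is positive gives ``pi * a * b * v_max / 2``.
    """
    if b is None:
        b = a
    return math.pi * a * b * v_max / 2.0


def flow_rate_ul_min(v_max: float, a: float, b: float | None = None) -> float:
    """Elliptic Poiseuille flow rate in uL/min (``v_max`` um/ms, axes um)."""
    return poiseuille_flow_rate(v_max, a, b) * UM3_PER_MS_TO_UL_PER_MIN


def v_max_from_flow_rate(q_ul_min: float, radius: float) -> float:
    """Centreline velocity (um/ms) of Poiseuille flow at ``q_ul_min`` uL/min."""
    q = q_ul_min / UM3_PER_MS_TO_UL_PER_MIN  # um^3/ms
    return 2.0 * q / (math.pi * radius * radius)
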