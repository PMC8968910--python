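"""Physical constants used across the package."""

import math

MU0: float = 4e-7 * math.pi
"""Vacuum permeability, T·m/A."""

K_BOLTZMANN: float = 1.380649e-23
"""Boltzmann constant, J/K."""
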