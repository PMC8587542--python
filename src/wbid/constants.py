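"""Physical constants and frame conventions.

The internal global frame is right-handed with X anterior, Y to the
subject's left and Z up; gravity acts along -Z.  All internal quantities
are SI (m, kg, s, N, N·m, rad).
"""

import numpy as np

#: Standard gravity, m/s^2.
G = 9.81

#: Unit vertical (up) axis of the internal frame.
Z_UP = np.array([0.0, 0.0, 1.0])

#: Gravity acceleration vector, m/s^2.
GRAVITY = np.array([0.0, 0.0, -G])
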