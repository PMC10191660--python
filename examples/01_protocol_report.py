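"""Timing and geometry of the repeating raster scan protocol.

Each B-scan location is imaged 32 times (0.23 s apart) before the beam
moves on; 128 locations split into 8 sub-fields make one volume. The
report below shows the derived bookkeeping: 4,096 frames per volume,
58.8 s total, and the en-face pixel pitches for the three fields of view.
"""

import json

from livoct import ScanProtocolParams, enface_pixel_pitch
from livoct.scan_protocol import protocol_report

params = ScanProtocolParams()
print(json.dumps(protocol_report(params), indent=1))

for fov in (6.0, 3.0, 1.0):
    fast, slow = enface_pixel_pitch(params, fov)
    print(f"FOV {fov} mm -> en-face pixel {fast} x {slow} um (fast x slow)")
# The slow-axis pitch is 4x the fast-axis pitch: 128 B-scan locations span
# the same width that 512 A-lines cover on the fast axis.
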