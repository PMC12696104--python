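"""Coverage from hand-countable visit structures and a scripted lap track.

Builds the two worked 24-sector visit structures and the deterministic
three-lap boundary track, then prints their coverage values.
"""

import numpy as np

from openfieldkit import coverage, demo_lap_track, locate_sector_visits

# Subject that visited every sector at least 4 times, 21 of 24 beyond that
v_busy = np.array([5] * 21 + [4] * 3)
# Subject that visited every sector at least 2 times, 13 of 24 beyond that
v_quiet = np.array([3] * 13 + [2] * 11)

print(f"busy subject coverage:  {coverage(v_busy):.2f}")   # 4.88
print(f"quiet subject coverage: {coverage(v_quiet):.2f}")  # 2.54
print("-> the busy subject accumulated ~2x the boundary learning trials")

# A scripted walker: first detected in sector 6, three full laps, then a
# walk from sector 6 down to sector 1.
track = demo_lap_track(duration_s=200.0)
_, counts = locate_sector_visits(track, node_size=15.0, edge_dist_cm=1.0)
print(f"scripted track: v_min={counts.min()}, "
      f"{int((counts > counts.min()).sum())}/24 sectors above the minimum, "
      f"coverage={coverage(counts):.2f}")
# v_min=3, 6/24 above -> coverage 3.25
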