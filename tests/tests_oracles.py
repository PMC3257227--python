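"""Independent brute-force oracles shared by the test modules.

These deliberately use plain Python loops and scalar math so they share no
code path with the vectorized implementations they check.
"""

import math

import numpy as np


def hbond_oracle(traj, donors, acceptors, criteria, convention="dha"):
    out = {}
    for d_idx, h_idx in donors:
        if h_idx is None:
            continue
        hits = 0
        for f in range(traj.n_frames):
            found = False
            for a_idx in acceptors:
                if a_idx == d_idx:
                    continue
                d = traj.frames[f, d_idx]
                h = traj.frames[f, h_idx]
                a = traj.frames[f, a_idx]
                if math.dist(d, a) > criteria.distance_cut:
                    continue
                if convention == "dha":
                    v1, v2 = d - h, a - h
                else:
                    v1, v2 = a - d, h - d
                cosang = float(np.dot(v1, v2)
                               / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                ok = (ang >= 180.0 - criteria.angle_cut
                      if convention == "dha" else ang <= criteria.angle_cut)
                if ok:
                    found = True
                    break
            hits += found
        out[d_idx] = 100.0 * hits / traj.n_frames
    return out
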