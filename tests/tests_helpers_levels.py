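"""Constructed vessel trees with known branch-level structure."""

import numpy as np

from vascatlas.graph import VesselGraph


def binary_tree_graph(trunk_d=100.0, child_d=60.0, grandchild_d=20.0, mirror_x=0.0):
    """Trunk (diameter 100 um) splitting into 2 children (60 um), each
    splitting into 2 grandchildren (20 um): branch levels 1/2/3 count 1/2/4."""
    ids, tc, xs, ys, zs, rs, ps = [], [], [], [], [], [], []

    def add(x, y, z, d, parent):
        ids.append(len(ids) + 1)
        tc.append(5)
        xs.append(x + mirror_x)
        ys.append(y)
        zs.append(z)
        rs.append(d / 2)
        ps.append(parent)
        return ids[-1]

    t0 = add(100, 0, 0, trunk_d, -1)
    t1 = add(100, 0, 100, trunk_d, t0)
    for dx in (-40, 40):
        c0 = add(100 + dx, 0, 160, child_d, t1)
        for dy in (-30, 30):
            add(100 + dx, dy, 220, grandchild_d, c0)
    return VesselGraph(
        np.array(ids), np.array(tc), np.array(xs, float), np.array(ys, float),
        np.array(zs, float), np.array(rs, float), np.array(ps),
    )
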