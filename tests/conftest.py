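import numpy as np
import pytest

import vesseltort as vt
from vesseltort import tracing as tr


@pytest.fixture(scope="session")
def radial_phantom():
    """A 20-vessel radial phantom with analytic truth (seed 0)."""
    return vt.generate_phantom(vt.make_radial_spec(seed=0))


@pytest.fixture(scope="session")
def phantom_config():
    """Pipeline configuration matched to the phantom's coloring (vessels are
    dark in the LAB b channel, so segmentation polarity is inverted)."""
    return vt.PipelineConfig(invert_b=True)


def skeleton_of(spec: vt.VesselSpec, shape=(300, 300)) -> vt.Skeleton:
    """Rasterize a single vessel and thin it to a centerline."""
    mask = vt.phantom.rasterize_vessel(spec, shape)
    return vt.skeletonize(vt.VesselMask(mask, "synthetic"), vessel_class=spec.vessel_class)


def trace_open_curve(skel: vt.Skeleton):
    """Trace a lone open curve between its two detected tips."""
    ends = sorted(tr.detect_endpoints(skel))
    assert len(ends) == 2, f"expected 2 tips, found {len(ends)}"
    return tr.curve_length(skel, tr.PathPair(ends[0], ends[1]))


def dijkstra_pixel_count(grid, start_xy, end_xy):
    """Independent oracle: unit-weight Dijkstra over the 8-connected
    skeleton pixel graph; returns the pixel count of a shortest path."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra

    coords = [tuple(p) for p in np.argwhere(grid)]  # (row, col)
    index = {p: i for i, p in enumerate(coords)}
    adj = lil_matrix((len(coords), len(coords)))
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    adj[i, j] = 1
    s = index[(start_xy[1], start_xy[0])]
    e = index[(end_xy[1], end_xy[0])]
    dist = dijkstra(adj.tocsr(), indices=s, unweighted=False)[e]
    return int(dist) + 1 if np.isfinite(dist) else None


def grid_from_pixels(pixels, shape):
    """Build a skeleton grid from (x, y) coordinates."""
    g = np.zeros(shape, dtype=bool)
    for x, y in pixels:
        g[y, x] = True
    return vt.Skeleton(grid=g)
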