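import itertools

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def proper_crossing_count(order, points) -> int:
    """Number of properly crossing edge pairs in a closed tour."""
    pts = np.asarray(points, dtype=float)
    n = len(order)
    edges = [(pts[order[i]], pts[order[(i + 1) % n]]) for i in range(n)]

    def ccw(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    count = 0
    for (a, b), (c, d) in itertools.combinations(edges, 2):
        if any(np.array_equal(x, y) for x in (a, b) for y in (c, d)):
            continue  # shared endpoint: adjacency, not a crossing
        if ccw(a, b, c) * ccw(a, b, d) < 0 and ccw(c, d, a) * ccw(c, d, b) < 0:
            count += 1
    return count
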