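"""Shared fixtures: small deterministic phantoms and geometry helpers."""

import numpy as np
import pytest

from breastar.phantom import PhantomSpec, generate_ct


@pytest.fixture(scope="session")
def default_phantom():
    """The pinned default phantom (with pad artifact and noise) + truth."""
    return generate_ct(PhantomSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Brute-force min distance from each point to a triangle set.

    ``points`` is (n, 3); ``tri`` is (m, 3, 3). Exact closest-point
    computation: clamped barycentric projection onto each face plus the
    three edge segments. Quadratic cost — an oracle, not a tool.
    """
    n = len(points)
    out = np.full(n, np.inf)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    for i0 in range(0, n, 512):
        p = points[i0 : i0 + 512][:, None, :]
        ap = p - a[None]
        d1 = (ab[None] * ap).sum(-1)
        d2 = (ac[None] * ap).sum(-1)
        dab = (ab * ab).sum(-1)[None]
        dac = (ac * ac).sum(-1)[None]
        dbc = (ab * ac).sum(-1)[None]
        denom = np.maximum(dab * dac - dbc * dbc, 1e-300)
        v = np.clip((dac * d1 - dbc * d2) / denom, 0, 1)
        w = np.clip((dab * d2 - dbc * d1) / denom, 0, 1)
        s = v + w
        scale = np.where(s > 1, 1 / np.maximum(s, 1e-300), 1.0)
        v *= scale
        w *= scale
        cp = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        d_best = np.linalg.norm(p - cp, axis=-1)
        for p0, p1 in ((a, b), (a, c), (b, c)):
            e = p1 - p0
            t = np.clip(
                ((p - p0[None]) * e[None]).sum(-1)
                / np.maximum((e * e).sum(-1)[None], 1e-300),
                0,
                1,
            )
            cpe = p0[None] + t[..., None] * e[None]
            d_best = np.minimum(d_best, np.linalg.norm(p - cpe, axis=-1))
        out[i0 : i0 + 512] = d_best.min(axis=1)
    return out
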