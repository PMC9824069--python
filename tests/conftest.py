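"""Shared fixtures: small simulated bundles and the desk-scale benchmark.

The benchmark fixture (simulate 20 pairs at 256x256, train the network for
2000 steps, score all five methods) is expensive, so it is session-scoped
and shared by every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from debundle import bundlesim, pipeline


def brute_force_forward(params, image: np.ndarray) -> np.ndarray:
    """Direct triple-nested-loop evaluation of the three-layer network.

    Deliberately naive (loops over every output pixel, tap and channel,
    replicate padding by explicit np.pad) so it shares no code path with
    the production implementation.
    """

    def conv(x, W, b):
        k = W.shape[0]
        p = (k - 1) // 2
        h, w, _ = x.shape
        o_ch = W.shape[3]
        xp = np.pad(x, ((p, p), (p, p), (0, 0)), mode="edge")
        y = np.zeros((h, w, o_ch))
        for i in range(h):
            for j in range(w):
                for o in range(o_ch):
                    acc = b[o]
                    for u in range(k):
                        for v in range(k):
                            for c in range(x.shape[2]):
                                acc += xp[i + u, j + v, c] * W[u, v, c, o]
                    y[i, j, o] = acc
        return y

    x = np.asarray(image, dtype=np.float64)[:, :, None]
    a1 = np.maximum(conv(x, params.W1.astype(np.float64),
                         params.b1.astype(np.float64)), 0.0)
    a2 = np.maximum(conv(a1, params.W2.astype(np.float64),
                         params.b2.astype(np.float64)), 0.0)
    z3 = conv(a2, params.W3.astype(np.float64), params.b3.astype(np.float64))
    return z3[:, :, 0]


@pytest.fixture(scope="session")
def small_ref() -> bundlesim.WhiteReference:
    """A 128x128 jittered reference shared by read-only tests."""
    spec = bundlesim.BundleSpec(image_size=(128, 128), seed=7)
    return bundlesim.generate_reference(spec)


@pytest.fixture(scope="session")
def clean_ref() -> bundlesim.WhiteReference:
    """An unjittered, uniform-transmission 128x128 reference."""
    spec = bundlesim.BundleSpec(image_size=(128, 128), jitter_sigma=0.0,
                                intensity_jitter=0.0, seed=7)
    return bundlesim.generate_reference(spec)


@pytest.fixture(scope="session")
def benchmark_run() -> dict:
    """The scaled-down study: 20 pairs at 256^2, 2000 training steps."""
    return pipeline.run_benchmark(pipeline.RunConfig(seed=0))
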