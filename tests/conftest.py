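import numpy as np
import pytest

from mlvmf import build_kernel_bank


@pytest.fixture(scope="session")
def bank():
    return build_kernel_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220911)


def random_rgb(rng, h, w):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Independent brute-force references (plain window arithmetic, no scipy/ndimage)
# ---------------------------------------------------------------------------

def naive_convolve_abs(channel, weights):
    """|K (*) I| by explicit window sums under replicate padding."""
    channel = np.asarray(channel, dtype=np.int64)
    k = np.asarray(weights, dtype=np.int64)
    r = k.shape[0] // 2
    padded = np.pad(channel, r, mode="edge")
    h, w = channel.shape
    out = np.empty((h, w), dtype=np.int64)
    for i in range(h):
        for j in range(w):
            out[i, j] = abs(int((padded[i : i + 2 * r + 1, j : j + 2 * r + 1] * k).sum()))
    return out


def naive_detect(image, kernels, threshold):
    """One full detection round, written independently: per-pixel scan of the
    24 (kernel, channel) responses, explicit min + tie-break, then the
    threshold and 0/255 rule."""
    image = np.asarray(image)
    h, w, _ = image.shape
    responses = [
        [naive_convolve_abs(image[:, :, ch], k.weights) for ch in range(3)] for k in kernels
    ]
    flagged = np.zeros((h, w), dtype=bool)
    minima = np.zeros((h, w), dtype=np.int64)
    arg = np.zeros((h, w, 2), dtype=np.intp)  # (kernel index, channel)
    for i in range(h):
        for j in range(w):
            best = None
            for ki in range(len(kernels)):
                for ch in range(3):
                    v = responses[ki][ch][i, j]
                    if best is None or v < best[0]:
                        best = (v, ki, ch)
            minima[i, j] = best[0]
            arg[i, j] = (best[1], best[2])
            if best[0] > threshold and image[i, j, best[2]] in (0, 255):
                flagged[i, j] = True
    return flagged, minima, arg


def naive_vector_median(vectors, norm="L1"):
    """Exhaustive O(k^2) distance-sum scan; earliest minimizer wins."""
    vectors = np.asarray(vectors, dtype=np.float64)
    best_idx, best_sum = 0, None
    for i, v in enumerate(vectors):
        if norm == "L1":
            s = float(np.abs(vectors - v).sum())
        else:
            s = float(np.sqrt(((vectors - v) ** 2).sum(axis=1)).sum())
        if best_sum is None or s < best_sum:
            best_idx, best_sum = i, s
    return np.asarray(vectors[best_idx], dtype=np.uint8)
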