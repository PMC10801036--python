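import numpy as np
import pytest

from podseg.pseudo_label import ClassSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_step_schedule():
    return ClassSchedule([(1, 2), (4,)])


def naive_local_pod(x: np.ndarray, scales) -> np.ndarray:
    """Triple-loop reference for the local POD embedding (oracle)."""
    h, w, c = x.shape
    out = []
    for s in scales:
        for i in range(s):
            for j in range(s):
                h0, h1 = i * h // s, (i + 1) * h // s
                w0, w1 = j * w // s, (j + 1) * w // s
                sub = x[h0:h1, w0:w1, :]
                for hh in range(sub.shape[0]):
                    for cc in range(c):
                        out.append(sub[hh, :, cc].mean())
                for ww in range(sub.shape[1]):
                    for cc in range(c):
                        out.append(sub[:, ww, cc].mean())
    return np.array(out)


def brute_force_hausdorff(t: np.ndarray, p: np.ndarray) -> float:
    """Double-loop sup-inf Hausdorff distance (oracle)."""
    d = np.sqrt(((t[:, None, :] - p[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())
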