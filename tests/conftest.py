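import numpy as np
import pytest

from segloss import ClassSet, LabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cs3():
    return ClassSet.from_count(3)


def random_labelmap(rng, class_set, shape=(8, 8)):
    values = rng.choice(class_set.labels, size=shape)
    return LabelMap(values, class_set)


def brute_force_confusion(gnd: LabelMap, seg: LabelMap):
    """Independent oracle: per-pixel double loop, one pass per class."""
    h, w = gnd.shape
    out = {}
    for c in gnd.class_set.labels:
        tp = fp = fn = tn = 0
        for i in range(h):
            for j in range(w):
                g = gnd.values[i, j] == c
                s = seg.values[i, j] == c
                if g and s:
                    tp += 1
                elif g and not s:
                    fn += 1
                elif s and not g:
                    fp += 1
                else:
                    tn += 1
        out[c] = dict(tp=tp, fp=fp, fn=fn, tn=tn)
    return out
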