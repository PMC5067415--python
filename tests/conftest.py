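import random

import pytest

from idyot import Symbol


def syms(text: str, viewpoint: str = "default", level: int = 0):
    """Whitespace-separated token string -> symbol list."""
    return [Symbol(t, level, viewpoint) for t in text.split()]


def brute_force_counts(stream, order=1):
    """Independent n-gram counting oracle: enumerate sliding windows."""
    out = {}
    for i in range(len(stream)):
        for clen in range(0, order + 1):
            if clen > i:
                break
            ctx = tuple(stream[i - clen : i])
            out.setdefault(ctx, {})
            out[ctx][stream[i]] = out[ctx].get(stream[i], 0) + 1
    return out


@pytest.fixture
def rng():
    return random.Random(12345)
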