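"""Layered memory: chunks labelled by higher-level symbols, losslessly.

Words chunk out of phonemes, habitual two-word phrases chunk out of
words; expanding the top level reproduces the input exactly.
"""

import random

from idyot import Symbol, build_hierarchy, reconstruct

first = [[Symbol(t, 0, "ph") for t in w.split()] for w in ("p1 p2 p3", "q1 q2 q3")]
second = [[Symbol(t, 0, "ph") for t in w.split()] for w in ("r1 r2 r3", "s1 s2 s3")]
r = random.Random(0)
stream = []
for _ in range(120):
    i = r.randrange(2)
    j = i if r.random() < 0.9 else 1 - i  # habitual pairing of word pairs
    stream.extend(first[i] + second[j])

memory = build_hierarchy([stream], max_depth=2)
for k, level in enumerate(memory.levels):
    n = len(level.streams[0])
    a = memory.alphabet_size(k)
    print(f"level {k}: {n:4d} symbols, alphabet size {a}")

ok = reconstruct(memory, memory.depth) == [stream]
print(f"expanding level {memory.depth} labels reproduces the input exactly: {ok}")
print("Each level is a shorter, lossless re-description of the one below;")
print("capping depth bounds what can be remembered as a single unit.")
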