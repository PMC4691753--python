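"""Small test utilities shared across modules."""

from __future__ import annotations

import numpy as np

from mirmzt.mapping import GenomeRef


def make_random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> GenomeRef:
    return GenomeRef(
        {
            name: "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
            for name, n in lengths.items()
        }
    )


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)])
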