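"""The 21-letter design alphabet: 20 standard amino acids plus X (unknown).

X is consumed as sequence context but never sampled as a design target.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
UNKNOWN_INDEX = AA_TO_INDEX["X"]
VOCAB_SIZE = len(ALPHABET)  # 21


def seq_to_tokens(seq: str) -> np.ndarray:
    """Map a one-letter sequence to integer tokens; unknown letters become X."""
    return np.array([AA_TO_INDEX.get(c.upper(), UNKNOWN_INDEX) for c in seq], dtype=np.int64)


def tokens_to_seq(tokens) -> str:
    return "".join(ALPHABET[int(t)] for t in tokens)
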