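"""Synthetic circular mtDNA-like reference sequence.

All coordinates in the package are 1-based and inclusive, following the rCRS
convention for the 16,569 bp human mitochondrial genome.  The simulator and
the variant caller share a deterministic synthetic reference so that
substitution/trinucleotide classes are well defined without shipping genome
data.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default (human mtDNA) genome length in bp.
DEFAULT_GENOME_LENGTH = 16569

# Fixed internal seed: the reference is part of the coordinate system, not a
# random draw of any one run.
_REFERENCE_SEED = 16569


def synthetic_reference(length: int = DEFAULT_GENOME_LENGTH) -> str:
    """Return a deterministic random circular reference of ``length`` bp."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(_REFERENCE_SEED)
    idx = rng.integers(0, 4, size=length)
    return "".join(BASES[i] for i in idx)


def reference_array(reference: str) -> np.ndarray:
    """Encode a reference string as an int8 array (A,C,G,T -> 0..3)."""
    arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    if (out < 0).any():
        raise ValueError("reference contains non-ACGT characters")
    return out


def complement(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[base]
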