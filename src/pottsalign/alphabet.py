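"""Amino-acid alphabet and background frequencies.

The package works on a fixed, ordered q=20 alphabet so that field vectors and
coupling matrices inferred from different MSAs are always index-compatible.
A q=21 mode (gap as an explicit state) is supported by the frequency code but
is off by default.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino-acid order used for all models in this package.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

GAP = "-"

#: Background amino-acid frequencies, Robinson & Robinson (1991), the
#: standard background table of the PSI-BLAST / HH-suite tool lineage,
#: re-ordered to AMINO_ACIDS and renormalized to sum exactly to 1.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def background_frequencies(alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """Return the background frequency vector f0 for ``alphabet``.

    Known amino acids get their Robinson & Robinson frequency; any other
    symbol (e.g. in a reduced synthetic alphabet) gets a uniform share.
    The result is renormalized to sum to 1.
    """
    f0 = np.array([_ROBINSON.get(a, 1.0 / len(alphabet)) for a in alphabet],
                  dtype=float)
    return f0 / f0.sum()


def encode_sequences(sequences: list[str], alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """Integer-encode aligned sequences; gaps (and unknowns) become -1."""
    lut = np.full(128, -1, dtype=np.int8)
    for idx, sym in enumerate(alphabet):
        lut[ord(sym)] = idx
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(len(sequences), -1).astype(np.int64)
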