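"""MSA reading and preprocessing.

Implements the preprocessing pipeline applied to an MSA of close homologs
before Potts-model inference: redundancy filtering at 80% identity, capping
at the first 1000 sequences, and removal of columns with more than 50% gaps
(with bookkeeping so trimmed columns can be re-inserted into the model
afterwards).  Also computes the empirical single- and pair-frequency tables
that the field prior is built from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, GAP, background_frequencies, encode_sequences


class MSAFormatError(ValueError):
    """Raised when an input alignment cannot be parsed into a rectangular MSA."""


@dataclass
class MSA:
    """A rectangular multiple sequence alignment over ``alphabet`` ∪ {'-'}.

    The first row is by convention the query sequence the model represents.
    """

    sequences: list[str]
    ids: list[str]
    alphabet: str = AMINO_ACIDS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MSAFormatError("empty MSA")
        L = len(self.sequences[0])
        if L == 0:
            raise MSAFormatError("zero-length alignment rows")
        for name, seq in zip(self.ids, self.sequences):
            if len(seq) != L:
                raise MSAFormatError(
                    f"ragged alignment: row {name!r} has length {len(seq)}, expected {L}")
            bad = set(seq) - set(self.alphabet) - {GAP}
            if bad:
                raise MSAFormatError(f"row {name!r} contains symbols outside "
                                     f"the alphabet: {sorted(bad)}")

    @property
    def depth(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_array(self) -> np.ndarray:
        """Integer encoding, shape (N, L); gaps are -1."""
        return encode_sequences(self.sequences, self.alphabet)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.ids, self.sequences):
                fh.write(f">{name}\n{seq}\n")


@dataclass
class TrimRecord:
    """Mapping from a column-trimmed MSA back to original column indices."""

    kept_columns: list[int]
    original_length: int

    def __post_init__(self) -> None:
        cols = self.kept_columns
        if any(c < 0 or c >= self.original_length for c in cols):
            raise ValueError("kept_columns out of range")
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("kept_columns must be strictly increasing")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"original_length": self.original_length,
                       "kept_columns": list(self.kept_columns)}, fh)

    @classmethod
    def from_json(cls, path) -> "TrimRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kept_columns=d["kept_columns"],
                   original_length=d["original_length"])


@dataclass
class FrequencyTables:
    """Empirical marginals of an MSA.

    f_single[i, a] is the fraction of rows carrying symbol ``a`` at column
    ``i``; f_pair[i, j, a, b] the fraction carrying (a, b) at (i, j).  With
    the default q=20 alphabet gaps contribute to no state, so rows of
    f_single sum to ≤ 1 (the missing mass is the gap fraction).
    """

    f_single: np.ndarray
    f_pair: np.ndarray | None
    f_background: np.ndarray


def read_msa(path, format: str = "fasta") -> MSA:
    """Read an alignment in FASTA or A3M format.

    A3M lowercase characters denote insertion states relative to the master
    sequence and are removed before the rectangularity check; '.' gap
    placeholders are dropped likewise.
    """
    if format not in ("fasta", "a3m"):
        raise ValueError(f"unknown MSA format {format!r}")
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if format == "a3m":
            seq = "".join(c for c in seq if not (c.islower() or c == "."))
        seqs.append(seq.upper())
        ids.append(rec.id)
    if not seqs:
        raise MSAFormatError(f"no sequences found in {path}")
    return MSA(sequences=seqs, ids=ids,
               provenance={"source": str(path), "format": format})


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residues: matches / min(ungapped lengths).

    Columns where both rows are gapped are ignored; a pair of empty rows has
    identity 0 by convention.
    """
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    la = sum(1 for x in a if x != GAP)
    lb = sum(1 for x in b if x != GAP)
    denom = min(la, lb)
    return matches / denom if denom else 0.0


def filter_identity(msa: MSA, max_identity: float = 0.80) -> MSA:
    """Greedy redundancy filter at ``max_identity``.

    Rows are scanned top to bottom; a row is kept iff its identity to every
    already-kept row is ≤ the threshold.  The first row (query) is always
    kept.  This emulates the HHfilter `-id` step deterministically.
    """
    if not (0.0 < max_identity <= 1.0):
        raise ValueError("max_identity must be in (0, 1]")
    kept_seqs: list[str] = []
    kept_ids: list[str] = []
    for name, seq in zip(msa.ids, msa.sequences):
        if all(pairwise_identity(seq, k) <= max_identity for k in kept_seqs):
            kept_seqs.append(seq)
            kept_ids.append(name)
    return MSA(sequences=kept_seqs, ids=kept_ids, alphabet=msa.alphabet,
               provenance={**msa.provenance, "max_identity": max_identity})


def cap_depth(msa: MSA, n_max: int = 1000) -> MSA:
    """Keep the first ``n_max`` rows (order preserved)."""
    if n_max < 1:
        raise ValueError("n_max must be ≥ 1")
    if msa.depth <= n_max:
        return msa
    return MSA(sequences=msa.sequences[:n_max], ids=msa.ids[:n_max],
               alphabet=msa.alphabet,
               provenance={**msa.provenance, "n_max": n_max})


def trim_gappy_columns(msa: MSA, max_gap_fraction: float = 0.50
                       ) -> tuple[MSA, TrimRecord]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_fraction``."""
    arr = msa.to_array()
    gap_frac = (arr < 0).mean(axis=0)
    kept = [int(i) for i in np.nonzero(gap_frac <= max_gap_fraction)[0]]
    if not kept:
        raise MSAFormatError("all columns trimmed; cannot build a model")
    trimmed = MSA(
        sequences=["".join(s[i] for i in kept) for s in msa.sequences],
        ids=list(msa.ids), alphabet=msa.alphabet,
        provenance={**msa.provenance, "max_gap_fraction": max_gap_fraction})
    return trimmed, TrimRecord(kept_columns=kept, original_length=msa.length)


def compute_frequencies(msa: MSA, include_pairs: bool = True,
                        gap_as_state: bool = False) -> FrequencyTables:
    """Empirical single and pair frequencies of an MSA.

    With the default q=20 convention gaps are simply excluded from the
    counts; with ``gap_as_state`` the gap is appended as a 21st state.
    The pair table is O(L²q²) memory — skip it with ``include_pairs=False``
    when only the fields prior is needed.
    """
    arr = msa.to_array()
    q = len(msa.alphabet)
    if gap_as_state:
        arr = arr.copy()
        arr[arr < 0] = q
        q += 1
    N, L = arr.shape
    onehot = np.zeros((N, L, q))
    valid = arr >= 0
    onehot[np.nonzero(valid)[0], np.nonzero(valid)[1], arr[valid]] = 1.0
    f_single = onehot.mean(axis=0)
    f_pair = None
    if include_pairs:
        f_pair = np.einsum("nia,njb->ijab", onehot, onehot) / N
    f0 = background_frequencies(msa.alphabet)
    if gap_as_state:
        f0 = np.append(f0, 0.0)
        f0 = np.where(f0 == 0, 1e-9, f0)
        f0 = f0 / f0.sum()
    return FrequencyTables(f_single=f_single, f_pair=f_pair, f_background=f0)


def preprocess(msa: MSA, max_identity: float = 0.80, n_max: int = 1000,
               max_gap_fraction: float = 0.50) -> tuple[MSA, TrimRecord]:
    """Full preprocessing pipeline: identity filter → depth cap → trim."""
    return trim_gappy_columns(cap_depth(filter_identity(msa, max_identity), n_max),
                              max_gap_fraction)
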