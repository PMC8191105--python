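"""Alignment quality metrics against a reference alignment.

Precision is the fraction of computed residue pairs that are in the
reference, recall the fraction of reference pairs recovered, and F1 their
harmonic mean.  Correctness is exact pair identity (no ±k column slack),
with residue indices in original (pre-trim) sequence numbering so the
metrics are independent of any model-building column trimming.
"""

from __future__ import annotations

from dataclasses import dataclass

from .msa import MSA, GAP


@dataclass
class EvalReport:
    n_correct: int
    n_computed: int
    n_reference: int
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {"n_correct": self.n_correct, "n_computed": self.n_computed,
                "n_reference": self.n_reference, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def aligned_pairs_from_fasta(two_row_alignment: MSA) -> set[tuple[int, int]]:
    """Residue-index pairs (1-based, ungapped numbering) of a 2-row alignment."""
    if two_row_alignment.depth != 2:
        raise ValueError("reference alignment must have exactly 2 rows")
    a, b = two_row_alignment.sequences
    pairs = set()
    pos_a = pos_b = 0
    for ca, cb in zip(a, b):
        if ca != GAP:
            pos_a += 1
        if cb != GAP:
            pos_b += 1
        if ca != GAP and cb != GAP:
            pairs.add((pos_a, pos_b))
    return pairs


def precision_recall_f1(computed: set[tuple[int, int]],
                        reference: set[tuple[int, int]]) -> EvalReport:
    """Precision, recall and F1 of a computed pair set versus a reference."""
    computed = set(computed)
    reference = set(reference)
    n_correct = len(computed & reference)
    n_computed = len(computed)
    n_reference = len(reference)
    precision = n_correct / n_computed if n_computed else 0.0
    recall = n_correct / n_reference if n_reference else 0.0
    f1 = (2.0 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return EvalReport(n_correct=n_correct, n_computed=n_computed,
                      n_reference=n_reference, precision=precision,
                      recall=recall, f1=f1)
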