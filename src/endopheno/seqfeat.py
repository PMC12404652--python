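"""Protein sequence feature analyses.

Covers the sequence-level side of a structure-function study of a large
endosomal protein: per-residue disorder consensus across structure
models, motif location (e.g. the regulatory YLT motif), counting of
phospho-capable residues (S/T/Y) in a region, triplet alanine-scan
mutant generation, truncation/substitution construct arithmetic, and a
simple modal-residue conservation profile over an alignment.

All residue coordinates are 1-based inclusive, matching how constructs
are named in the field (``2198t`` keeps residues 1..2198; ``t347``
removes residues 1..347 and keeps 348..end).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
PHOSPHO_CAPABLE = set("STY")
GAP_CHARACTERS = set("-.")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier.

    The alphabet is restricted to the 20 standard residues; ``X`` is
    tolerated but flagged with a warning.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - STANDARD_RESIDUES - {"X"}
        if bad:
            raise ValueError(f"{self.id}: non-standard residues {sorted(bad)}")
        if "X" in seq:
            logger.warning("%s: sequence contains X residues", self.id)

    def __len__(self) -> int:
        return len(self.sequence)

    def region(self, start: int, end: int) -> str:
        """Subsequence for a 1-based inclusive range."""
        if not (1 <= start <= end <= len(self)):
            raise ValueError(
                f"region {start}..{end} outside 1..{len(self)} for {self.id}"
            )
        return self.sequence[start - 1:end]

    def cterm(self, n: int) -> tuple[int, int]:
        """1-based range of the C-terminal ``n`` residues."""
        if not 1 <= n <= len(self):
            raise ValueError(f"cannot take C-terminal {n} of length {len(self)}")
        return len(self) - n + 1, len(self)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [ProteinRecord(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path), "fasta",
    )


@dataclass
class DisorderConsensus:
    """Per-residue mean of binary disorder calls across M structure models.

    A value of 1 means every model calls the residue unstructured, 0 that
    every model calls it structured; values live on the grid {0, 1/M, ..., 1}.
    """

    scores: np.ndarray
    n_models: int

    def __len__(self) -> int:
        return len(self.scores)


def disorder_consensus(model_calls: Sequence[Sequence[int]]) -> DisorderConsensus:
    """Element-wise mean of binary per-residue disorder calls.

    Each element of ``model_calls`` is one structure model's binary vector
    (1 = unstructured, 0 = structured); all vectors must share one length.
    """
    if len(model_calls) == 0:
        raise ValueError("need at least one model")
    arrays = [np.asarray(v) for v in model_calls]
    lengths = {a.shape for a in arrays}
    if len(lengths) != 1 or arrays[0].ndim != 1:
        raise ValueError(f"model call vectors differ in shape: {lengths}")
    stack = np.stack(arrays)
    if not np.isin(stack, (0, 1)).all():
        raise ValueError("disorder calls must be binary (0/1)")
    return DisorderConsensus(scores=stack.mean(axis=0),
                             n_models=len(arrays))


def count_phospho_capable(record: ProteinRecord,
                          region: tuple[int, int] | None = None
                          ) -> tuple[int, int, float]:
    """Count S/T/Y residues in a region.

    Returns ``(count, percent, fraction)`` where ``percent`` is
    100*count/region_length rounded to the nearest integer (reporting
    convention) and ``fraction`` is the unrounded value.
    """
    if region is None:
        region = (1, len(record))
    seq = record.region(*region)
    count = sum(1 for aa in seq if aa in PHOSPHO_CAPABLE)
    fraction = count / len(seq)
    return count, int(round(100.0 * fraction)), fraction


def find_motif(record: ProteinRecord, motif: str,
               region: tuple[int, int] | None = None) -> list[int]:
    """All (possibly overlapping) motif matches, as ascending 1-based
    positions in full-length coordinates."""
    if not motif:
        raise ValueError("motif must be nonempty")
    motif = motif.upper()
    if region is None:
        region = (1, len(record))
    start, end = region
    seq = record.region(start, end)
    hits = []
    pos = seq.find(motif)
    while pos != -1:
        hits.append(start + pos)
        pos = seq.find(motif, pos + 1)
    return hits


def triplet_alanine_scan(record: ProteinRecord,
                         region: tuple[int, int] | None = None
                         ) -> list[ProteinRecord]:
    """Generate triple-alanine-scan mutants across a region.

    One mutant per consecutive non-overlapping 3-residue window anchored
    at the region start; a trailing 1-2 residue remainder is skipped with
    a log message.  Mutant ids encode the original residues and 1-based
    window start, e.g. ``toy6_YLT3AAA``.  A window that already reads
    ``AAA`` is still emitted (flagged in the log) and equals the input.
    """
    if region is None:
        region = (1, len(record))
    start, end = region
    length = end - start + 1
    if length < 3:
        raise ValueError(f"region {start}..{end} shorter than one triplet")
    leftover = length % 3
    if leftover:
        logger.info("%s: trailing %d residue(s) of region %d..%d not scanned",
                    record.id, leftover, start, end)
    mutants = []
    for w in range(start, end - 1, 3):
        original = record.region(w, w + 2)
        if original == "AAA":
            logger.info("%s: window %d..%d already AAA", record.id, w, w + 2)
        seq = record.sequence[:w - 1] + "AAA" + record.sequence[w + 2:]
        mutants.append(ProteinRecord(id=f"{record.id}_{original}{w}AAA",
                                     sequence=seq))
    return mutants


@dataclass
class ConstructSpec:
    """Ordered edits defining an expression construct.

    Edits (1-based inclusive positions, applied left to right):

    * ``("truncate_after", n)`` — keep residues 1..n (an ``Nt`` name);
    * ``("keep_from", n)`` — keep residues n+1..end (a ``tN`` name);
    * ``("substitute", (start, end, replacement))`` — splice in a
      replacement for residues start..end (e.g. a YLT→AAA mutation).
    """

    name: str
    edits: list[tuple] = field(default_factory=list)

    @classmethod
    def from_name(cls, name: str) -> "ConstructSpec":
        """Parse the field's construct shorthand: ``FL``, ``2198t``
        (truncate after 2198), ``t347`` (remove first 347)."""
        if name == "FL":
            return cls(name=name, edits=[])
        if name.endswith("t") and name[:-1].isdigit():
            return cls(name=name, edits=[("truncate_after", int(name[:-1]))])
        if name.startswith("t") and name[1:].isdigit():
            return cls(name=name, edits=[("keep_from", int(name[1:]))])
        raise ValueError(f"cannot parse construct name {name!r}")


def apply_construct(record: ProteinRecord, spec: ConstructSpec) -> ProteinRecord:
    """Apply a construct's edits to a sequence, with exact length
    bookkeeping; raises on any out-of-range coordinate."""
    seq = record.sequence
    for edit in spec.edits:
        kind, arg = edit[0], edit[1]
        if kind == "truncate_after":
            if not 1 <= arg <= len(seq):
                raise ValueError(f"truncate_after {arg} outside 1..{len(seq)}")
            seq = seq[:arg]
        elif kind == "keep_from":
            if not 1 <= arg < len(seq):
                raise ValueError(f"keep_from {arg} outside 1..{len(seq) - 1}")
            seq = seq[arg:]
        elif kind == "substitute":
            start, end, repl = arg
            if not (1 <= start <= end <= len(seq)):
                raise ValueError(f"substitute {start}..{end} outside 1..{len(seq)}")
            seq = seq[:start - 1] + repl + seq[end:]
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    return ProteinRecord(id=f"{record.id}_{spec.name}", sequence=seq)


def conservation_profile(records: Sequence[ProteinRecord | str]) -> np.ndarray:
    """Per-column modal-residue fraction over an aligned set.

    For each alignment column, the fraction of non-gap sequences sharing
    the most common residue.  This is a simple surrogate conservation
    score; an all-gap column scores 0.
    """
    seqs = [r.sequence if isinstance(r, ProteinRecord) else str(r).upper()
            for r in records]
    if len(seqs) < 2:
        raise ValueError("need at least two aligned sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must share one length")
    ncol = len(seqs[0])
    profile = np.zeros(ncol)
    for j in range(ncol):
        column = [s[j] for s in seqs if s[j] not in GAP_CHARACTERS]
        if column:
            profile[j] = Counter(column).most_common(1)[0][1] / len(column)
    return profile
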