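"""Pairwise mapping of remnants onto the consensus reference.

Each remnant is aligned semi-globally: the reference's unaligned flanks are
free, so a (possibly 5'-truncated) remnant can land anywhere inside the
reference as one contiguous block, while gaps at the remnant's own ends pay
the ordinary gap cost.  An "overlap" mode with both end gaps free is kept as
a switch.  Bases opposite gaps are never counted: only precisely mapped
remnant bases enter the per-position profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ._seq import BASE_CODES, N_CODE, encode
from .datamodel import ReferenceSeq, SubfamilyPool

logger = logging.getLogger(__name__)

#: bound on how many co-optimal alignments are scanned for the leftmost start
_TIE_SCAN = 16


@dataclass(frozen=True)
class AlignParams:
    """Scoring for remnant-vs-reference alignment.

    A gap of length g costs ``gap_open + (g - 1) * gap_extend``.  In
    ``semi_global`` mode only the reference's end gaps are free; ``overlap``
    frees both sequences' end gaps.  ``min_score`` is the floor below which a
    remnant is discarded (None keeps everything).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    mode: str = "semi_global"
    min_score: float | None = None

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        # gaps in the query (remnant) opposite the reference's flanks
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
        if self.mode == "overlap":
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
        elif self.mode != "semi_global":
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        return aligner


@dataclass
class PositionMap:
    """Reference positions (1-based, strictly increasing) covered by aligned,
    non-gap remnant bases, with the remnant base at each."""

    positions: np.ndarray
    bases: np.ndarray  # uint8 codes, may include N
    score: float

    def pairs(self) -> list[tuple[int, str]]:
        from ._seq import decode

        return [(int(p), decode(np.array([b], dtype=np.uint8)))
                for p, b in zip(self.positions, self.bases)]


def align_remnant(remnant: str, reference: ReferenceSeq | str,
                  params: AlignParams | None = None) -> PositionMap | None:
    """Align one remnant to the reference; None when below the score floor.

    Ties between co-optimal alignments break to the leftmost reference start.
    """
    params = params or AlignParams()
    ref_seq = reference.sequence if isinstance(reference, ReferenceSeq) else reference
    if not remnant or not ref_seq:
        raise ValueError("both remnant and reference must be non-empty")
    aligner = params.make_aligner()
    alignments = aligner.align(ref_seq.upper(), remnant.upper())
    best = None
    for i, aln in enumerate(alignments):
        start = aln.aligned[0][0][0] if len(aln.aligned[0]) else len(ref_seq)
        if best is None or start < best[0]:
            best = (start, aln)
        if i + 1 >= _TIE_SCAN:
            break
    score = float(alignments.score)
    if params.min_score is not None and score < params.min_score:
        logger.info("remnant discarded: score %.1f below floor %.1f",
                    score, params.min_score)
        return None
    aln = best[1]
    rem_codes = encode(remnant.upper())
    pos_blocks, base_blocks = [], []
    for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1]):
        pos_blocks.append(np.arange(t0 + 1, t1 + 1, dtype=np.int64))
        base_blocks.append(rem_codes[q0:q1])
    positions = np.concatenate(pos_blocks) if pos_blocks else np.empty(0, np.int64)
    bases = np.concatenate(base_blocks) if base_blocks else np.empty(0, np.uint8)
    return PositionMap(positions=positions, bases=bases, score=score)


@dataclass
class PositionProfile:
    """Per-position base counts among precisely mapped remnant bases,
    one 4-vector (A/C/G/T) per subfamily."""

    position: int  # 1-based
    consensus_base: str
    subfamilies: tuple[str, ...]
    counts: np.ndarray = field(repr=False)  # (n_subfamilies, 4)


def _pool_counts(pool: SubfamilyPool, ref: ReferenceSeq,
                 params: AlignParams | None, trusted_offsets: bool) -> np.ndarray:
    """Tally (L, 5) base counts (column 4 = N, dropped by the caller)."""
    L = len(ref)
    counts = np.zeros((L, 5), dtype=np.int64)
    if trusted_offsets:
        if pool.offsets is None:
            raise ValueError(f"pool {pool.name!r} has no trusted offsets")
        for seq, off in zip(pool.remnants, pool.offsets):
            codes = encode(seq)
            np.add.at(counts, (np.arange(off - 1, off - 1 + len(codes)), codes), 1)
    else:
        for seq in pool.remnants:
            pm = align_remnant(seq, ref, params)
            if pm is None:
                continue
            np.add.at(counts, (pm.positions - 1, pm.bases), 1)
    return counts


def profile_counts(pools: list[SubfamilyPool], reference: ReferenceSeq,
                   params: AlignParams | None = None,
                   trusted_offsets: bool = False) -> np.ndarray:
    """Stacked per-subfamily count tensor, shape (n_pools, L, 4); N bases are
    never counted."""
    return np.stack([
        _pool_counts(p, reference, params, trusted_offsets)[:, :4] for p in pools
    ])


def build_profiles(pools: list[SubfamilyPool], reference: ReferenceSeq,
                   params: AlignParams | None = None,
                   trusted_offsets: bool = False) -> list[PositionProfile]:
    """One profile per non-excluded reference position."""
    if not pools:
        raise ValueError("at least one pool required")
    ages = [p.age for p in pools]
    if len(set(ages)) != len(ages):
        raise ValueError("pools must have distinct ages")
    counts = profile_counts(pools, reference, params, trusted_offsets)
    names = tuple(p.name for p in pools)
    excluded = reference.excluded_mask()
    return [
        PositionProfile(position=i + 1, consensus_base=reference.sequence[i],
                        subfamilies=names, counts=counts[:, i, :])
        for i in range(len(reference)) if not excluded[i]
    ]
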