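"""The k-mer rate database: build, strand symmetrization, fallback queries.

Every passing reference position contributes its centred 7-, 5-, 3- and
1-mer contexts; per (k-mer, target) the median rate across contributing
positions is stored.  Queries walk 7 -> 5 -> 3 -> 1, returning the record
from the longest context with a database entry; the BSP (basal substitution
propensity) of a position is the sum of its three returned rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import (BASES, BASE_CODES, N_CODE, complement_base, encode,
                   kmer_index, revcomp, window_indices)
from .datamodel import CONTEXT_LEVELS, RateConstant, ReferenceSeq, TrekDatabase
from .inference import PositionRates


# ------------------------------------------------------------------- building

def build_database(position_rates: list[PositionRates],
                   reference: ReferenceSeq) -> TrekDatabase:
    """Aggregate position rates into k-mer records at levels 7/5/3/1.

    A position contributes a level only when the centred window fits inside
    the reference and contains no N.  Ties in the median (even occurrence
    count) take the midpoint of the two central values.
    """
    if not position_rates:
        raise ValueError("no passing positions: cannot build a database")
    seq = reference.sequence
    L = len(seq)
    groups: dict[tuple[str, str], list[tuple[float, float | None]]] = {}
    for pr in position_rates:
        i = pr.position - 1
        for level in CONTEXT_LEVELS:
            h = level // 2
            if i - h < 0 or i + h >= L:
                continue
            kmer = seq[i - h : i + h + 1]
            if "N" in kmer:
                continue
            for target, rate in pr.rates.items():
                groups.setdefault((kmer, target), []).append(
                    (rate, pr.t_value.get(target))
                )
    db = TrekDatabase()
    for (kmer, target), vals in groups.items():
        rates = [v[0] for v in vals]
        ts = [v[1] for v in vals if v[1] is not None]
        db.add(RateConstant(
            kmer=kmer, target_base=target,
            rate=float(np.median(rates)),
            context_level=len(kmer),
            t_value=float(np.median(ts)) if ts else None,
            n_occurrences=len(rates),
        ))
    return db


# -------------------------------------------------------------- symmetrization

def symmetrize(db: TrekDatabase) -> TrekDatabase:
    """Equalise complementary rates of reverse-complementary k-mers.

    For k-mer K with target j, the strand mate is (revcomp(K), complement(j))
    at the same level.  Both present: both rates become (r1+r2)/2 (t-values
    averaged likewise; each record keeps its own n_occurrences).  Only one
    present: the existing (better-quality) value is assigned to both, i.e.
    the missing mate is created at the same context level.  Idempotent.
    """
    out = db.copy()
    for level in CONTEXT_LEVELS:
        keys = [k for k, r in out.records.items() if r.context_level == level]
        seen: set[tuple[str, str]] = set()
        for key in keys:
            if key in seen:
                continue
            kmer, target = key
            mate = (revcomp(kmer), complement_base(target))
            assert mate[0] != kmer or level == 1, "odd k-mer equal to its revcomp"
            seen.add(key)
            seen.add(mate)
            rec = out.records[key]
            other = out.records.get(mate)
            if other is not None and other.context_level == level:
                mean = 0.5 * (rec.rate + other.rate)
                ts = [t for t in (rec.t_value, other.t_value) if t is not None]
                t = float(np.mean(ts)) if ts else None
                rec.rate = other.rate = mean
                rec.t_value = other.t_value = t
            else:
                out.add(RateConstant(
                    kmer=mate[0], target_base=mate[1], rate=rec.rate,
                    context_level=level, t_value=rec.t_value,
                    n_occurrences=rec.n_occurrences,
                ))
    out.symmetrized = True
    out._resolved = None
    return out


# ------------------------------------------------------------------- querying

@dataclass
class QueryResult:
    """Three rate constants for one queried position plus their sum (BSP)."""

    central_base: str
    records: dict[str, RateConstant]      # target base -> record
    levels: dict[str, int]                # target base -> context level used

    @property
    def bsp(self) -> float:
        return sum(r.rate for r in self.records.values())

    def rate(self, target: str) -> float:
        return self.records[target].rate


def query(db: TrekDatabase, context: str) -> QueryResult:
    """Rates for the central base of an odd-length context (<= 7 nt).

    Per target base the record comes from the longest level (7 -> 5 -> 3 ->
    1) whose centred sub-k-mer has an entry; sub-k-mers containing N fall
    through to shorter levels.
    """
    context = context.upper()
    k = len(context)
    if k % 2 == 0 or k > 7:
        raise ValueError(f"context length must be odd and <= 7, got {k}")
    centre = k // 2
    central = context[centre]
    if central not in BASE_CODES:
        raise ValueError(f"central base {central!r} is not A/C/G/T")
    records: dict[str, RateConstant] = {}
    levels: dict[str, int] = {}
    for target in BASES:
        if target == central:
            continue
        for level in CONTEXT_LEVELS:
            if level > k:
                continue
            h = level // 2
            sub = context[centre - h : centre + h + 1]
            if "N" in sub:
                continue
            rec = db.get(sub, target)
            if rec is not None:
                records[target] = rec
                levels[target] = level
                break
        else:
            raise KeyError(
                f"database incomplete: no entry for {central}->{target} "
                f"even at level 1"
            )
    return QueryResult(central_base=central, records=records, levels=levels)


def map_sequence(db: TrekDatabase, seq: str) -> list[QueryResult | None]:
    """Per-position query results over a sequence (the BSP profile).

    Positions within 3 nt of either end use the longest centred k-mer that
    fits; positions whose central base is N are reported as None.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    L = len(seq)
    out: list[QueryResult | None] = []
    for i in range(L):
        if seq[i] not in BASE_CODES:
            out.append(None)
            continue
        h = min(i, L - 1 - i, 3)
        out.append(query(db, seq[i - h : i + h + 1]))
    return out


# ------------------------------------------------------- dense resolved table

def resolved_table(db: TrekDatabase) -> tuple[np.ndarray, np.ndarray]:
    """Fallback-resolved rates for all 16,384 heptamers.

    Returns ``(rates, levels)``, each of shape (16384, 4): ``rates[h, j]``
    is the rate from the heptamer's central base to base code j (0 for the
    central base itself), ``levels[h, j]`` the context level that supplied
    it.  Cached on the database; raises if level-1 coverage is incomplete.
    """
    if db._resolved is not None:
        return db._resolved
    if not db.is_complete():
        raise KeyError("database incomplete: missing level-1 records")
    rates = np.zeros((4 ** 7, 4), dtype=np.float64)
    levels = np.zeros((4 ** 7, 4), dtype=np.int8)
    hepta_central = (np.arange(4 ** 7) // (4 ** 3)) % 4
    for level in (1, 3, 5, 7):  # ascending so longer contexts overwrite
        h = level // 2
        lo, hi = 3 - h, 3 + h           # heptamer digit span of the window
        n_pre, n_post = lo, 6 - hi
        pre = np.arange(4 ** n_pre, dtype=np.int64)
        post = np.arange(4 ** n_post, dtype=np.int64)
        for (kmer, target), rec in db.level_records(level).items():
            tgt = BASE_CODES[target]
            base_idx = kmer_index(kmer) * (4 ** n_post)
            idx = (pre[:, None] * (4 ** (level + n_post)) + base_idx + post[None, :]).ravel()
            rates[idx, tgt] = rec.rate
            levels[idx, tgt] = level
    # wipe self-targets (central base) for safety
    rates[np.arange(4 ** 7), hepta_central] = 0.0
    levels[np.arange(4 ** 7), hepta_central] = 0
    db._resolved = (rates, levels)
    return db._resolved


def rates_for_codes(db: TrekDatabase, codes: np.ndarray) -> np.ndarray:
    """Per-position substitution rates, shape (L, 4), for an encoded sequence.

    Interior positions are resolved through the dense heptamer table; the
    first/last 3 positions (and any position near an N) go through
    :func:`query` with the longest centred k-mer that fits.
    """
    L = len(codes)
    rates = np.zeros((L, 4), dtype=np.float64)
    table, _ = resolved_table(db)
    if L >= 7:
        idx, valid = window_indices(codes, 7)
        centre = np.arange(3, L - 3)
        rates[centre[valid]] = table[idx[valid]]
        fixup = list(np.flatnonzero(~valid) + 3)
    else:
        fixup = list(range(3, max(L - 3, 3)))
    edges = [i for i in range(L) if i < 3 or i >= L - 3]
    from ._seq import decode

    seq = decode(codes)
    for i in edges + fixup:
        if codes[i] == N_CODE:
            continue
        h = min(i, L - 1 - i, 3)
        qr = query(db, seq[i - h : i + h + 1])
        for target, rec in qr.records.items():
            rates[i, BASE_CODES[target]] = rec.rate
    return rates


def count_constants(db: TrekDatabase) -> int:
    """Total rate constants served over all 4^7 heptamer queries (3 per
    heptamer when the database is complete)."""
    n = 0
    from ._seq import index_to_kmer

    for h in range(4 ** 7):
        n += len(query(db, index_to_kmer(h, 7)).records)
    return n
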