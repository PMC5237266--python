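"""Ground-truth generators: references, remnant pools and mutation sites.

The generator emulates the statistical premise of the inference: remnant
copies of a reference, silenced at known ages, accumulate substitutions
per site at context-dependent rates.  Two regimes are available: a
single-hit Bernoulli draw with p = r * t per target (the small-r*t regime
the inference assumes), and an exact continuous-time chain that allows
repeated hits, with the sequence context refreshed after every event.
Every emitted remnant comes with an event log that replays to it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import BASES, BASE_CODES, decode, encode, window_indices
from .datamodel import MutationSiteTable, RateConstant, ReferenceSeq, SubfamilyPool, TrekDatabase
from .mapper import rates_for_codes

#: default subfamily ages (myr) spanning the 3.1-20.4 myr window
DEFAULT_AGES = (3.1, 7.0, 10.0, 15.0, 20.4)

#: one substitution event: (1-based reference position, from base, to base)
Event = tuple[int, str, str]


def make_reference(length: int, gc: float, seed: int,
                   exclude_lowcomplexity: bool = False) -> ReferenceSeq:
    """I.i.d. random reference at the stated G+C content.

    With ``exclude_lowcomplexity`` a G-rich and an A-rich tail are appended
    and marked as excluded ranges, mimicking alignment-hostile 3' runs.
    """
    if not 0 <= gc <= 1:
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    seq = decode(codes)
    excluded: tuple[tuple[int, int], ...] = ()
    if exclude_lowcomplexity:
        g_tail = "".join(rng.choice(list("GGGGGA"), size=40))
        a_tail = "".join(rng.choice(list("AAAAAT"), size=47))
        excluded = ((length + 1, length + 40), (length + 41, length + 87))
        seq = seq + g_tail + a_tail
    return ReferenceSeq(seq, excluded)


@dataclass
class TruthModel:
    """Known context-dependent rates driving the generator.

    ``table`` has one row per k-mer (lexicological order) and one column per
    target base; entries are rates in byr^-1, self-targets 0.  ``k`` is the
    context length (odd).  Remnants are 5'-truncated: a fraction are full
    length, the rest start uniformly within the reference and run to its 3'
    end.
    """

    table: np.ndarray = field(repr=False)
    k: int = 7
    ages: tuple[float, ...] = DEFAULT_AGES
    n_per_age: int = 1000
    full_length_fraction: float = 0.5
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k > 7:
            raise ValueError("context length k must be odd and <= 7")
        if self.table.shape != (4 ** self.k, 4):
            raise ValueError(f"table must be (4^{self.k}, 4)")
        if (self.table < 0).any():
            raise ValueError("rates must be non-negative")

    @classmethod
    def random(cls, seed: int, lo: float = 0.2, hi: float = 4.0,
               k: int = 7, **kw) -> "TruthModel":
        """Each i->j rate drawn uniformly from [lo, hi] per context."""
        rng = np.random.default_rng(seed)
        table = rng.uniform(lo, hi, size=(4 ** k, 4))
        central = (np.arange(4 ** k) // (4 ** (k // 2))) % 4
        table[np.arange(4 ** k), central] = 0.0
        return cls(table=table, k=k, **kw)

    @classmethod
    def singleton(cls, matrix: np.ndarray, **kw) -> "TruthModel":
        """Context-free truth from a 4x4 rate matrix (rows = from-base)."""
        m = np.asarray(matrix, dtype=float).copy()
        np.fill_diagonal(m, 0.0)
        return cls(table=m, k=1, **kw)

    @classmethod
    def uniform(cls, rate: float, **kw) -> "TruthModel":
        """Every i->j rate equal; BSP = 3*rate for every base."""
        return cls.singleton(np.full((4, 4), rate), **kw)

    # -- rate lookups ------------------------------------------------------

    def singleton_rates(self) -> np.ndarray:
        """(4, 4) per-central-base mean rates across all contexts."""
        if self.k == 1:
            return self.table
        central = (np.arange(4 ** self.k) // (4 ** (self.k // 2))) % 4
        out = np.zeros((4, 4))
        for b in range(4):
            out[b] = self.table[central == b].mean(axis=0)
        return out

    def rates_for_codes(self, codes: np.ndarray) -> np.ndarray:
        """(L, 4) true rates along an encoded sequence; positions whose
        centred k-mer leaves the sequence use the singleton averages."""
        L = len(codes)
        single = self.singleton_rates()
        safe = np.minimum(codes, 3)
        rates = single[safe]
        rates[codes > 3] = 0.0
        if self.k > 1 and L >= self.k:
            h = self.k // 2
            idx, valid = window_indices(codes, self.k)
            centre = np.arange(h, L - h)
            rates[centre[valid]] = self.table[idx[valid]]
        return rates

    def to_database(self) -> TrekDatabase:
        """A rate database whose queries reproduce this truth exactly:
        level-k records for every context plus level-1 singleton medians."""
        from ._seq import index_to_kmer

        db = TrekDatabase()
        central = (np.arange(4 ** self.k) // (4 ** (self.k // 2))) % 4
        if self.k > 1:
            for idx in range(4 ** self.k):
                kmer = index_to_kmer(idx, self.k)
                for j, target in enumerate(BASES):
                    if j == central[idx]:
                        continue
                    db.add(RateConstant(kmer=kmer, target_base=target,
                                        rate=float(self.table[idx, j]),
                                        context_level=self.k))
        for b, base in enumerate(BASES):
            med = (np.median(self.table[central == b], axis=0)
                   if self.k > 1 else self.table[b])
            for j, target in enumerate(BASES):
                if j == b:
                    continue
                db.add(RateConstant(kmer=base, target_base=target,
                                    rate=float(med[j]), context_level=1))
        return db


# ---------------------------------------------------------------- evolution

def _draw_offsets(truth: TruthModel, L: int, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """0-based remnant start positions under the 5'-truncation model."""
    full = rng.random(n) < truth.full_length_fraction
    starts = rng.integers(0, max(L - truth.min_length, 1), size=n)
    starts[full] = 0
    return starts


def _evolve_single_hit(ref_codes: np.ndarray, rates: np.ndarray, age_byr: float,
                       offsets: np.ndarray, rng: np.random.Generator
                       ) -> tuple[np.ndarray, list[list[Event]]]:
    L = len(ref_codes)
    n = len(offsets)
    bsp = rates.sum(axis=1)
    p = bsp * age_byr
    if (p >= 1).any():
        raise ValueError("r*t >= 1 at some site: single-hit regime violated")
    cond = np.cumsum(np.divide(rates, bsp[:, None], where=bsp[:, None] > 0,
                               out=np.zeros_like(rates)), axis=1)
    mat = np.tile(ref_codes, (n, 1))
    hit = rng.random((n, L)) < p[None, :]
    hit &= np.arange(L)[None, :] >= offsets[:, None]
    rows, cols = np.nonzero(hit)
    u = rng.random(len(rows))
    targets = (u[:, None] >= cond[cols]).sum(axis=1).astype(np.uint8)
    mat[rows, cols] = targets
    logs: list[list[Event]] = [[] for _ in range(n)]
    for r, c, t in zip(rows, cols, targets):
        logs[r].append((int(c) + 1, BASES[ref_codes[c]], BASES[t]))
    return mat, logs


def _evolve_exact(ref_codes: np.ndarray, truth: TruthModel, age_byr: float,
                  offset: int, rng: np.random.Generator
                  ) -> tuple[np.ndarray, list[Event]]:
    """Gillespie chain for one remnant with +/- context refresh per event."""
    codes = ref_codes[offset:].copy()
    rates = truth.rates_for_codes(codes)
    per_pos = rates.sum(axis=1)
    log: list[Event] = []
    t = 0.0
    h = truth.k // 2
    while True:
        total = per_pos.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > age_byr:
            break
        pos = int(np.searchsorted(np.cumsum(per_pos), rng.random() * total))
        pos = min(pos, len(codes) - 1)
        row = rates[pos]
        tgt = int(np.searchsorted(np.cumsum(row), rng.random() * row.sum()))
        tgt = min(tgt, 3)
        log.append((offset + pos + 1, BASES[codes[pos]], BASES[tgt]))
        codes[pos] = tgt
        lo, hi = max(pos - h, 0), min(pos + h, len(codes) - 1)
        sub = truth.rates_for_codes(codes[max(lo - h, 0): hi + h + 1])
        rates[lo: hi + 1] = sub[lo - max(lo - h, 0): lo - max(lo - h, 0) + hi - lo + 1]
        per_pos[lo: hi + 1] = rates[lo: hi + 1].sum(axis=1)
    return codes, log


def evolve_remnant_pool(reference: ReferenceSeq, truth: TruthModel, seed: int,
                        mode: str = "single_hit"
                        ) -> tuple[list[SubfamilyPool], list[list[list[Event]]]]:
    """Evolve age-graded remnant pools from the reference.

    Returns one pool per age (named age_<myr>, carrying ground-truth
    offsets) and the per-pool, per-remnant event logs.
    """
    if mode not in ("single_hit", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    ref_codes = encode(reference.sequence)
    L = len(ref_codes)
    rates = truth.rates_for_codes(ref_codes)
    pools, logs = [], []
    for age in truth.ages:
        age_byr = age / 1000.0
        offsets = _draw_offsets(truth, L, truth.n_per_age, rng)
        if mode == "single_hit":
            mat, pool_logs = _evolve_single_hit(ref_codes, rates, age_byr,
                                                offsets, rng)
            remnants = [decode(mat[i, offsets[i]:]) for i in range(truth.n_per_age)]
        else:
            remnants, pool_logs = [], []
            for off in offsets:
                codes, log = _evolve_exact(ref_codes, truth, age_byr, int(off), rng)
                remnants.append(decode(codes))
                pool_logs.append(log)
        pools.append(SubfamilyPool(name=f"age_{age:g}", age=age,
                                   remnants=remnants,
                                   offsets=[int(o) + 1 for o in offsets]))
        logs.append(pool_logs)
    return pools, logs


def replay_events(reference: ReferenceSeq, offset: int,
                  events: list[Event]) -> str:
    """Apply an event log to the (1-based ``offset``-truncated) reference."""
    codes = encode(reference.sequence)[offset - 1:].copy()
    for pos, _from, to in events:
        codes[pos - offset] = BASE_CODES[to]
    return decode(codes)


# ------------------------------------------------------------ mutation sites

def make_mutation_sites(genome: str | ReferenceSeq, db: TrekDatabase, n: int,
                        weighting: str = "uniform", seed: int = 0,
                        snp_fraction: float = 0.0,
                        duplicate_fraction: float = 0.0,
                        chrom: str = "synth1") -> MutationSiteTable:
    """Sample a mutation-site table from a genome.

    ``weighting="bsp"`` samples positions proportionally to their basal
    substitution propensity under ``db`` (uniform otherwise); the alt base
    is always drawn proportionally to the per-target rates.  A fraction of
    rows is flagged as SNPs and a fraction duplicated, to exercise the
    filtering rules.
    """
    seq = genome.sequence if isinstance(genome, ReferenceSeq) else genome.upper()
    rng = np.random.default_rng(seed)
    codes = encode(seq)
    rates = rates_for_codes(db, codes)
    interior = np.arange(3, len(seq) - 3)
    if weighting == "uniform":
        w = np.ones(len(interior))
    elif weighting == "bsp":
        w = rates[interior].sum(axis=1)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    pos0 = rng.choice(interior, size=n, p=w)
    row_rates = rates[pos0]
    cum = np.cumsum(row_rates, axis=1)
    u = rng.random(n) * cum[:, -1]
    alts = (u[:, None] >= cum).sum(axis=1)
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": pos0 + 1,
        "ref": [seq[i] for i in pos0],
        "alt": [BASES[a] for a in alts],
        "is_snp": False,
        "non_coding": True,
        "cancer_type": "",
    })
    n_snp = int(round(n * snp_fraction))
    if n_snp:
        df.loc[rng.choice(n, size=n_snp, replace=False), "is_snp"] = True
    if duplicate_fraction > 0:
        n_dup = int(round(n * duplicate_fraction / (1 - duplicate_fraction)))
        if n_dup:
            dup = df[~df["is_snp"]].sample(n=n_dup, replace=True,
                                           random_state=int(rng.integers(2 ** 31)))
            df = pd.concat([df, dup], ignore_index=True)
    return MutationSiteTable(df)
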