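"""Core domain types: remnant pools, the consensus reference, rate constants
and the k-mer rate database.

Units: subfamily ages are in myr (million years); all rate constants are in
byr^-1 (events per site per billion years). File coordinates are 1-based
inclusive; internal arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import BASES, encode

CONTEXT_LEVELS = (7, 5, 3, 1)

#: 3'-end low-complexity stretches of the packaged L1Hs-like use case
#: (G-rich and A-rich runs prone to alignment error), 1-based inclusive.
DEFAULT_L1_EXCLUDED = ((5856, 5895), (6018, 6064))


@dataclass
class SubfamilyPool:
    """A cohort of retrotransposon remnants silenced at a common epoch.

    ``age`` (myr) dates the start of neutral substitution accumulation.
    ``offsets``, when present, are ground-truth 1-based start positions of
    each remnant within the reference (synthetic pools only); they enable a
    trusted-offsets fast path that bypasses alignment.
    """

    name: str
    age: float
    remnants: list[str]
    offsets: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"subfamily {self.name!r}: age must be > 0, got {self.age}")
        if self.offsets is not None and len(self.offsets) != len(self.remnants):
            raise ValueError(f"subfamily {self.name!r}: offsets/remnants length mismatch")
        for seq in self.remnants:
            if not seq:
                raise ValueError(f"subfamily {self.name!r}: empty remnant sequence")


@dataclass
class ReferenceSeq:
    """Consensus reference with 1-based inclusive excluded position ranges."""

    sequence: str
    excluded_ranges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        encode(self.sequence)  # validates the alphabet
        n = len(self.sequence)
        for lo, hi in self.excluded_ranges:
            if not (1 <= lo <= hi <= n):
                raise ValueError(f"excluded range ({lo}, {hi}) outside [1, {n}]")

    def __len__(self) -> int:
        return len(self.sequence)

    def excluded_mask(self) -> np.ndarray:
        """Boolean mask over 0-based positions; True where excluded."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for lo, hi in self.excluded_ranges:
            mask[lo - 1 : hi] = True
        return mask


@dataclass
class RateConstant:
    """One i->j substitution rate constant tied to a k-mer context.

    ``rate`` is the core rate r_core (byr^-1): the genomic single-base
    average plus the short-range context deviation for this k-mer.
    """

    kmer: str
    target_base: str
    rate: float
    context_level: int
    t_value: float | None = None
    n_occurrences: int = 1

    def __post_init__(self) -> None:
        if self.context_level not in CONTEXT_LEVELS:
            raise ValueError(f"context_level must be one of {CONTEXT_LEVELS}")
        if len(self.kmer) != self.context_level:
            raise ValueError(
                f"kmer {self.kmer!r} length does not match context_level {self.context_level}"
            )
        if any(b not in BASES for b in self.kmer):
            raise ValueError(f"kmer {self.kmer!r} contains non-ACGT characters")
        if self.target_base not in BASES:
            raise ValueError(f"invalid target base {self.target_base!r}")
        if self.target_base == self.central_base:
            raise ValueError(
                f"target base {self.target_base!r} equals central base of {self.kmer!r}"
            )
        if not self.rate >= 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if self.n_occurrences < 1:
            raise ValueError("n_occurrences must be >= 1")

    @property
    def central_base(self) -> str:
        return self.kmer[len(self.kmer) // 2]


class TrekDatabase:
    """k-mer-indexed store of rate constants at context levels 7/5/3/1.

    Lookup keys are (kmer, target_base).  A complete database has, for every
    single base, all three level-1 target records, which guarantees that the
    7->5->3->1 fallback of the mapper always terminates.
    """

    def __init__(self, records: dict[tuple[str, str], RateConstant] | None = None,
                 symmetrized: bool = False) -> None:
        self.records: dict[tuple[str, str], RateConstant] = {}
        self.symmetrized = symmetrized
        self._resolved: tuple[np.ndarray, np.ndarray] | None = None
        if records:
            for rec in records.values():
                self.add(rec)

    def add(self, rec: RateConstant) -> None:
        key = (rec.kmer, rec.target_base)
        self.records[key] = rec
        self._resolved = None

    def get(self, kmer: str, target_base: str) -> RateConstant | None:
        return self.records.get((kmer, target_base))

    def level_records(self, level: int) -> dict[tuple[str, str], RateConstant]:
        return {k: r for k, r in self.records.items() if r.context_level == level}

    def is_complete(self) -> bool:
        """True when every base has all three level-1 target records."""
        for base in BASES:
            for target in BASES:
                if target != base and (base, target) not in self.records:
                    return False
        return True

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrekDatabase):
            return NotImplemented
        if self.symmetrized != other.symmetrized:
            return False
        if set(self.records) != set(other.records):
            return False
        for key, rec in self.records.items():
            o = other.records[key]
            if (rec.kmer, rec.target_base, rec.context_level, rec.n_occurrences) != (
                o.kmer, o.target_base, o.context_level, o.n_occurrences
            ):
                return False
            if not np.isclose(rec.rate, o.rate, rtol=0, atol=1e-12):
                return False
            if (rec.t_value is None) != (o.t_value is None):
                return False
            if rec.t_value is not None and not np.isclose(rec.t_value, o.t_value,
                                                          rtol=0, atol=1e-9):
                return False
        return True

    def copy(self) -> "TrekDatabase":
        out = TrekDatabase(symmetrized=self.symmetrized)
        for key, rec in self.records.items():
            out.records[key] = replace(rec)
        return out


@dataclass
class MutationSiteTable:
    """Normalised mutation-site table (BED-like, 1-based positions).

    Backed by a pandas DataFrame with columns: chrom, pos, ref, alt,
    is_snp, non_coding, cancer_type (primT:primC label, may be empty).
    """

    df: "object" = field(repr=False)

    COLUMNS = ("chrom", "pos", "ref", "alt", "is_snp", "non_coding", "cancer_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"mutation site table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def validate_against(self, genome: dict[str, str]) -> None:
        """Check every row's ref base and bounds against the genome."""
        for row in self.df.itertuples(index=False):
            seq = genome.get(row.chrom)
            if seq is None:
                raise ValueError(f"unknown sequence id {row.chrom!r}")
            if not (1 <= row.pos <= len(seq)):
                raise ValueError(f"{row.chrom}:{row.pos} outside [1, {len(seq)}]")
            if seq[row.pos - 1] != row.ref:
                raise ValueError(
                    f"{row.chrom}:{row.pos} ref {row.ref!r} does not match genome "
                    f"{seq[row.pos - 1]!r}"
                )
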