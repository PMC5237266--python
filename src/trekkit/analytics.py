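"""k-mer spectra, mutation-site filtering, enrichment scores and the
genome-wide mutation-rate estimate.

k-mers are indexed lexicologically (A<C<G<T, base-4), so a spectrum is a
dense vector of length 4^k.  The cancer-style enrichment ratio of a 7-mer
is its occurrence fraction among mutation sites divided by its occurrence
fraction in the background genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import BASES, BASE_CODES, encode, index_to_kmer, kmer_index, window_indices
from .datamodel import MutationSiteTable, TrekDatabase
from .mapper import query

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- spectra

@dataclass
class KmerSpectrum:
    """Counts and/or fractions over all 4^k k-mers, lexicologically indexed."""

    k: int
    counts: np.ndarray | None
    fractions: np.ndarray

    @classmethod
    def from_counts(cls, k: int, counts: np.ndarray) -> "KmerSpectrum":
        total = counts.sum()
        frac = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
        return cls(k=k, counts=counts, fractions=frac)

    def kmer(self, idx: int) -> str:
        return index_to_kmer(idx, self.k)


def count_kmers(seq: str, k: int) -> KmerSpectrum:
    """Sliding-window k-mer counts; windows containing N are skipped."""
    if not 1 <= k <= 7:
        raise ValueError("k must be in 1..7")
    counts = np.zeros(4 ** k, dtype=np.int64)
    if k <= len(seq):
        idx, valid = window_indices(encode(seq.upper()), k)
        counts = np.bincount(idx[valid], minlength=4 ** k)
    return KmerSpectrum.from_counts(k, counts)


def expected_fractions(base_composition, k: int) -> KmerSpectrum:
    """Fractions expected by chance: each k-mer's fraction is the product of
    its constituent base fractions."""
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 fractions summing to 1")
    frac = comp.copy()
    for _ in range(k - 1):
        frac = np.multiply.outer(frac, comp).ravel()
    return KmerSpectrum(k=k, counts=None, fractions=frac)


def contains_cg_mask(k: int) -> np.ndarray:
    """Mask over 4^k k-mers containing a CG dinucleotide anywhere."""
    return np.array(["CG" in index_to_kmer(i, k) for i in range(4 ** k)])


def central_cpg_mask(k: int) -> np.ndarray:
    """Mask over 4^k k-mers whose central base is the C or G of a CpG dyad."""
    if k < 2:
        return np.zeros(4 ** k, dtype=bool)
    c = k // 2
    out = np.zeros(4 ** k, dtype=bool)
    for i in range(4 ** k):
        s = index_to_kmer(i, k)
        out[i] = (s[c] == "C" and c + 1 < k and s[c + 1] == "G") or \
                 (s[c] == "G" and c - 1 >= 0 and s[c - 1] == "C")
    return out


def spectrum_correlation(obs: KmerSpectrum, ref: KmerSpectrum,
                         exclude: str = "none") -> float:
    """Pearson correlation of two spectra's fractions over retained k-mers.

    ``exclude`` is one of ``none``, ``contains_cg`` (any CG dinucleotide in
    the k-mer) or ``central_cpg`` (central base part of a CpG dyad).
    """
    if obs.k != ref.k:
        raise ValueError("spectra must share k")
    keep = np.ones(4 ** obs.k, dtype=bool)
    if exclude == "contains_cg":
        keep = ~contains_cg_mask(obs.k)
    elif exclude == "central_cpg":
        keep = ~central_cpg_mask(obs.k)
    elif exclude != "none":
        raise ValueError(f"unknown exclusion {exclude!r}")
    if keep.sum() < 3:
        raise ValueError("fewer than 3 retained k-mers")
    return float(np.corrcoef(obs.fractions[keep], ref.fractions[keep])[0, 1])


# ----------------------------------------------------------- site filtering

@dataclass
class FilterReport:
    n_input: int
    n_coding: int
    n_snp: int
    n_duplicate: int
    n_kept: int


def filter_mutation_sites(table: MutationSiteTable) -> tuple[MutationSiteTable, FilterReport]:
    """Keep non-coding, non-SNP, first-encountered-unique sites.

    Duplicates are rows identical in (chrom, pos, ref, alt); the first copy
    survives.
    """
    df = table.df
    n0 = len(df)
    noncoding = df[df["non_coding"]]
    n_coding = n0 - len(noncoding)
    nosnp = noncoding[~noncoding["is_snp"]]
    n_snp = len(noncoding) - len(nosnp)
    deduped = nosnp.drop_duplicates(subset=["chrom", "pos", "ref", "alt"], keep="first")
    n_dup = len(nosnp) - len(deduped)
    report = FilterReport(n_input=n0, n_coding=n_coding, n_snp=n_snp,
                          n_duplicate=n_dup, n_kept=len(deduped))
    return MutationSiteTable(deduped.reset_index(drop=True)), report


# --------------------------------------------------------------- enrichment

@dataclass
class EnrichmentRecord:
    """Occurrence of one 7-mer at mutation sites relative to the genome."""

    kmer: str
    site_fraction: float
    genome_fraction: float
    ratio: float                 # NaN when genome_fraction == 0
    central_bsp: float
    cpg_central: bool
    contains_cg: bool
    n_sites: int


def enrichment(table: MutationSiteTable, genome: dict[str, str] | str,
               db: TrekDatabase) -> list[EnrichmentRecord]:
    """Per-7-mer enrichment ratio of mutation-site contexts vs the genome.

    The numerator counts the centred 7-mers of the (filtered) sites; the
    denominator is the overlapping-window 7-mer spectrum of the whole
    background genome.  Sites whose ref base mismatches the genome, or whose
    centred 7-mer leaves the sequence or contains N, are rejected and logged.
    """
    if isinstance(genome, str):
        genome = {"synth1": genome}
    genome = {k: v.upper() for k, v in genome.items()}
    bg = np.zeros(4 ** 7, dtype=np.int64)
    for seq in genome.values():
        bg += count_kmers(seq, 7).counts
    bg_spec = KmerSpectrum.from_counts(7, bg)

    site_counts = np.zeros(4 ** 7, dtype=np.int64)
    n_rejected = 0
    for row in table.df.itertuples(index=False):
        seq = genome.get(row.chrom)
        i = row.pos - 1
        if seq is None or not (0 <= i < len(seq)) or seq[i] != row.ref:
            n_rejected += 1
            continue
        if i < 3 or i + 3 >= len(seq):
            n_rejected += 1
            continue
        heptamer = seq[i - 3 : i + 4]
        if "N" in heptamer:
            n_rejected += 1
            continue
        site_counts[kmer_index(heptamer)] += 1
    if n_rejected:
        logger.info("enrichment: rejected %d sites (ref mismatch/bounds/N)", n_rejected)
    total_sites = site_counts.sum()
    if total_sites == 0:
        raise ValueError("no usable mutation sites")

    cg_any = contains_cg_mask(7)
    cg_central = central_cpg_mask(7)
    records = []
    for idx in np.flatnonzero(site_counts):
        kmer = index_to_kmer(idx, 7)
        sf = site_counts[idx] / total_sites
        gf = float(bg_spec.fractions[idx])
        records.append(EnrichmentRecord(
            kmer=kmer,
            site_fraction=float(sf),
            genome_fraction=gf,
            ratio=float(sf / gf) if gf > 0 else float("nan"),
            central_bsp=query(db, kmer).bsp,
            cpg_central=bool(cg_central[idx]),
            contains_cg=bool(cg_any[idx]),
            n_sites=int(site_counts[idx]),
        ))
    return records


def enrichment_slope(records: list[EnrichmentRecord], bsp_max: float = 1.3,
                     exclude_central_cpg: bool = True) -> float:
    """OLS slope of enrichment ratio versus central-base BSP, restricted to
    records with BSP below ``bsp_max`` (central-CpG 7-mers excluded by
    default)."""
    pts = [(r.central_bsp, r.ratio) for r in records
           if r.central_bsp < bsp_max and np.isfinite(r.ratio)
           and not (exclude_central_cpg and r.cpg_central)]
    if len(pts) < 3:
        raise ValueError(f"only {len(pts)} retained records; need >= 3")
    x, y = np.array(pts).T
    return float(stats.linregress(x, y).slope)


# -------------------------------------------------------- mutation-rate math

@dataclass
class GenomeRateEstimate:
    rate_byr: float
    rate_per_generation: float
    generation_years: float


def genome_rate_estimate(base_composition, db: TrekDatabase,
                         generation_years: float = 20.0) -> GenomeRateEstimate:
    """Overall mutation-rate estimate: the base-composition-weighted mean of
    the four singleton (level-1) BSPs, plus its per-generation conversion."""
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 fractions summing to 1")
    bsp = np.zeros(4)
    for i, base in enumerate(BASES):
        for target in BASES:
            if target == base:
                continue
            rec = db.get(base, target)
            if rec is None:
                raise KeyError(f"missing level-1 record {base}->{target}")
            bsp[i] += rec.rate
    rate_byr = float(comp @ bsp)
    return GenomeRateEstimate(
        rate_byr=rate_byr,
        rate_per_generation=rate_byr * generation_years / 1e9,
        generation_years=generation_years,
    )


def convert_rate(rate_per_generation: float, generation_years: float) -> float:
    """Per-generation rate to a time-domain rate constant in byr^-1."""
    if rate_per_generation < 0 or generation_years <= 0:
        raise ValueError("rates must be non-negative and generation span positive")
    return rate_per_generation / generation_years * 1e9
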