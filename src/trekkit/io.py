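"""Readers and writers for the file formats the pipeline touches.

All positions in external files are 1-based inclusive.  Rate tables are TSV
with the fixed column set (kmer, target_base, rate_byr, context_level,
t_value, n_occurrences); a leading ``# symmetrized: ...`` comment preserves
the database flag across round trips.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import BASES
from .datamodel import MutationSiteTable, RateConstant, ReferenceSeq, SubfamilyPool

RATE_TABLE_COLUMNS = ("kmer", "target_base", "rate_byr", "context_level",
                      "t_value", "n_occurrences")

_VALID = set(BASES) | {"N"}


def read_ages(path: str | Path) -> dict[str, float]:
    """Read a TSV ages table (columns: subfamily, age_myr)."""
    df = pd.read_csv(path, sep="\t")
    if not {"subfamily", "age_myr"} <= set(df.columns):
        raise ValueError(f"{path}: ages table needs columns 'subfamily' and 'age_myr'")
    ages = dict(zip(df["subfamily"].astype(str), df["age_myr"].astype(float)))
    for name, age in ages.items():
        if not age > 0:
            raise ValueError(f"{path}: non-positive age {age} for subfamily {name!r}")
    return ages


def _validated_seq(seq: str, record_id: str, path: str | Path) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"{path}: record {record_id!r} contains non-DNA characters {sorted(bad)}"
        )
    return seq


def read_pools(fasta_paths: list[str | Path], ages: dict[str, float]) -> list[SubfamilyPool]:
    """Load remnant FASTAs into subfamily pools; names are FASTA stems.

    Every FASTA must have a matching age (myr) entry; sequences are
    uppercased and validated against the A/C/G/T/N alphabet.
    """
    pools = []
    seen: set[str] = set()
    for path in fasta_paths:
        name = Path(path).stem
        if name in seen:
            raise ValueError(f"duplicate subfamily name {name!r}")
        seen.add(name)
        if name not in ages:
            raise ValueError(f"no age given for subfamily {name!r} ({path})")
        remnants = [
            _validated_seq(str(rec.seq), rec.id, path)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not remnants:
            warnings.warn(f"{path}: empty FASTA, pool {name!r} has zero remnants")
        pools.append(SubfamilyPool(name=name, age=ages[name], remnants=remnants))
    return pools


def read_reference(path: str | Path,
                   excluded_ranges: tuple[tuple[int, int], ...] = ()) -> ReferenceSeq:
    """Read the first record of a FASTA as the consensus reference."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return ReferenceSeq(_validated_seq(str(rec.seq), rec.id, path),
                            tuple(excluded_ranges))
    raise ValueError(f"{path}: no FASTA records")


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- rate tables

def write_rate_table(db, path: str | Path) -> None:
    from .datamodel import TrekDatabase  # local to avoid cycle at import time

    if not isinstance(db, TrekDatabase) or len(db) == 0:
        raise ValueError("refusing to write an empty rate database")
    keys = sorted(db.records, key=lambda kt: (-db.records[kt].context_level, kt))
    with open(path, "w") as fh:
        fh.write(f"# symmetrized: {str(db.symmetrized).lower()}\n")
        fh.write("\t".join(RATE_TABLE_COLUMNS) + "\n")
        for key in keys:
            r = db.records[key]
            t = "NA" if r.t_value is None else repr(float(r.t_value))
            fh.write(
                f"{r.kmer}\t{r.target_base}\t{float(r.rate)!r}\t{r.context_level}"
                f"\t{t}\t{r.n_occurrences}\n"
            )


def read_rate_table(path: str | Path):
    from .datamodel import TrekDatabase

    db = TrekDatabase()
    with open(path) as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            if "symmetrized:" in line:
                db.symmetrized = line.split("symmetrized:")[1].strip() == "true"
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != RATE_TABLE_COLUMNS:
                raise ValueError(f"{path}:{lineno}: bad header {fields}")
            header_seen = True
            continue
        if len(fields) != len(RATE_TABLE_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(RATE_TABLE_COLUMNS)} "
                             f"columns, got {len(fields)}")
        kmer, target, rate, level, t, n = fields
        try:
            rec = RateConstant(
                kmer=kmer,
                target_base=target,
                rate=float(rate),
                context_level=int(level),
                t_value=None if t == "NA" else float(t),
                n_occurrences=int(n),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        db.add(rec)
    if len(db) == 0:
        raise ValueError(f"{path}: no rate records")
    return db


# ------------------------------------------------------------- mutation sites

def read_sites(path: str | Path) -> MutationSiteTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cancer_type": str},
                     keep_default_na=False)
    for col in ("is_snp", "non_coding"):
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    if "cancer_type" not in df.columns:
        df["cancer_type"] = ""
    df["pos"] = df["pos"].astype(int)
    return MutationSiteTable(df[list(MutationSiteTable.COLUMNS)].copy())


def write_sites(table: MutationSiteTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
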