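"""Filter, combine and export entity tables — the non-graphical query layer.

Tables are flat pandas DataFrames keyed by an ``id`` column at one of
three levels (gene, transcript, snp), with per-library p-value columns
named ``p_<measure>:<library>`` and direction columns
``dir_<measure>:<library>``. Filters combine by conjunction; a union of
two filtered tables expresses disjunction. An undefined p-value (NaN)
fails every p-value criterion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from . import formats_io as fio
from .formats_io import ALT_SUFFIX, REF_SUFFIX, SequenceRecord
from .parental_seq import ParentalTranscriptPair

LEVELS = {"gene", "transcript", "snp"}


@dataclass
class EntityTable:
    """A queryable table of entities at one level."""

    level: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown table level {self.level!r}")
        if "id" not in self.df.columns:
            raise ValueError("entity table requires an 'id' column")
        if self.df["id"].duplicated().any():
            raise ValueError("entity ids must be unique")

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    def __len__(self) -> int:
        return len(self.df)

    def select_columns(self, columns: Iterable[str]) -> "EntityTable":
        cols = ["id"] + [c for c in columns if c != "id"]
        return EntityTable(self.level, self.df[cols].copy())


@dataclass
class FilterSpec:
    """Conjunction of row criteria.

    ``p_ceilings`` maps (measure, library) to a p-value ceiling in (0, 1];
    rows with an undefined p-value there are excluded. ``direction``
    requires at least one library (those referenced by ``p_ceilings``, or
    all libraries when none are referenced) to point that way.
    """

    rank: Optional[int] = None
    min_missense: Optional[int] = None
    min_damaging: Optional[int] = None
    p_ceilings: dict[tuple[str, str], float] = field(default_factory=dict)
    min_snps_covered: Optional[int] = None
    direction: Optional[str] = None
    required_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        criteria = (self.rank, self.min_missense, self.min_damaging,
                    self.min_snps_covered, self.direction)
        if all(c is None for c in criteria) and not self.p_ceilings \
                and not self.required_flags:
            raise ValueError("FilterSpec with no criteria set")
        for (measure, lib), ceiling in self.p_ceilings.items():
            if not 0.0 < ceiling <= 1.0:
                raise ValueError(
                    f"p ceiling for {measure}:{lib} outside (0,1]")
        if self.direction is not None and \
                self.direction not in {"ref>alt", "alt>ref"}:
            raise ValueError(f"unknown direction {self.direction!r}")


def filter_table(t: EntityTable, f: FilterSpec) -> EntityTable:
    """Rows satisfying the conjunction of all set criteria (order kept)."""
    df = t.df
    mask = pd.Series(True, index=df.index)
    if f.rank is not None:
        mask &= df.get("rank", pd.Series(-1, index=df.index)) == f.rank
    if f.min_missense is not None:
        mask &= df.get("n_missense",
                       pd.Series(0, index=df.index)) >= f.min_missense
    if f.min_damaging is not None:
        mask &= df.get("n_damaging",
                       pd.Series(0, index=df.index)) >= f.min_damaging
    if f.min_snps_covered is not None:
        mask &= df.get("n_snps_covered",
                       pd.Series(0, index=df.index)) >= f.min_snps_covered
    for (measure, lib), ceiling in f.p_ceilings.items():
        col = f"p_{measure}:{lib}"
        if col not in df.columns:
            raise KeyError(f"unknown library/measure column {col}")
        mask &= df[col].notna() & (df[col] < ceiling)
    if f.direction is not None:
        if f.p_ceilings:
            dir_cols = [f"dir_{m}:{lib}" for (m, lib) in f.p_ceilings]
        else:
            dir_cols = [c for c in df.columns if c.startswith("dir_")]
        if not dir_cols:
            raise KeyError("no direction columns in table")
        missing = [c for c in dir_cols if c not in df.columns]
        if missing:
            raise KeyError(f"unknown library/measure column {missing[0]}")
        dmask = pd.Series(False, index=df.index)
        for c in dir_cols:
            dmask |= df[c] == f.direction
        mask &= dmask
    for flag in f.required_flags:
        if flag not in df.columns:
            raise KeyError(f"unknown flag column {flag}")
        mask &= df[flag].astype(bool)
    return EntityTable(t.level, df[mask].copy())


def combine_tables(a: EntityTable, b: EntityTable, op: str) -> EntityTable:
    """Key-set algebra on entity ids; ``union`` prefers a's row on
    collisions, ``difference`` is a minus b."""
    if a.level != b.level:
        raise ValueError(
            f"cannot combine tables of level {a.level} and {b.level}")
    a_ids = set(a.ids)
    if op == "union":
        extra = b.df[~b.df["id"].isin(a_ids)]
        df = pd.concat([a.df, extra], ignore_index=True)
    elif op == "intersection":
        df = a.df[a.df["id"].isin(set(b.ids))].copy()
    elif op == "difference":
        df = a.df[~a.df["id"].isin(set(b.ids))].copy()
    else:
        raise ValueError(f"unknown set operation {op!r}")
    return EntityTable(a.level, df.reset_index(drop=True))


def export_selection(t: EntityTable, what: str, path: str | os.PathLike,
                     seqs: Optional[Mapping[str, ParentalTranscriptPair]]
                     = None,
                     columns: Optional[Iterable[str]] = None) -> None:
    """Export a table as TSV, or the parental sequences of its rows.

    ``tsv``: header plus one row per entity, undefined values as "NA",
    columns in selection order. ``parental_fasta``: ``path`` is a
    directory receiving ``transcripts.fa`` (paired _R/_A nucleotide
    records per selected transcript) and ``proteins.fa`` (for coding
    transcripts).
    """
    if what == "tsv":
        out = t.select_columns(columns).df if columns is not None else t.df
        out.to_csv(path, sep="\t", index=False, na_rep="NA")
        return
    if what != "parental_fasta":
        raise ValueError(f"unknown export kind {what!r}")
    if seqs is None:
        raise ValueError("parental_fasta export needs a sequence store")
    missing = [tid for tid in t.ids if tid not in seqs]
    if missing:
        raise KeyError("no parental sequences for: " + ", ".join(missing))
    os.makedirs(path, exist_ok=True)
    nt_records: list[SequenceRecord] = []
    aa_records: list[SequenceRecord] = []
    for tid in t.ids:
        pair = seqs[tid]
        nt_records.append(SequenceRecord(tid + REF_SUFFIX, pair.ref_seq))
        nt_records.append(SequenceRecord(tid + ALT_SUFFIX, pair.alt_seq))
        if pair.ref_protein:
            aa_records.append(
                SequenceRecord(tid + REF_SUFFIX, pair.ref_protein))
            aa_records.append(
                SequenceRecord(tid + ALT_SUFFIX, pair.alt_protein))
    fio.write_fasta(nt_records, os.path.join(path, "transcripts.fa"))
    if aa_records:
        fio.write_fasta(aa_records, os.path.join(path, "proteins.fa"))


def read_table(path: str | os.PathLike, level: str) -> EntityTable:
    """Re-read an exported TSV (NA becomes NaN)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    return EntityTable(level, df)
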