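"""Readers and writers for CpG methylation tracks and per-read call tables.

Two on-disk formats are owned by this module:

* canonical bedmethyl — 5 tab-separated columns
  ``chrom  start  end  meth_count  total_count``, one line per CpG, sorted.
  The position is the 0-based coordinate of the forward-strand C of the CpG
  dinucleotide. A reader shim additionally accepts the 9+-column modkit
  dialect, collapsing minus-strand records onto the forward-strand C.
* read-level TSV — header ``read_id  chrom  pos  call  allele_tag  hap_tag``
  with one row per CpG call per read; ``call`` is ``M`` or ``U``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HAPLOTYPES = ("combined", "hap1", "hap2")
TRACK_COLUMNS = ["chrom", "pos", "haplotype", "meth", "unmeth"]


class ParseError(ValueError):
    """Raised on malformed input lines; message names the offending line."""


class ValidationError(ValueError):
    """Raised on structurally valid but semantically invalid input."""


@dataclass(frozen=True)
class CpGRecord:
    chrom: str
    pos: int
    haplotype: str = "combined"
    meth_count: int = 0
    unmeth_count: int = 0

    @property
    def total(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def fraction(self) -> float:
        return self.meth_count / self.total if self.total > 0 else float("nan")


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced molecule: ordered binary CpG calls plus optional tags."""

    read_id: str
    chrom: str
    calls: tuple[tuple[int, str], ...]
    allele_tag: str = "none"
    haplotype_tag: str = "none"

    def __post_init__(self) -> None:
        if not self.calls:
            raise ValidationError(f"read {self.read_id}: no calls")
        positions = [p for p, _ in self.calls]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValidationError(
                f"read {self.read_id}: positions not strictly increasing"
            )
        for _, c in self.calls:
            if c not in ("M", "U"):
                raise ParseError(f"read {self.read_id}: unknown call symbol {c!r}")

    def calls_in(self, start: int, end: int) -> tuple[tuple[int, str], ...]:
        return tuple((p, c) for p, c in self.calls if start <= p < end)

    def calls_at(self, positions: Sequence[int]) -> dict[int, str]:
        wanted = set(positions)
        return {p: c for p, c in self.calls if p in wanted}


class MethylationTrack:
    """Per-CpG methylated/unmethylated counts for one sample.

    Rows are keyed by (chrom, pos, haplotype) with haplotype one of
    ``combined``, ``hap1``, ``hap2``; the frame is kept sorted and key-unique.
    """

    def __init__(self, sample_id: str, df: pd.DataFrame, validate: bool = True):
        self.sample_id = sample_id
        df = df.loc[:, TRACK_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["unmeth"] = df["unmeth"].astype(np.int64)
        df = df.sort_values(["chrom", "pos", "haplotype"], kind="mergesort")
        df = df.reset_index(drop=True)
        if validate:
            if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
                raise ValidationError(f"{sample_id}: negative counts")
            if df.duplicated(["chrom", "pos", "haplotype"]).any():
                dup = df[df.duplicated(["chrom", "pos", "haplotype"])].iloc[0]
                raise ValidationError(
                    f"{sample_id}: duplicate record at "
                    f"{dup.chrom}:{dup.pos} ({dup.haplotype})"
                )
            bad = ~df["haplotype"].isin(HAPLOTYPES)
            if bad.any():
                raise ValidationError(
                    f"{sample_id}: unknown haplotype {df.loc[bad, 'haplotype'].iloc[0]!r}"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"MethylationTrack({self.sample_id!r}, n={len(self)})"

    def haplotype(self, haplotype: str = "combined") -> pd.DataFrame:
        """The sub-frame for one haplotype label, sorted by (chrom, pos)."""
        return self.df[self.df["haplotype"] == haplotype]

    def with_fraction(self) -> pd.DataFrame:
        df = self.df.copy()
        total = df["meth"] + df["unmeth"]
        with np.errstate(invalid="ignore"):
            df["fraction"] = np.where(total > 0, df["meth"] / total, np.nan)
        return df

    def records(self) -> Iterable[CpGRecord]:
        for row in self.df.itertuples(index=False):
            yield CpGRecord(row.chrom, row.pos, row.haplotype, row.meth, row.unmeth)

    def restrict(self, chroms: Iterable[str]) -> "MethylationTrack":
        keep = set(chroms)
        return MethylationTrack(
            self.sample_id, self.df[self.df["chrom"].isin(keep)], validate=False
        )


def track_from_arrays(
    sample_id: str,
    chrom,
    pos,
    meth,
    unmeth,
    haplotype="combined",
    validate: bool = True,
) -> MethylationTrack:
    n = len(pos)
    df = pd.DataFrame(
        {
            "chrom": chrom if not isinstance(chrom, str) else [chrom] * n,
            "pos": pos,
            "haplotype": haplotype if not isinstance(haplotype, str) else [haplotype] * n,
            "meth": meth,
            "unmeth": unmeth,
        }
    )
    return MethylationTrack(sample_id, df, validate=validate)


def parse_bedmethyl(
    path,
    haplotype_label: str = "combined",
    sample_id: str | None = None,
    dialect: str = "canonical",
) -> MethylationTrack:
    """Parse a bedmethyl file into a MethylationTrack.

    ``dialect='canonical'`` expects 5 columns (chrom, start, end, meth, total).
    ``dialect='modkit'`` accepts the 9+-column modkit table (strand in column
    6, valid coverage in column 10, modified count in column 12); minus-strand
    records are collapsed onto the forward-strand C at ``start - 1`` by
    summing counts.
    """
    if haplotype_label not in HAPLOTYPES:
        raise ValidationError(f"unknown haplotype label {haplotype_label!r}")
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "canonical":
                    if len(fields) < 5:
                        raise ValueError("expected 5 columns")
                    chrom, start = fields[0], int(fields[1])
                    meth, total = int(fields[3]), int(fields[4])
                    pos = start
                elif dialect == "modkit":
                    if len(fields) < 12:
                        raise ValueError("expected >=12 columns")
                    chrom, start, strand = fields[0], int(fields[1]), fields[5]
                    total, meth = int(fields[9]), int(fields[11])
                    pos = start - 1 if strand == "-" else start
                else:
                    raise ValidationError(f"unknown dialect {dialect!r}")
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: malformed line {lineno}: {exc}") from exc
            if meth < 0 or total < 0 or meth > total:
                raise ValidationError(
                    f"{path}: invalid counts at line {lineno} (meth={meth}, total={total})"
                )
            rows.append((chrom, pos, meth, total - meth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    if not df.empty:
        df = df.groupby(["chrom", "pos"], as_index=False)[["meth", "unmeth"]].sum()
    df["haplotype"] = haplotype_label
    sid = sample_id if sample_id is not None else str(path)
    return MethylationTrack(sid, df.reindex(columns=TRACK_COLUMNS, fill_value=haplotype_label))


def write_bedmethyl(track: MethylationTrack, path, haplotype: str = "combined") -> None:
    """Write one haplotype of a track as canonical 5-column bedmethyl."""
    sub = track.haplotype(haplotype)
    with open(path, "w") as fh:
        for row in sub.itertuples(index=False):
            total = row.meth + row.unmeth
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 2}\t{row.meth}\t{total}\n")


def parse_read_table(path) -> list[ReadRecord]:
    """Parse the read-level call TSV into ReadRecords (one per read_id x chrom)."""
    grouped: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header and header.split("\t")[0] != "read_id":
            raise ParseError(f"{path}: missing read-table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: malformed line {lineno}")
            read_id, chrom, pos_s, call, allele, hap = fields[:6]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}: malformed line {lineno}: {exc}") from exc
            if call not in ("M", "U"):
                raise ParseError(
                    f"{path}: unknown call symbol {call!r} at line {lineno}"
                )
            key = (read_id, chrom)
            if key not in grouped:
                grouped[key] = {"calls": {}, "allele": allele, "hap": hap}
                order.append(key)
            entry = grouped[key]
            if pos in entry["calls"]:
                raise ValidationError(
                    f"{path}: duplicate call for read {read_id} at {chrom}:{pos}"
                )
            entry["calls"][pos] = call
    reads = []
    for read_id, chrom in order:
        entry = grouped[(read_id, chrom)]
        calls = tuple(sorted(entry["calls"].items()))
        reads.append(
            ReadRecord(read_id, chrom, calls, entry["allele"], entry["hap"])
        )
    return reads


def write_read_table(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tpos\tcall\tallele_tag\thap_tag\n")
        for read in reads:
            for pos, call in read.calls:
                fh.write(
                    f"{read.read_id}\t{read.chrom}\t{pos}\t{call}"
                    f"\t{read.allele_tag}\t{read.haplotype_tag}\n"
                )
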