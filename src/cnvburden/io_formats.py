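"""Readers and writers for every external format the pipeline touches.

Internal coordinate convention: 0-based half-open everywhere.  The PennCNV
rawcnv dialect is 1-based inclusive and BED is 0-based half-open; conversion
happens at the I/O boundary only, so ``call.length == end - start`` equals
the 1-based inclusive length PennCNV prints as ``length=``.

Chromosome labels are normalised by stripping a leading ``chr``; only
autosomes 1-22 are accepted (the calls derive from autosomal SNP probes).
GRCh37 is assumed and never checked against a sequence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

AUTOSOMES = frozenset(range(1, 23))

DEL = "DEL"
DUP = "DUP"


class FormatError(ValueError):
    """A file did not conform to its documented dialect."""


def normalize_chrom(label: str | int) -> int:
    """Strip a leading ``chr`` and return the autosome number.

    Raises :class:`FormatError` for anything outside 1-22.
    """
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        c = int(s)
    except ValueError:
        raise FormatError(f"non-autosomal or unparseable chromosome {label!r}")
    if c not in AUTOSOMES:
        raise FormatError(f"chromosome {label!r} is not an autosome (1-22)")
    return c


@dataclass
class CnvCall:
    """One called deletion or duplication segment in one sample.

    ``start``/``end`` are internal 0-based half-open coordinates, so
    ``length`` equals the external 1-based inclusive span.
    """

    sample_id: str
    chrom: int
    start: int
    end: int
    cnv_type: str
    copy_number: int
    num_probes: int
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"chrom {self.chrom} not an autosome")
        if not self.start < self.end:
            raise ValueError(f"start {self.start} must be < end {self.end}")
        if self.copy_number == 2:
            raise ValueError("copy number 2 is not a CNV")
        if not 0 <= self.copy_number <= 4:
            raise ValueError(f"copy number {self.copy_number} outside 0-4")
        expected = DEL if self.copy_number < 2 else DUP
        if self.cnv_type != expected:
            raise ValueError(
                f"cnv_type {self.cnv_type} inconsistent with cn={self.copy_number}"
            )
        if self.num_probes < 1:
            raise ValueError("num_probes must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SampleRecord:
    """One study participant with array-quality metrics."""

    sample_id: str
    phenotype: str  # "case" | "control"
    country: str  # "NO" | "SE"
    sex: str  # "M" | "F"
    lrr_sd: float
    baf_drift: float
    wf: float
    num_cnvs: int = 0
    autoantibody_21oh: str | None = None

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control"):
            raise ValueError(f"phenotype {self.phenotype!r} not case/control")
        if self.lrr_sd < 0 or self.baf_drift < 0:
            raise ValueError("lrr_sd and baf_drift must be >= 0")
        if self.num_cnvs < 0:
            raise ValueError("num_cnvs must be >= 0")


@dataclass
class GenomicInterval:
    """A labelled interval in internal 0-based half-open coordinates."""

    chrom: int
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start {self.start} must be < end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


# --- PennCNV rawcnv dialect -------------------------------------------------

_REGION_RE = re.compile(r"^(?:chr)?([0-9XYMT]+):(\d+)-(\d+)$", re.IGNORECASE)
_STATE_RE = re.compile(r"^state(\d+),cn=(\d+)$")


def _parse_rawcnv_line(line: str, lineno: int, strict: bool) -> CnvCall | None:
    tokens = line.split()
    if len(tokens) < 5:
        raise FormatError(f"line {lineno}: expected >=5 fields, got {len(tokens)}")
    m = _REGION_RE.match(tokens[0])
    if not m:
        raise FormatError(f"line {lineno}: malformed region {tokens[0]!r}")
    chrom_label, start1, end1 = m.group(1), int(m.group(2)), int(m.group(3))
    try:
        chrom = normalize_chrom(chrom_label)
    except FormatError:
        if strict:
            raise FormatError(f"line {lineno}: non-autosomal chromosome {chrom_label!r}")
        return None
    if not tokens[1].startswith("numsnp="):
        raise FormatError(f"line {lineno}: expected numsnp=, got {tokens[1]!r}")
    num_probes = int(tokens[1][len("numsnp="):])
    if not tokens[2].startswith("length="):
        raise FormatError(f"line {lineno}: expected length=, got {tokens[2]!r}")
    declared_length = int(tokens[2][len("length="):].replace(",", ""))
    sm = _STATE_RE.match(tokens[3])
    if not sm:
        raise FormatError(f"line {lineno}: malformed state/cn token {tokens[3]!r}")
    cn = int(sm.group(2))
    if cn == 2:
        raise FormatError(f"line {lineno}: cn=2 is not a CNV call")
    sample_id = tokens[4]
    confidence = None
    for tok in tokens[5:]:
        if tok.startswith("conf="):
            confidence = float(tok[len("conf="):])
    if declared_length != end1 - start1 + 1:
        warnings.warn(
            f"line {lineno}: declared length={declared_length} disagrees with "
            f"coordinates ({end1 - start1 + 1}); trusting coordinates",
            stacklevel=3,
        )
    return CnvCall(
        sample_id=sample_id,
        chrom=chrom,
        start=start1 - 1,
        end=end1,
        cnv_type=DEL if cn < 2 else DUP,
        copy_number=cn,
        num_probes=num_probes,
        confidence=confidence,
    )


def read_rawcnv(path: str | Path, strict: bool = False) -> list[CnvCall]:
    """Parse a PennCNV rawcnv file into a list of :class:`CnvCall`.

    ``strict=False`` silently drops non-autosomal lines; ``strict=True``
    raises.  Thousands separators in ``length=`` are accepted and ignored;
    a declared length that disagrees with the coordinates triggers a warning
    and the coordinates win.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            call = _parse_rawcnv_line(line, lineno, strict)
            if call is not None:
                calls.append(call)
    return calls


def write_rawcnv(calls: list[CnvCall], path: str | Path) -> None:
    """Write calls as PennCNV-dialect lines (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for c in calls:
            state = 2 if c.copy_number < 2 else 5  # HMM state label, informational
            fields = [
                f"chr{c.chrom}:{c.start + 1}-{c.end}",
                f"numsnp={c.num_probes}",
                f"length={c.length:,}",
                f"state{state},cn={c.copy_number}",
                c.sample_id,
            ]
            if c.confidence is not None:
                fields.append(f"conf={c.confidence:g}")
            fh.write(" ".join(fields) + "\n")


# --- BED and tabular inputs -------------------------------------------------

def read_regions_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 (0-based half-open, same as internal) regions.

    Non-autosomal lines are dropped; output is sorted by (chrom, start).
    Overlapping intervals are preserved as-is (unions are computed downstream).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: BED needs >=3 columns")
            try:
                chrom = normalize_chrom(parts[0])
            except FormatError:
                continue
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"line {lineno}: start {start} >= end {end}")
            label = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(chrom, start, end, label))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


_SAMPLE_COLUMNS = ("sample_id", "phenotype", "country", "sex", "lrr_sd", "baf_drift", "wf")


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the TSV sample table (header required, one row per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample table missing mandatory column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s): {dupes[:5]}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                phenotype=row.phenotype,
                country=row.country,
                sex=row.sex,
                lrr_sd=float(row.lrr_sd),
                baf_drift=float(row.baf_drift),
                wf=float(row.wf),
                num_cnvs=int(getattr(row, "num_cnvs", 0) or 0),
                autoantibody_21oh=getattr(row, "autoantibody_21oh", None),
            )
        )
    return records


def read_gene_table(path: str | Path) -> list[GenomicInterval]:
    """Read the gene annotation TSV (symbol, chrom, tx_start, tx_end).

    Transcript coordinates follow the UCSC convention (0-based half-open),
    matching the internal convention directly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    required = ("symbol", "chrom", "tx_start", "tx_end")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"gene table missing mandatory column(s): {missing}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            chrom = normalize_chrom(row.chrom)
        except FormatError:
            continue
        genes.append(GenomicInterval(chrom, int(row.tx_start), int(row.tx_end), row.symbol))
    return genes


def read_gene_set(path: str | Path, known_symbols: set[str] | None = None) -> set[str]:
    """Read a plain-text gene set (one symbol per line).

    Symbols absent from ``known_symbols`` (if supplied) are reported with a
    warning but kept — annotation gaps are not fatal.
    """
    symbols = set()
    with open(path) as fh:
        for raw in fh:
            s = raw.strip()
            if s and not s.startswith("#"):
                symbols.add(s)
    if known_symbols is not None:
        unknown = symbols - known_symbols
        if unknown:
            warnings.warn(
                f"{len(unknown)} gene-set symbol(s) absent from the gene table "
                f"(e.g. {sorted(unknown)[:3]})",
                stacklevel=2,
            )
    return symbols


def read_prs_table(path: str | Path) -> dict[str, float]:
    """Read the PRS TSV (sample_id, prs_z) into a sample -> Z-score map."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "prs_z"):
        if col not in df.columns:
            raise FormatError(f"PRS table missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in PRS table")
    return dict(zip(df["sample_id"], df["prs_z"].astype(float)))


def write_sample_table(samples: list[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "phenotype": s.phenotype,
                "country": s.country,
                "sex": s.sex,
                "lrr_sd": s.lrr_sd,
                "baf_drift": s.baf_drift,
                "wf": s.wf,
                "num_cnvs": s.num_cnvs,
            }
            for s in samples
        ]
    )
    df.to_csv(path, sep="\t", index=False)
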