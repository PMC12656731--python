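"""Reading and validating coding sequences, metadata and host codon tables.

The module owns the package's three external input formats — CDS FASTA,
isolate metadata TSV, and Kazusa/CUTG-style codon usage tables — plus
deterministic TSV report writing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .genetic_code import ALL_CODONS, STOP_CODONS, to_dna

REGIONS = ("polyprotein", "MP", "CP", "other")

_VALID = frozenset("ACGT")


class CubkitError(Exception):
    """Base class for package errors."""


class FastaError(CubkitError):
    """Malformed or empty FASTA input."""


class CdsValidationError(CubkitError):
    """A record violates a coding-sequence invariant (frame, stops)."""


class MetadataError(CubkitError):
    """Metadata table missing, inconsistent, or failing to cover sequences."""


class HostTableError(CubkitError):
    """Host codon usage table malformed or incomplete."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame CDS with isolate/host/region labels.

    ``seq`` holds only A/C/G/T, its length is a multiple of 3, it carries
    no stop codon (a single terminal stop is trimmed at validation), and
    ``dropped_codons`` records how many codons were removed because they
    contained ambiguity codes.
    """

    id: str
    seq: str
    accession: str | None = None
    host: str | None = None
    region: str = "other"
    dropped_codons: int = 0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            object.__setattr__(self, "region", "other")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codons(self) -> tuple[str, ...]:
        s = self.seq
        return tuple(s[i : i + 3] for i in range(0, len(s), 3))


@dataclass(frozen=True)
class HostCodonUsageTable:
    """Codon usage weights (counts or per-thousand) for one host organism."""

    host: str
    weights: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ALL_CODONS if c not in self.weights]
        if missing:
            raise HostTableError(
                f"host table {self.host!r} missing codons: {', '.join(missing)}"
            )
        bad = [c for c, w in self.weights.items() if w < 0]
        if bad:
            raise HostTableError(
                f"host table {self.host!r} has negative weights for: {', '.join(bad)}"
            )


def read_fasta(
    path: str | Path,
    on_duplicate: Literal["error", "first"] = "error",
) -> list[CodingSequence]:
    """Read raw FASTA records, preserving ids and order; U is normalized to T.

    Records are *not* validated as CDSs here; pass them through
    :func:`validate_cds`. Duplicate ids raise by default (``on_duplicate``
    = ``"first"`` keeps the first occurrence) — never a silent overwrite.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FastaError(f"{path}: not FASTA (first non-blank character is not '>')")
    records: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaError(f"{path}: record with empty id")
        if rec.id in seen:
            if on_duplicate == "first":
                continue
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(CodingSequence(id=rec.id, seq=seq))
    if not records:
        raise FastaError(f"{path}: no records parsed")
    return records


def validate_cds(
    record: CodingSequence,
    policy: Literal["drop_ambiguous", "reject_record"] = "drop_ambiguous",
) -> CodingSequence:
    """Enforce the CDS invariants on a raw record.

    Check order: (1) length must be a positive multiple of 3; (2) codons
    containing non-ACGT characters are dropped (default) or the record is
    rejected, with the dropped count recorded; (3) a single terminal stop
    is trimmed; any other stop codon is a frame error reported with its
    1-based codon index.
    """
    seq = record.seq.upper().replace("U", "T")
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise CdsValidationError(
            f"{record.id}: length {len(seq)} nt is not a positive multiple of 3"
        )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    kept: list[str] = []
    dropped = 0
    last_idx = len(codons) - 1
    for idx, codon in enumerate(codons):
        if not _VALID.issuperset(codon):
            if policy == "reject_record":
                raise CdsValidationError(
                    f"{record.id}: ambiguity code in codon {idx + 1} ({codon})"
                )
            dropped += 1
            continue
        if codon in STOP_CODONS:
            if idx == last_idx:
                continue  # terminal stop: trimmed, never counted
            raise CdsValidationError(
                f"{record.id}: internal stop codon {codon} at codon {idx + 1}"
            )
        kept.append(codon)
    if not kept:
        raise CdsValidationError(f"{record.id}: no intact codons remain")
    return replace(
        record,
        seq="".join(kept),
        dropped_codons=record.dropped_codons + dropped,
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the isolate metadata TSV (columns: id, accession, host, recombinant).

    ``recombinant`` is parsed as boolean; extra columns pass through.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"id", "host", "recombinant"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: metadata missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise MetadataError(f"{path}: duplicate metadata ids {dups}")
    df = df.copy()
    df["recombinant"] = (
        df["recombinant"].str.strip().str.lower().map(
            {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
        )
    )
    if df["recombinant"].isna().any():
        raise MetadataError(f"{path}: unparseable values in 'recombinant' column")
    return df


def filter_nonrecombinant(meta: pd.DataFrame) -> pd.DataFrame:
    """Drop rows flagged recombinant; downstream analyses use only the rest."""
    return meta.loc[~meta["recombinant"]].reset_index(drop=True)


def join_metadata(
    seqs: Iterable[CodingSequence], meta: pd.DataFrame
) -> list[CodingSequence]:
    """Attach host (and accession) labels to sequences by isolate id.

    The join is total: any sequence whose id has no metadata row aborts
    the pipeline, because grouped analyses would otherwise silently lose
    records.
    """
    rows = meta.set_index("id")
    out: list[CodingSequence] = []
    orphans: list[str] = []
    for s in seqs:
        if s.id not in rows.index:
            orphans.append(s.id)
            continue
        row = rows.loc[s.id]
        out.append(
            replace(
                s,
                host=str(row["host"]),
                accession=str(row["accession"]) if "accession" in row else s.accession,
            )
        )
    if orphans:
        raise MetadataError(f"sequences without metadata rows: {orphans}")
    return out


_KAZUSA_ENTRY = re.compile(
    r"([ACGTUacgtu]{3})\s+([0-9]*\.?[0-9]+)(?:\s*\(\s*([0-9]+)\s*\))?"
)


def read_host_table(
    path: str | Path,
    host: str | None = None,
    format: Literal["auto", "kazusa", "tsv"] = "auto",
) -> HostCodonUsageTable:
    """Parse a host codon usage table.

    Accepts the Kazusa/CUTG text layout — whitespace-separated
    ``codon frequency(count)`` or ``codon frequency count`` entries, several
    per line, RNA or DNA spelled — or a two-column codon/weight TSV.
    All 64 codons must be present exactly once.
    """
    path = Path(path)
    name = host or path.stem
    text = path.read_text()
    weights: dict[str, float] = {}

    def put(codon: str, w: float) -> None:
        c = to_dna(codon)
        if c in weights:
            raise HostTableError(f"{path}: codon {c} appears more than once")
        if w < 0:
            raise HostTableError(f"{path}: negative weight for codon {c}")
        weights[c] = w

    if format == "tsv" or (format == "auto" and "\t" in text and "(" not in text):
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("codon"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise HostTableError(f"{path}: malformed TSV line {line!r}")
            put(parts[0].strip(), float(parts[1]))
    else:
        for m in _KAZUSA_ENTRY.finditer(text):
            put(m.group(1), float(m.group(2)))
    missing = [c for c in ALL_CODONS if c not in weights]
    if missing:
        raise HostTableError(f"{path}: missing codons: {', '.join(missing)}")
    return HostCodonUsageTable(host=name, weights=weights)


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    float_decimals: int = 4,
) -> list[Path]:
    """Write result tables as TSVs with a deterministic layout.

    Column order is taken from each DataFrame as-is; floats are fixed at
    ``float_decimals`` decimals so repeated runs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        dest = out_dir / f"{name}.tsv"
        tables[name].to_csv(
            dest, sep="\t", index=False, float_format=f"%.{float_decimals}f"
        )
        written.append(dest)
    return written


def write_fasta(seqs: Sequence[CodingSequence], path: str | Path) -> Path:
    """Write sequences as FASTA (ids verbatim, 70-column wrap)."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), 70):
                fh.write(s.seq[i : i + 70] + "\n")
    return path
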