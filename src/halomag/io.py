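"""Readers, writers and shared sequence containers.

All tables are plain tab-separated text with a single header line; genomic
coordinates are 0-based half-open everywhere. FASTA/FASTQ parsing is
delegated to Biopython.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_PROTEIN = set("BZXUJO*")


class ValidationError(ValueError):
    """Raised when an input file or parameter fails validation."""


@dataclass(frozen=True)
class Genome:
    """A genome (MAG) as an ordered set of contigs."""

    id: str
    contigs: tuple[tuple[str, str], ...]

    @property
    def length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def sequence(self) -> str:
        """Concatenation of all contigs (analysis steps never span contigs)."""
        return "".join(seq for _, seq in self.contigs)

    @staticmethod
    def from_sequence(genome_id: str, sequence: str) -> "Genome":
        return Genome(genome_id, ((genome_id, sequence.upper()),))


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _check_alphabet(seq: str, allowed: set[str], name: str) -> None:
    bad = set(seq) - allowed
    if bad:
        raise ValidationError(
            f"record {name!r} contains characters outside the allowed "
            f"alphabet: {sorted(bad)}"
        )


def read_fasta(path: str | Path, alphabet: set[str] | None = None) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased sequence), ...]``.

    Record order is preserved; duplicate ids and (optionally) out-of-alphabet
    characters raise :class:`ValidationError`. Multi-line wraps and CRLF line
    endings are handled by the underlying parser.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet is not None:
            _check_alphabet(seq, alphabet, rec.id)
        records.append((rec.id, seq))
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def read_genome_fasta(path: str | Path, genome_id: str | None = None) -> Genome:
    path = Path(path)
    records = read_fasta(path, alphabet=DNA_ALPHABET)
    return Genome(genome_id or path.stem, tuple(records))


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    """Write reads with a constant Phred-33 quality of 'I' (Q40)."""
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def read_table(
    path: str | Path,
    schema: Mapping[str, Callable],
    required: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a tab-separated table with one header line into typed rows.

    ``schema`` maps column name -> type converter. Columns listed in
    ``required`` (default: all schema columns) must be present; unknown
    columns are preserved untouched. Cell-level parse failures report the
    1-based data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", skip_blank_lines=True)
    required = list(schema) if required is None else list(required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    for col, conv in schema.items():
        if col not in df.columns:
            continue
        parsed = []
        for row_no, raw in enumerate(df[col], start=1):
            try:
                parsed.append(conv(raw))
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: cannot parse {col}={raw!r} at data row {row_no}"
                ) from exc
        df[col] = parsed
    return df


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None,
                float_format: str = "%.4f") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        if comment:
            for line in comment.splitlines():
                handle.write(f"# {line}\n")
        df.to_csv(handle, sep="\t", index=False, float_format=float_format)


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed from one global seed."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2**31)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (synthetic demo driven).

    Defaults reproduce the study's stated parameters: 95% identity over a
    minimum of 50 aligned bases for read recruitment, 10^7-read subsample,
    1020-b ANI fragments with the 95/69 decision thresholds, and 0.2-width
    pI bins.
    """

    out_dir: Path
    seed: int = 1
    # synthetic community (demo scale)
    n_genomes: int = 5
    genome_length: int = 20_000
    gc: float = 0.5
    read_length: int = 150
    n_reads_per_dataset: int = 1_000
    error_rate: float = 0.0
    datasets: dict = field(default_factory=lambda: {
        "B1Sed10": "high", "T1Sed": "high",
        "CSSed10": "moderate", "CSSed11": "moderate", "T3Sed10": "moderate",
    })
    # analysis parameters
    min_identity: float = 0.95
    min_aligned: int = 50
    subsample_n: int = 10_000_000
    fragment_length: int = 1020
    bin_width: float = 0.2
    top_n: int = 10
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "out_dir" not in raw:
            raise ValidationError("run config must set out_dir")
        raw["out_dir"] = Path(raw["out_dir"])
        cfg = RunConfig(**raw)
        for group in cfg.datasets.values():
            if group not in ("high", "moderate"):
                raise ValidationError(
                    f"unknown salinity group {group!r}: expected 'high' or 'moderate'"
                )
        return cfg
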