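"""Synthetic data with known ground truth for every downstream stage.

The generators emulate the study conditions rather than real sequencing
artefacts: genomes are i.i.d. base draws at a target GC, divergent genome
pairs apply independent per-site substitutions (uniform over the three
alternative bases) and rare geometric-length indels, community read sets
draw each read's source genome with probability proportional to copy-number
weight x genome length (so length-normalized RPKG recovery is the natural
test), proteomes draw residues i.i.d. with a controlled Asp+Glu fraction,
and KO annotation tables realize a planned completeness fraction per
genome x pathway. Every generator is a pure function of its explicit
integer seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Genome, Read, ValidationError
from .pathways import PathwayDef

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_NON_ACIDIC = [aa for aa in _AA if aa not in "DE"]


# ---------------------------------------------------------------- genomes

@dataclass(frozen=True)
class GenomeSpec:
    id: str
    length: int
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValidationError("genome length must be positive")
        if not (0.0 <= self.gc <= 1.0):
            raise ValidationError("gc must lie in [0, 1]")


@dataclass(frozen=True)
class DivergenceTruth:
    parent_id: str
    child_id: str
    sub_rate: float
    indel_rate: float
    realized_subs: int
    realized_indels: int


def generate_genome(spec: GenomeSpec) -> Genome:
    """Random genome with i.i.d. bases at the target GC fraction."""
    rng = np.random.default_rng(spec.seed)
    at = (1.0 - spec.gc) / 2.0
    gcp = spec.gc / 2.0
    codes = rng.choice(4, size=spec.length, p=[at, gcp, gcp, at])  # A C G T
    seq = _BASES[codes].tobytes().decode("ascii")
    return Genome.from_sequence(spec.id, seq)


def mutate_genome(genome: Genome, sub_rate: float, indel_rate: float, seed: int,
                  indel_mean: float = 2.0, child_id: str | None = None
                  ) -> tuple[Genome, DivergenceTruth]:
    """Divergent copy of a genome with recorded mutation truth.

    Each site is substituted independently with probability ``sub_rate``
    (uniformly to one of the three other bases). Indel events occur per
    site at ``indel_rate`` with geometric lengths (mean ``indel_mean``),
    insertions and deletions equiprobable. With ``indel_rate`` 0 the
    per-site alignment is the identity, so mutation truth doubles as a
    coordinate-preserving alignment for ANI recovery tests.
    """
    if not (0.0 <= sub_rate < 1.0 and 0.0 <= indel_rate < 1.0):
        raise ValidationError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8).copy()
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    codes = code[arr]
    mask = rng.random(codes.size) < sub_rate
    n_subs = int(mask.sum())
    offsets = rng.integers(1, 4, size=n_subs)
    codes[mask] = (codes[mask] + offsets) % 4
    seq = _BASES[codes].tobytes().decode("ascii")
    n_indels = 0
    if indel_rate > 0.0:
        events = np.flatnonzero(rng.random(codes.size) < indel_rate)
        n_indels = int(events.size)
        pieces: list[str] = []
        cursor = 0
        geo_p = 1.0 / indel_mean
        for pos in events:
            if pos < cursor:  # swallowed by a previous deletion
                n_indels -= 1
                continue
            pieces.append(seq[cursor:pos])
            length = int(rng.geometric(geo_p))
            if rng.random() < 0.5:  # insertion
                ins = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
                pieces.append(seq[pos] + ins)
                cursor = pos + 1
            else:  # deletion
                cursor = pos + length
        pieces.append(seq[cursor:])
        seq = "".join(pieces)
        if not seq:
            raise ValidationError("mutation deleted the whole genome")
    child = child_id or f"{genome.id}_mut"
    truth = DivergenceTruth(genome.id, child, sub_rate, indel_rate, n_subs, n_indels)
    return Genome.from_sequence(child, seq), truth


# ------------------------------------------------------------------ reads

@dataclass(frozen=True)
class CommunitySpec:
    members: tuple[tuple[str, float], ...]  # (genome id, copy-number weight)
    n_reads: int
    read_length: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reads < 0:
            raise ValidationError("n_reads must be >= 0")
        if not self.members or sum(w for _, w in self.members) <= 0:
            raise ValidationError("community weights must sum to > 0")
        if any(w < 0 for _, w in self.members):
            raise ValidationError("weights must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValidationError("error_rate must lie in [0, 1)")


def simulate_reads(spec: CommunitySpec, genomes: dict[str, Genome]
                   ) -> tuple[list[Read], pd.DataFrame]:
    """Community read set plus a truth table (read -> source, start, strand).

    Source genomes are drawn with probability proportional to copy-number
    weight x genome length; start positions are uniform; strands are
    uniform; each base is substituted independently with ``error_rate``.
    Coordinates refer to the forward strand, 0-based half-open.
    """
    missing = [gid for gid, _ in spec.members if gid not in genomes]
    if missing:
        raise ValidationError(f"community member(s) not resolvable: {missing}")
    for gid, _ in spec.members:
        if spec.read_length > genomes[gid].length:
            raise ValidationError(
                f"read_length {spec.read_length} exceeds genome {gid!r} length")
    rng = np.random.default_rng(spec.seed)
    ids = [gid for gid, _ in spec.members]
    weights = np.array([w * genomes[gid].length for gid, w in spec.members], dtype=float)
    probs = weights / weights.sum()
    sources = rng.choice(len(ids), size=spec.n_reads, p=probs)
    strands = rng.random(spec.n_reads) < 0.5
    reads: list[Read] = []
    truth_rows = []
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(spec.n_reads):
        gid = ids[int(sources[i])]
        seq_full = genomes[gid].sequence
        start = int(rng.integers(0, len(seq_full) - spec.read_length + 1))
        seq = seq_full[start:start + spec.read_length]
        strand = "-" if strands[i] else "+"
        if strand == "-":
            seq = seq.translate(comp)[::-1]
        if spec.error_rate > 0.0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            code = np.zeros(256, dtype=np.uint8)
            for bi, b in enumerate("ACGT"):
                code[ord(b)] = bi
            codes = code[arr]
            mask = rng.random(codes.size) < spec.error_rate
            codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
            seq = _BASES[codes].tobytes().decode("ascii")
        read_id = f"read_{i:07d}"
        reads.append(Read(read_id, seq))
        truth_rows.append({"read": read_id, "source": gid, "start": start,
                           "strand": strand})
    truth = pd.DataFrame(truth_rows, columns=["read", "source", "start", "strand"])
    return reads, truth


# -------------------------------------------------------------- proteomes

@dataclass(frozen=True)
class ProteomeSpec:
    n_proteins: int
    length_range: tuple[int, int] = (100, 500)
    acidic_enrichment: float = 0.1   # target Asp+Glu residue fraction
    seed: int = 0
    id: str = "proteome"

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError("bad length_range")
        if not (0.0 <= self.acidic_enrichment <= 1.0):
            raise ValidationError("acidic_enrichment must lie in [0, 1]")


def generate_proteome(spec: ProteomeSpec) -> list[tuple[str, str]]:
    """Proteome with i.i.d. residues at a controlled Asp+Glu fraction."""
    rng = np.random.default_rng(spec.seed)
    probs = np.empty(20)
    for i, aa in enumerate(_AA):
        if aa in "DE":
            probs[i] = spec.acidic_enrichment / 2.0
        else:
            probs[i] = (1.0 - spec.acidic_enrichment) / 18.0
    alphabet = np.frombuffer(_AA.encode("ascii"), dtype=np.uint8)
    lo, hi = spec.length_range
    proteome = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        codes = rng.choice(20, size=length, p=probs)
        seq = alphabet[codes].tobytes().decode("ascii")
        proteome.append((f"{spec.id}_p{i:05d}", seq))
    return proteome


# ------------------------------------------------------------ annotations

def generate_annotation_table(genome_ids: list[str], defs: dict[str, PathwayDef],
                              plan: dict[tuple[str, str], float], seed: int = 0
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KO annotation rows realizing a planned completeness per genome x pathway.

    ``plan`` maps (genome id, pathway id) -> fraction of that pathway's
    required KOs to include; the included subset of size
    ``floor(fraction * |required|)`` is chosen uniformly. Returns the
    annotation table (genome, gene, ko) and a truth table with planned and
    realized fractions.
    """
    for (gid, pid), frac in plan.items():
        if pid not in defs:
            raise ValidationError(f"unknown pathway id {pid!r} in plan")
        if gid not in genome_ids:
            raise ValidationError(f"unknown genome id {gid!r} in plan")
        if not (0.0 <= frac <= 1.0):
            raise ValidationError("plan fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    gene_counter = {gid: 0 for gid in genome_ids}
    for gid in genome_ids:
        for pid in sorted(defs):
            frac = plan.get((gid, pid))
            if frac is None:
                continue
            required = sorted(defs[pid].required)
            n_take = int(np.floor(frac * len(required)))
            chosen = sorted(rng.choice(len(required), size=n_take, replace=False))
            for idx in chosen:
                gene_counter[gid] += 1
                rows.append({"genome": gid,
                             "gene": f"{gid}_g{gene_counter[gid]:05d}",
                             "ko": required[idx]})
            truth_rows.append({"genome": gid, "pathway": pid, "planned": frac,
                               "included": n_take,
                               "realized": n_take / len(required)})
    table = pd.DataFrame(rows, columns=["genome", "gene", "ko"])
    truth = pd.DataFrame(truth_rows,
                         columns=["genome", "pathway", "planned", "included", "realized"])
    return table, truth


# ---------------------------------------------------------- quality table

def generate_quality_table(tier_counts: dict[str, int], seed: int = 0) -> pd.DataFrame:
    """Bin quality table with a known number of MAGs per tier.

    ``tier_counts`` maps tier name (near_complete / medium / fail) to the
    number of bins to draw inside that tier's completeness/contamination
    region.
    """
    ranges = {
        "near_complete": ((90.0, 100.0), (0.0, 5.0)),
        "medium": ((50.0, 89.9), (0.0, 9.9)),
        "fail": ((5.0, 49.0), (0.0, 40.0)),
    }
    unknown = set(tier_counts) - set(ranges)
    if unknown:
        raise ValidationError(f"unknown tier(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for tier in ("near_complete", "medium", "fail"):
        (clo, chi), (rlo, rhi) = ranges[tier]
        for _ in range(tier_counts.get(tier, 0)):
            i += 1
            rows.append({
                "mag": f"bin_{i:04d}",
                "completeness": round(float(rng.uniform(clo, chi)), 2),
                "contamination": round(float(rng.uniform(rlo, rhi)), 2),
            })
    return pd.DataFrame(rows, columns=["mag", "completeness", "contamination"])
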