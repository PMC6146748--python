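"""Read recruitment onto MAGs and RPKG abundance estimation.

Reads (treated as singletons) are subsampled without replacement, aligned
to each MAG with the seed-and-extend aligner, and counted as recruited when
the best alignment reaches >= 95% identity over >= 50 aligned bases
(defaults). Abundance is expressed as RPKG: reads recruited per kilobase of
MAG per gigabase of mapped reads. The denominator is, per dataset, the
total bases of reads mapped to any MAG (``denominator="mapped"``); a
``"sampled"`` alternative divides by the total bases of the subsampled read
set instead.

Two mapping modes are provided: the default maps every read independently
onto each MAG; ``competitive`` assigns each read only to its best-scoring
MAG (ties broken by lexicographic MAG id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import AlignParams, align_query, kmer_index
from .io import Genome, Read, ValidationError


@dataclass(frozen=True)
class RecruitmentParams:
    min_identity: float = 0.95        # fraction of aligned columns matching
    min_aligned: int = 50             # minimum aligned bases
    subsample_n: int = 10_000_000
    seed: int = 0
    mode: str = "independent"         # or "competitive"
    denominator: str = "mapped"       # or "sampled"
    align: AlignParams = field(default_factory=lambda: AlignParams(
        min_band=8, seed_stride=4, max_candidates=3))

    def __post_init__(self):
        if not (0.0 < self.min_identity <= 1.0):
            raise ValidationError("min_identity must be in (0, 1]")
        if self.min_aligned < 1:
            raise ValidationError("min_aligned must be >= 1")
        if self.mode not in ("independent", "competitive"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.denominator not in ("mapped", "sampled"):
            raise ValidationError(f"unknown denominator {self.denominator!r}")


@dataclass
class RecruitResult:
    """Per-MAG recruitment outcome, with per-read best-hit statistics."""

    mag_id: str
    count: int
    base_count: int
    scores: np.ndarray          # best alignment score per read (0 = no hit)
    identities: np.ndarray      # percent identity of the best hit
    aligned: np.ndarray         # aligned columns of the best hit
    spans: np.ndarray           # read bases covered by the best hit


@dataclass
class AbundanceProfile:
    """Recruited counts and RPKG per (MAG, dataset)."""

    table: pd.DataFrame         # columns: dataset, mag, reads, bases, rpkg
    mag_lengths: dict
    dataset_mapped_bases: dict
    flags: set = field(default_factory=set)

    def rpkg_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="mag", columns="dataset", values="rpkg")

    def rpkg(self, mag: str, dataset: str) -> float:
        row = self.table[(self.table["mag"] == mag) & (self.table["dataset"] == dataset)]
        return float(row["rpkg"].iloc[0])


def subsample_reads(reads: list[Read], n: int, seed: int) -> list[Read]:
    """Uniform sample of ``n`` reads without replacement (order preserved)."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    if n >= len(reads):
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


def _best_hits(reads: list[Read], mag: Genome, params: RecruitmentParams) -> RecruitResult:
    seq = mag.sequence
    index = kmer_index(seq, params.align.k)
    n = len(reads)
    scores = np.zeros(n, dtype=np.int64)
    idents = np.zeros(n, dtype=np.float64)
    aligned = np.zeros(n, dtype=np.int64)
    spans = np.zeros(n, dtype=np.int64)
    for i, read in enumerate(reads):
        hit = align_query(read.sequence, seq, index, params.align)
        if hit is None:
            continue
        scores[i] = hit.score
        idents[i] = hit.identity
        aligned[i] = hit.aligned_length
        spans[i] = hit.query_span
    return RecruitResult(mag.id, 0, 0, scores, idents, aligned, spans)


def _passes(res: RecruitResult, params: RecruitmentParams) -> np.ndarray:
    return (res.aligned >= params.min_aligned) & (res.identities >= 100.0 * params.min_identity)


def recruit_reads(reads: list[Read], mag: Genome,
                  params: RecruitmentParams = RecruitmentParams()) -> RecruitResult:
    """Recruit reads onto one MAG; each read is counted at most once."""
    if not reads or mag.length == 0:
        raise ValidationError("reads and MAG must be non-empty")
    res = _best_hits(reads, mag, params)
    ok = _passes(res, params)
    res.count = int(ok.sum())
    res.base_count = int(res.spans[ok].sum())
    return res


def compute_rpkg(count: int, total_mapped_bases: int, mag_length: int) -> float:
    """Reads per kilobase of MAG per gigabase of mapped reads."""
    if mag_length <= 0:
        raise ValidationError("mag_length must be positive")
    if total_mapped_bases < 0:
        raise ValidationError("total_mapped_bases must be >= 0")
    if total_mapped_bases == 0:
        return 0.0
    return count / (mag_length / 1e3) / (total_mapped_bases / 1e9)


def profile_community(read_sets: dict[str, list[Read]], mags: list[Genome],
                      params: RecruitmentParams = RecruitmentParams()) -> AbundanceProfile:
    """Subsample, recruit and normalize every (dataset, MAG) pair."""
    if not read_sets or not mags:
        raise ValidationError("need at least one dataset and one MAG")
    mag_ids = [m.id for m in mags]
    if len(mag_ids) != len(set(mag_ids)):
        raise ValidationError("duplicate MAG ids")
    rows = []
    flags: set = set()
    mag_lengths = {m.id: m.length for m in mags}
    mapped_bases: dict[str, int] = {}
    for dataset, reads in sorted(read_sets.items()):
        sample = subsample_reads(reads, params.subsample_n, params.seed)
        results = {m.id: _best_hits(sample, m, params) for m in mags}
        passing = {mid: _passes(res, params) for mid, res in results.items()}
        if params.mode == "competitive" and mags:
            # keep each read only for its best-scoring passing MAG
            ordered = sorted(results)  # lexicographic tie-break
            score_stack = np.stack([
                np.where(passing[mid], results[mid].scores, -1) for mid in ordered
            ])
            winner = np.argmax(score_stack, axis=0)  # first max wins ties
            any_pass = score_stack.max(axis=0) >= 0
            for k, mid in enumerate(ordered):
                passing[mid] = any_pass & (winner == k)
        if params.denominator == "sampled":
            denom = sum(len(r) for r in sample)
        else:
            span_stack = np.stack([
                np.where(passing[mid], results[mid].spans, 0) for mid in sorted(results)
            ]) if results else np.zeros((1, 0), dtype=np.int64)
            denom = int(span_stack.max(axis=0).sum())
        mapped_bases[dataset] = denom
        if denom == 0:
            flags.add(f"no_mapped_bases:{dataset}")
        for mag in mags:
            ok = passing[mag.id]
            count = int(ok.sum())
            bases = int(results[mag.id].spans[ok].sum())
            rows.append({
                "dataset": dataset, "mag": mag.id, "reads": count,
                "bases": bases,
                "rpkg": compute_rpkg(count, denom, mag.length),
            })
    table = pd.DataFrame(rows, columns=["dataset", "mag", "reads", "bases", "rpkg"])
    return AbundanceProfile(table, mag_lengths, mapped_bases, flags)
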