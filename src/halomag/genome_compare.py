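"""Fragment-based ANI / conserved-DNA genome comparison and species calls.

A query genome is cut into consecutive non-overlapping 1020-b fragments
(within contigs; terminal remainders shorter than 100 b are dropped), each
fragment is aligned to the subject genome with the seed-and-extend aligner,
and two statistics are derived:

* ANI — the unweighted mean identity over *qualifying* fragments, where a
  fragment qualifies if its best alignment covers >= 70% of the fragment at
  >= 30% identity.
* conserved DNA (conDNA) — the fraction of the query genome covered by
  fragment alignments at >= 90% identity.

The species decision matrix maps (ANI, conDNA) to an integer code:
1 = same species (ANI >= 95, conDNA >= 69), -1 = might be same species
(ANI >= 95, conDNA < 69), 0 = different species otherwise. The quadrant
(ANI < 95, conDNA >= 69) is not addressed by the published rule; it is
mapped to 0 and flagged ``unspecified_quadrant``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import AlignmentHit, AlignParams, align_query, kmer_index
from .io import Genome, ValidationError

DEFAULT_FRAGMENT_LENGTH = 1020
MIN_FRAGMENT_LENGTH = 100
ANI_SAME_SPECIES = 95.0
CONDNA_SAME_SPECIES = 69.0

SAME_SPECIES = 1
MIGHT_BE_SAME = -1
DIFFERENT_SPECIES = 0


@dataclass(frozen=True)
class Fragment:
    """A query window: contig id plus 0-based half-open genomic span."""

    contig: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AniParams:
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    min_identity_qualify: float = 30.0   # % identity for a fragment to qualify
    min_coverage_qualify: float = 0.7    # fragment coverage to qualify
    condna_identity: float = 90.0        # % identity for conserved-DNA credit
    align: AlignParams = field(default_factory=AlignParams)


@dataclass
class AniResult:
    query_id: str
    subject_id: str
    ani: float
    condna: float
    n_fragments: int
    n_qualifying: int
    decision: int
    flags: frozenset[str] = frozenset()


def fragment_genome(genome: Genome, fragment_length: int = DEFAULT_FRAGMENT_LENGTH) -> list[Fragment]:
    """Cut a genome into consecutive windows, never spanning a contig.

    The terminal remainder of each contig is kept only when it is at least
    100 b long.
    """
    if fragment_length < MIN_FRAGMENT_LENGTH:
        raise ValidationError(f"fragment_length must be >= {MIN_FRAGMENT_LENGTH}")
    if genome.length == 0:
        raise ValidationError(f"genome {genome.id!r} is empty")
    fragments: list[Fragment] = []
    for contig_id, seq in genome.contigs:
        for start in range(0, len(seq), fragment_length):
            end = min(start + fragment_length, len(seq))
            if end - start >= MIN_FRAGMENT_LENGTH:
                fragments.append(Fragment(contig_id, start, end, seq[start:end]))
    return fragments


def align_fragment(fragment: Fragment | str, subject: Genome | str,
                   params: AlignParams = AlignParams(),
                   index: dict | None = None) -> AlignmentHit | None:
    """Best alignment of one fragment against a subject genome, or ``None``."""
    seq = fragment.sequence if isinstance(fragment, Fragment) else fragment
    subject_seq = subject.sequence if isinstance(subject, Genome) else subject
    if index is None:
        index = kmer_index(subject_seq, params.k)
    return align_query(seq, subject_seq, index, params)


def _compare(query: Genome, subject: Genome, params: AniParams) -> AniResult:
    fragments = fragment_genome(query, params.fragment_length)
    subject_seq = subject.sequence
    index = kmer_index(subject_seq, params.align.k)
    identities: list[float] = []
    conserved_bases = 0
    for frag in fragments:
        hit = align_query(frag.sequence, subject_seq, index, params.align)
        if hit is None:
            continue
        if (hit.identity >= params.min_identity_qualify
                and hit.coverage(len(frag)) >= params.min_coverage_qualify):
            identities.append(hit.identity)
        if hit.identity >= params.condna_identity:
            conserved_bases += hit.query_span
    flags: set[str] = set()
    if identities:
        ani = float(np.mean(identities))
    else:
        ani = 0.0
        flags.add("no_homology")
    condna = min(100.0, 100.0 * conserved_bases / query.length)
    decision, dflags = classify_pair(ani, condna)
    result = AniResult(
        query_id=query.id, subject_id=subject.id, ani=ani, condna=condna,
        n_fragments=len(fragments), n_qualifying=len(identities),
        decision=decision, flags=frozenset(flags | dflags),
    )
    return result


def compute_ani(query: Genome, subject: Genome, params: AniParams = AniParams()) -> AniResult:
    """Fragment-based ANI of ``query`` against ``subject`` (directional)."""
    if query.length == 0 or subject.length == 0:
        raise ValidationError("both genomes must be non-empty")
    return _compare(query, subject, params)


def compute_conserved_dna(query: Genome, subject: Genome,
                          params: AniParams = AniParams()) -> float:
    """Conserved-DNA percentage of ``query`` relative to ``subject``."""
    return compute_ani(query, subject, params).condna


def classify_pair(ani: float, condna: float) -> tuple[int, frozenset[str]]:
    """Species decision code for an (ANI %, conDNA %) pair.

    1 = same species, -1 = might be same species, 0 = different species.
    """
    if not (0.0 <= ani <= 100.0 and 0.0 <= condna <= 100.0):
        raise ValidationError("ani and condna must lie in [0, 100]")
    if ani >= ANI_SAME_SPECIES:
        if condna >= CONDNA_SAME_SPECIES:
            return SAME_SPECIES, frozenset()
        return MIGHT_BE_SAME, frozenset()
    if condna >= CONDNA_SAME_SPECIES:
        return DIFFERENT_SPECIES, frozenset({"unspecified_quadrant"})
    return DIFFERENT_SPECIES, frozenset()


def pairwise_matrices(genomes: list[Genome], params: AniParams = AniParams()
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ANI, conDNA and decision matrices over all ordered genome pairs.

    Fragment-based ANI is directional, so (A, B) and (B, A) are computed
    separately; the diagonal is (100, 100, 1) by definition.
    """
    ids = [g.id for g in genomes]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate genome ids")
    if len(genomes) < 2:
        raise ValidationError("need at least two genomes")
    ani = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    condna = ani.copy()
    decision = pd.DataFrame(np.zeros((len(ids), len(ids)), dtype=int), index=ids, columns=ids)
    for query in genomes:
        for subject in genomes:
            if query.id == subject.id:
                ani.loc[query.id, subject.id] = 100.0
                condna.loc[query.id, subject.id] = 100.0
                decision.loc[query.id, subject.id] = SAME_SPECIES
                continue
            res = _compare(query, subject, params)
            ani.loc[query.id, subject.id] = res.ani
            condna.loc[query.id, subject.id] = res.condna
            decision.loc[query.id, subject.id] = res.decision
    return ani, condna, decision
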