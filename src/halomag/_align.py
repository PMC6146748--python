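"""Seed-and-extend nucleotide aligner.

Exact k-mer seeds locate candidate diagonals; a banded affine-gap local
(Smith-Waterman) dynamic program extends around each candidate and the
highest-scoring alignment over both strands is returned. Scoring is fixed
and documented so results are reproducible bit-for-bit: match +2, mismatch
-3, a gap of length n costs gap_open + n * gap_ext (defaults -5 and -2).
Identity is matches / aligned columns, so gap columns count against
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A,C,G,T -> 0..3; anything else 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Aligner tuning knobs (defaults chosen for 1020-b genome fragments)."""

    k: int = 15                 # seed k-mer length
    band_frac: float = 0.2      # band half-width as a fraction of query length
    min_band: int = 16
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_ext: int = -2
    seed_stride: int = 1        # sample every Nth query k-mer when seeding
    max_candidates: int = 4     # diagonal clusters to extend per strand

    def band(self, query_length: int) -> int:
        return max(self.min_band, int(self.band_frac * query_length))


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a query against a subject."""

    score: int
    strand: str                 # '+' or '-'
    identity: float             # percent of aligned columns matching
    aligned_length: int         # aligned columns (matches+mismatches+gaps)
    matches: int
    query_start: int            # on the forward query, 0-based half-open
    query_end: int
    subject_start: int
    subject_end: int

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    def coverage(self, query_length: int) -> float:
        return self.query_span / query_length


@njit(cache=False)
def _banded_sw(q, s, lo_off, hi_off, match, mismatch, gap_open, gap_ext):
    """Banded local affine-gap DP restricted to lo_off <= j - i <= hi_off.

    Returns (score, qend, send, qstart, sstart, matches, aligned_columns)
    with 0-based half-open spans on q and s.
    """
    m = q.shape[0]
    n = s.shape[0]
    NEG = np.int32(-(10 ** 9))
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in query (consumes s)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in subject (consumes q)
    # H pointer: 0 stop, 1 diag, 2 from E, 3 from F; E/F pointer: 1 = opened here
    ph = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pe = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pf = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        jlo = i + lo_off
        if jlo < 1:
            jlo = 1
        jhi = i + hi_off
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            e_open = H[i, j - 1] + gap_open + gap_ext
            e_ext = E[i, j - 1] + gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                pe[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] + gap_open + gap_ext
            f_ext = F[i - 1, j] + gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                pf[i, j] = 1
            else:
                F[i, j] = f_ext
            qa = q[i - 1]
            sub = match if (qa == s[j - 1] and qa < 4) else mismatch
            d = H[i - 1, j - 1] + sub
            h = np.int32(0)
            p = np.uint8(0)
            if d > h:
                h = d
                p = np.uint8(1)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            H[i, j] = h
            ph[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    matches = 0
    cols = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ph[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                qa = q[i - 1]
                if qa == s[j - 1] and qa < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = pe[i, j]
            cols += 1
            j -= 1
            if opened == 1:
                state = 0
        else:
            opened = pf[i, j]
            cols += 1
            i -= 1
            if opened == 1:
                state = 0
    return int(best), bi, bj, i, j, matches, cols


def kmer_index(seq: str, k: int) -> dict:
    """Exact k-mer -> positions index of a subject sequence."""
    index: dict = {}
    for pos in range(len(seq) - k + 1):
        kmer = seq[pos:pos + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(pos)
    return index


def _candidate_diagonals(query: str, index: dict, params: AlignParams, band: int) -> list[int]:
    """Cluster seed diagonals (subject_pos - query_pos) and rank by support."""
    width = max(1, band // 2)
    votes: dict[int, int] = {}
    sums: dict[int, int] = {}
    k = params.k
    for qpos in range(0, len(query) - k + 1, params.seed_stride):
        hits = index.get(query[qpos:qpos + k])
        if not hits:
            continue
        for spos in hits:
            diag = spos - qpos
            key = diag // width
            votes[key] = votes.get(key, 0) + 1
            sums[key] = sums.get(key, 0) + diag
    ranked = sorted(votes, key=lambda key: (-votes[key], key))
    return [sums[key] // votes[key] for key in ranked[: params.max_candidates]]


def _extend(query: str, subject: str, diag: int, band: int,
            params: AlignParams) -> Optional[tuple]:
    m = len(query)
    lo = max(0, diag - band)
    hi = min(len(subject), diag + m + band)
    window = subject[lo:hi]
    off = diag - lo
    res = _banded_sw(
        encode(query), encode(window), off - band, off + band,
        params.match, params.mismatch, params.gap_open, params.gap_ext,
    )
    if res[0] <= 0:
        return None
    score, qend, send, qstart, sstart, matches, cols = res
    return score, qstart, qend, lo + sstart, lo + send, matches, cols


def align_query(query: str, subject: str, index: dict,
                params: AlignParams = AlignParams()) -> Optional[AlignmentHit]:
    """Best local alignment of ``query`` against ``subject`` on either strand.

    ``index`` must be ``kmer_index(subject, params.k)``. Returns ``None``
    when no seed yields a positive-scoring extension.
    """
    band = params.band(len(query))
    best: Optional[AlignmentHit] = None
    for strand, oriented in (("+", query), ("-", revcomp(query))):
        for diag in _candidate_diagonals(oriented, index, params, band):
            ext = _extend(oriented, subject, diag, band, params)
            if ext is None:
                continue
            score, qs, qe, ss, se, matches, cols = ext
            if best is not None and score <= best.score:
                continue
            if strand == "-":  # map span back onto the forward query
                qs, qe = len(query) - qe, len(query) - qs
            best = AlignmentHit(
                score=score, strand=strand,
                identity=100.0 * matches / cols if cols else 0.0,
                aligned_length=cols, matches=matches,
                query_start=qs, query_end=qe,
                subject_start=ss, subject_end=se,
            )
    return best


def read_align_params(read_length: int) -> AlignParams:
    """Aligner defaults scaled down for short-read recruitment."""
    return AlignParams(min_band=8, seed_stride=4, max_candidates=3)
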