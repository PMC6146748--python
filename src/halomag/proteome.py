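"""Isoelectric-point profiling of MAG proteomes.

Halophiles following the "salt-in" osmotic strategy keep molar K+
concentrations in the cytoplasm and compensate with acidic proteomes
(excess Asp/Glu). The predicted per-protein isoelectric point (pI) makes
this visible: an acid-shifted pI histogram with a pronounced peak below
pH 5.5 marks a salt-in proteome.

The net charge of a protein at a given pH is the standard
Henderson-Hasselbalch sum over its ionizable groups::

    Z(pH) = sum_basic  n_g / (1 + 10^(pH - pKa_g))
          - sum_acidic n_g / (1 + 10^(pKa_g - pH))

with basic groups {N-terminus, Lys, Arg, His} and acidic groups
{C-terminus, Asp, Glu, Cys, Tyr}; terminal groups count once per protein.
Z is strictly decreasing in pH, so the pI (Z = 0) is found by bisection.
Histograms use half-open bins of width 0.2 spanning [0, 14].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

from .io import PROTEIN_ALPHABET, ValidationError

BASIC_RESIDUES = ("K", "R", "H")
ACIDIC_RESIDUES = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PkaSet:
    """pKa of every ionizable group; immutable once constructed."""

    n_term: float
    c_term: float
    K: float
    R: float
    H: float
    D: float
    E: float
    C: float
    Y: float

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not (0.0 < value < 14.0):
                raise ValidationError(f"pKa {name}={value} outside (0, 14)")


def load_pka(path=None) -> PkaSet:
    """Load a pKa set from JSON (defaults to the packaged file)."""
    if path is None:
        raw = json.loads(resources.files("halomag.data").joinpath("pka.json").read_text())
    else:
        with open(path) as handle:
            raw = json.load(handle)
    raw.pop("comment", None)
    return PkaSet(**raw)


DEFAULT_PKA = load_pka()


@dataclass
class PiProfile:
    proteome_id: str
    bin_edges: np.ndarray       # multiples of bin_width spanning [0, 14]
    counts: np.ndarray          # half-open bins [left, right)
    n_proteins: int
    median_pi: float
    acidic_fraction: float      # share of proteins with pI < 5.5
    pis: np.ndarray             # unbinned per-protein pI values


def residue_counts(sequence: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for aa in sequence:
        counts[aa] = counts.get(aa, 0) + 1
    return counts


def net_charge(counts: Mapping[str, int], pH: float, pka: PkaSet = DEFAULT_PKA,
               n_term: int = 1, c_term: int = 1) -> float:
    """Net charge (elementary charges) at a given pH from residue counts."""
    if any(v < 0 for v in counts.values()) or n_term < 0 or c_term < 0:
        raise ValidationError("residue counts must be non-negative")
    charge = n_term / (1.0 + 10.0 ** (pH - pka.n_term))
    charge -= c_term / (1.0 + 10.0 ** (pka.c_term - pH))
    for res in BASIC_RESIDUES:
        n = counts.get(res, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - getattr(pka, res)))
    for res in ACIDIC_RESIDUES:
        n = counts.get(res, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (getattr(pka, res) - pH))
    return charge


def compute_pi(sequence: str, pka: PkaSet = DEFAULT_PKA,
               tolerance: float = 1e-4, on_unknown: str = "error") -> float:
    """Isoelectric point of a protein by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique
    and bracketed. The bracket is narrowed until the returned value (rounded
    to 6 decimals) satisfies |net_charge| < ``tolerance`` even for proteins
    with many ionizable groups. ``on_unknown`` controls handling of
    non-standard residue letters: ``"error"`` (default) raises, ``"skip"``
    drops them with no contribution to charge.
    """
    if not sequence:
        raise ValidationError("empty protein sequence")
    unknown = set(sequence) - PROTEIN_ALPHABET
    if unknown:
        if on_unknown == "error":
            raise ValidationError(f"unknown residue letter(s): {sorted(unknown)}")
        sequence = "".join(aa for aa in sequence if aa in PROTEIN_ALPHABET)
        if not sequence:
            raise ValidationError("no standard residues left after skipping")
    counts = residue_counts(sequence)
    lo, hi = 0.0, 14.0
    mid = 7.0
    # a 1e-9 bracket keeps |charge| < tolerance after 6-decimal rounding
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        z = net_charge(counts, mid, pka)
        if z > 0:
            lo = mid
        elif z < 0:
            hi = mid
        else:
            break
    return round(mid, 6)


def pi_profile(proteome: Iterable[tuple[str, str]] | Mapping[str, str],
               bin_width: float = 0.2, proteome_id: str = "",
               pka: PkaSet = DEFAULT_PKA, acidic_cutoff: float = 5.5) -> PiProfile:
    """pI histogram of a proteome over half-open bins of ``bin_width``."""
    if isinstance(proteome, Mapping):
        proteome = list(proteome.items())
    else:
        proteome = list(proteome)
    if not proteome:
        raise ValidationError("empty proteome")
    n_bins = round(14.0 / bin_width)
    if abs(n_bins * bin_width - 14.0) > 1e-9:
        raise ValidationError("bin_width must divide the [0, 14] span")
    pis = np.array([compute_pi(seq, pka) for _, seq in proteome])
    counts = np.zeros(n_bins, dtype=int)
    idx = np.minimum((pis / bin_width).astype(int), n_bins - 1)
    np.add.at(counts, idx, 1)
    return PiProfile(
        proteome_id=proteome_id,
        bin_edges=np.round(np.arange(n_bins + 1) * bin_width, 10),
        counts=counts,
        n_proteins=len(proteome),
        median_pi=float(np.median(pis)),
        acidic_fraction=float(np.mean(pis < acidic_cutoff)),
        pis=pis,
    )


def acidic_peak(profile: PiProfile, modal_cutoff: float = 5.5,
                min_acidic_fraction: float = 0.5) -> tuple[bool, dict]:
    """Call a pronounced acidic peak in a pI profile.

    True iff the modal bin center lies below ``modal_cutoff`` and at least
    ``min_acidic_fraction`` of proteins have pI below the acidic cutoff.
    Ties for the modal bin resolve to the most acidic (lowest) bin.
    """
    mode_idx = int(np.argmax(profile.counts))
    mode_center = float(0.5 * (profile.bin_edges[mode_idx] + profile.bin_edges[mode_idx + 1]))
    call = mode_center < modal_cutoff and profile.acidic_fraction >= min_acidic_fraction
    return call, {
        "modal_bin_center": mode_center,
        "acidic_fraction": profile.acidic_fraction,
        "modal_cutoff": modal_cutoff,
        "min_acidic_fraction": min_acidic_fraction,
    }
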