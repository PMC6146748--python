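"""MAG quality tiering and ecological summaries.

* quality tiers — near-complete (completeness >= 90%, contamination < 5%),
  medium (>= 50%, < 10%), else fail. The strict '<' boundary follows the
  MIMAG-style wording; the comparison is configurable.
* salinity preference score — with M MAGs, the MAG with the largest summed
  RPKG over high-salinity datasets receives positive rank score M (down to
  1), the largest sum over moderate-salinity datasets receives -M (up to
  -1); the two are added. Scores therefore sum to zero over the catalog and
  MAGs recruiting preferentially from high salinity end up positive.
* species aggregation — RPKG values of MAGs judged the same (or possibly
  the same) species are averaged per dataset; clusters are connected
  components over decision codes {1, -1}.
* phylogeny eligibility — a MAG enters the concatenated ribosomal-protein
  tree only when at least 8 of the 16 marker proteins are present at
  >= 80 aa.

All ranking ties break deterministically: descending value, then ascending
MAG id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import connected_components

from .io import ValidationError
from .recruitment import AbundanceProfile

NEAR_COMPLETE = "near_complete"
MEDIUM = "medium"
FAIL = "fail"

#: the 16 single-copy ribosomal proteins used for concatenated phylogeny
RIBOSOMAL_MARKERS = (
    "L2", "L3", "L4", "L5", "L6", "L14", "L15", "L16",
    "L18", "L22", "L24", "S3", "S8", "S10", "S17", "S19",
)


@dataclass(frozen=True)
class QualityRecord:
    mag_id: str
    completeness: float
    contamination: float
    tier: str


@dataclass(frozen=True)
class PreferenceScore:
    mag_id: str
    high_sum: float
    moderate_sum: float
    pos_rank_score: int
    neg_rank_score: int
    salinity_score: int


def quality_tier(completeness: float, contamination: float,
                 strict_boundaries: bool = True) -> str:
    """Tier a bin from its completeness/contamination estimates."""
    if not (0.0 <= completeness <= 100.0):
        raise ValidationError("completeness must lie in [0, 100]")
    if contamination < 0.0:
        raise ValidationError("contamination must be >= 0")
    below = (lambda x, t: x < t) if strict_boundaries else (lambda x, t: x <= t)
    if completeness >= 90.0 and below(contamination, 5.0):
        return NEAR_COMPLETE
    if completeness >= 50.0 and below(contamination, 10.0):
        return MEDIUM
    return FAIL


def tier_table(quality: pd.DataFrame, strict_boundaries: bool = True) -> pd.DataFrame:
    """Annotate a (mag, completeness, contamination) table with tiers."""
    out = quality.copy()
    out["tier"] = [
        quality_tier(c, r, strict_boundaries)
        for c, r in zip(out["completeness"], out["contamination"])
    ]
    return out


def _rank_scores(sums: pd.Series) -> pd.Series:
    """Rank 1 (largest) -> score M ... rank M -> 1; ties by ascending id."""
    ordered_ids = sorted(sums.index, key=lambda mag: (-sums[mag], mag))
    m = len(ordered_ids)
    return pd.Series({mag: m - rank for rank, mag in enumerate(ordered_ids)})


def salinity_preference_scores(profile: AbundanceProfile | pd.DataFrame,
                               groups: dict[str, str]) -> pd.DataFrame:
    """Rank-based salinity preference score per MAG.

    ``groups`` maps every dataset id to ``"high"`` or ``"moderate"``.
    Returns a table sorted by descending salinity score.
    """
    table = profile.table if isinstance(profile, AbundanceProfile) else profile
    datasets = set(table["dataset"])
    unlabeled = datasets - set(groups)
    if unlabeled:
        raise ValidationError(f"datasets without a salinity group: {sorted(unlabeled)}")
    bad = {g for g in groups.values() if g not in ("high", "moderate")}
    if bad:
        raise ValidationError(f"unknown salinity group(s): {sorted(bad)}")
    high = [d for d in datasets if groups[d] == "high"]
    moderate = [d for d in datasets if groups[d] == "moderate"]
    if not high or not moderate:
        raise ValidationError("both salinity groups must be non-empty")
    pivot = table.pivot(index="mag", columns="dataset", values="rpkg").fillna(0.0)
    high_sum = pivot[high].sum(axis=1)
    moderate_sum = pivot[moderate].sum(axis=1)
    pos = _rank_scores(high_sum)
    neg = -_rank_scores(moderate_sum)
    out = pd.DataFrame({
        "mag": pivot.index,
        "high_sum": high_sum.values,
        "moderate_sum": moderate_sum.values,
        "pos_rank_score": pos[pivot.index].values,
        "neg_rank_score": neg[pivot.index].values,
    })
    out["salinity_score"] = out["pos_rank_score"] + out["neg_rank_score"]
    out = out.sort_values(["salinity_score", "mag"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    return out


def top_n_abundant(profile: AbundanceProfile | pd.DataFrame, dataset: str,
                   n: int = 10) -> list[str]:
    """MAG ids sorted by RPKG in one dataset, descending, truncated to n."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    table = profile.table if isinstance(profile, AbundanceProfile) else profile
    sub = table[table["dataset"] == dataset]
    if sub.empty:
        raise ValidationError(f"unknown dataset {dataset!r}")
    ordered = sorted(zip(sub["mag"], sub["rpkg"]), key=lambda kv: (-kv[1], kv[0]))
    return [mag for mag, _ in ordered[:n]]


def aggregate_species(profile: AbundanceProfile | pd.DataFrame,
                      decision: pd.DataFrame, mags: list[str],
                      same_species_codes: tuple[int, ...] = (1, -1)) -> pd.DataFrame:
    """Average RPKG within species clusters of the given MAG subset.

    Clusters are connected components of the graph joining MAG pairs whose
    decision code is in ``same_species_codes`` (transitive closure). Returns
    one row per (cluster, dataset) with the arithmetic-mean RPKG; clusters
    are labelled by their sorted member ids joined with '|'.
    """
    table = profile.table if isinstance(profile, AbundanceProfile) else profile
    missing = [m for m in mags if m not in decision.index or m not in decision.columns]
    if missing:
        raise ValidationError(f"decision matrix does not cover MAG(s): {missing}")
    mags = sorted(set(mags))
    n = len(mags)
    adj = lil_matrix((n, n), dtype=np.int8)
    for i, a in enumerate(mags):
        for j, b in enumerate(mags):
            if i < j and int(decision.loc[a, b]) in same_species_codes:
                adj[i, j] = 1
    _, labels = connected_components(adj.tocsr(), directed=False)
    clusters: dict[int, list[str]] = {}
    for mag, lab in zip(mags, labels):
        clusters.setdefault(int(lab), []).append(mag)
    sub = table[table["mag"].isin(mags)]
    rows = []
    for members in sorted(clusters.values(), key=lambda ms: ms[0]):
        label = "|".join(sorted(members))
        cluster_rows = sub[sub["mag"].isin(members)]
        means = cluster_rows.groupby("dataset")["rpkg"].mean()
        for dataset, value in means.items():
            rows.append({"cluster": label, "dataset": dataset,
                         "n_members": len(members), "rpkg": float(value)})
    return pd.DataFrame(rows, columns=["cluster", "dataset", "n_members", "rpkg"])


def phylogeny_eligibility(markers: pd.DataFrame, min_length: int = 80,
                          min_markers: int = 8) -> set[str]:
    """MAGs with >= ``min_markers`` distinct ribosomal markers >= ``min_length`` aa.

    ``markers`` has columns (mag, marker, length_aa); duplicate copies of a
    marker within one MAG count once. Marker ids must come from the fixed
    16-protein panel.
    """
    unknown = set(markers["marker"]) - set(RIBOSOMAL_MARKERS)
    if unknown:
        raise ValidationError(f"unknown ribosomal marker id(s): {sorted(unknown)}")
    long_enough = markers[markers["length_aa"] >= min_length]
    counts = long_enough.groupby("mag")["marker"].nunique()
    return set(counts[counts >= min_markers].index)
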