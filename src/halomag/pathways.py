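"""KO-marker pathway screening over genome annotation tables.

Annotations are (genome, gene, KO[, length_aa]) rows, as produced by KEGG
annotation services. A pathway is defined by a required (and optional) KO
set; completeness is the fraction of required KOs present and a pathway is
called present when completeness reaches the definition's threshold. Calls
are presence-based: KO copy number never matters. A marker screen with a
product-length floor supports the acetyl-CoA synthase (acsB) analysis,
where only sequences of at least 500 aa are trusted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .io import ValidationError

KO_PATTERN = re.compile(r"^K\d{5}$")


@dataclass(frozen=True)
class PathwayDef:
    id: str
    name: str
    required: frozenset[str]
    optional: frozenset[str] = frozenset()
    presence_threshold: float = 1.0

    def __post_init__(self):
        if not self.required:
            raise ValidationError(f"pathway {self.id!r}: required KO set is empty")
        for ko in self.required | self.optional:
            if not KO_PATTERN.match(ko):
                raise ValidationError(f"pathway {self.id!r}: malformed KO id {ko!r}")
        if self.required & self.optional:
            raise ValidationError(
                f"pathway {self.id!r}: required and optional KO sets overlap")
        if not (0.0 < self.presence_threshold <= 1.0):
            raise ValidationError(f"pathway {self.id!r}: bad presence_threshold")


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene -> KO assignments of one genome, with optional product lengths."""

    genome_id: str
    table: pd.DataFrame = field(repr=False)  # columns: gene, ko[, length_aa]

    def __post_init__(self):
        genes = self.table["gene"]
        if genes.duplicated().any():
            dup = sorted(genes[genes.duplicated()].unique())
            raise ValidationError(f"{self.genome_id}: duplicate gene id(s) {dup[:5]}")
        bad = [ko for ko in self.table["ko"] if not KO_PATTERN.match(str(ko))]
        if bad:
            raise ValidationError(f"{self.genome_id}: malformed KO id(s) {sorted(set(bad))[:5]}")

    @property
    def kos(self) -> frozenset[str]:
        return frozenset(self.table["ko"])


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    pathway_id: str
    completeness: float
    present: bool
    missing: frozenset[str]


def load_pathway_defs(path: str | Path | None = None) -> dict[str, PathwayDef]:
    """Load pathway definitions from YAML (defaults to the packaged set)."""
    if path is None:
        text = resources.files("halomag.data").joinpath("pathways.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    defs: dict[str, PathwayDef] = {}
    for pid, body in raw["pathways"].items():
        if pid in defs:
            raise ValidationError(f"duplicate pathway id {pid!r}")
        defs[pid] = PathwayDef(
            id=pid,
            name=body.get("name", pid),
            required=frozenset(body["required"]),
            optional=frozenset(body.get("optional", ())),
            presence_threshold=float(body.get("presence_threshold", 1.0)),
        )
    return defs


def write_pathway_defs(defs: dict[str, PathwayDef], path: str | Path) -> None:
    payload = {"pathways": {
        pid: {
            "name": d.name,
            "required": sorted(d.required),
            "optional": sorted(d.optional),
            "presence_threshold": d.presence_threshold,
        } for pid, d in sorted(defs.items())
    }}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def score_pathway(annotation: GenomeAnnotation, pdef: PathwayDef) -> PathwayCall:
    """Completeness fraction and presence verdict for one genome x pathway."""
    found = annotation.kos & pdef.required
    completeness = len(found) / len(pdef.required)
    return PathwayCall(
        genome_id=annotation.genome_id,
        pathway_id=pdef.id,
        completeness=completeness,
        present=completeness >= pdef.presence_threshold,
        missing=pdef.required - found,
    )


def screen_marker(annotations: list[GenomeAnnotation], ko: str,
                  min_length: int = 0) -> list[str]:
    """Genomes with at least one gene hitting ``ko`` at product length
    >= ``min_length`` aa.

    Genes lacking length data are excluded from a length-screened query
    (with a warning); with ``min_length=0`` no length data is needed.
    """
    if min_length < 0:
        raise ValidationError("min_length must be >= 0")
    qualifying = []
    for ann in annotations:
        hits = ann.table[ann.table["ko"] == ko]
        if hits.empty:
            continue
        if min_length > 0:
            if "length_aa" not in hits.columns:
                warnings.warn(
                    f"{ann.genome_id}: no product lengths; all {ko} hits excluded "
                    f"from the {min_length}-aa screen")
                continue
            lengths = hits["length_aa"]
            if lengths.isna().any():
                warnings.warn(
                    f"{ann.genome_id}: {int(lengths.isna().sum())} {ko} hit(s) "
                    f"without length excluded from the {min_length}-aa screen")
            hits = hits[lengths.notna() & (lengths >= min_length)]
        if not hits.empty:
            qualifying.append(ann.genome_id)
    return qualifying


def summarize_functions(annotations: list[GenomeAnnotation],
                        defs: dict[str, PathwayDef]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome x pathway presence (0/1, with totals) and completeness matrices."""
    if not annotations or not defs:
        raise ValidationError("need at least one genome and one pathway definition")
    presence = pd.DataFrame(0, index=[a.genome_id for a in annotations],
                            columns=sorted(defs), dtype=int)
    completeness = pd.DataFrame(0.0, index=presence.index.copy(),
                                columns=presence.columns.copy(), dtype=float)
    for ann in annotations:
        for pid in sorted(defs):
            call = score_pathway(ann, defs[pid])
            presence.loc[ann.genome_id, pid] = int(call.present)
            completeness.loc[ann.genome_id, pid] = call.completeness
    presence["n_present"] = presence.sum(axis=1)
    presence.loc["n_genomes"] = presence.sum(axis=0)
    return presence, completeness


def split_annotations(table: pd.DataFrame) -> list[GenomeAnnotation]:
    """Split a combined (genome, gene, ko[, length_aa]) table per genome."""
    cols = [c for c in ("gene", "ko", "length_aa") if c in table.columns]
    return [
        GenomeAnnotation(genome_id=str(gid), table=sub[cols].reset_index(drop=True))
        for gid, sub in table.groupby("genome", sort=True)
    ]
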