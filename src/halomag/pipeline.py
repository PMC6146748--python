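"""End-to-end synthetic-demo pipeline.

Runs every post-binning analysis in method order on a generated community:
quality tiering -> read recruitment -> RPKG -> salinity preference scores
-> ANI/conDNA/decision matrices on the top-N abundant subset -> species-
averaged abundance -> pI profiles -> pathway presence matrix. All outputs
are tab-separated tables with a parameter header comment; tables are
byte-identical across reruns with the same configuration (the run log
carries the wall-clock timestamps).
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ecology import (aggregate_species, salinity_preference_scores, tier_table,
                      top_n_abundant)
from .genome_compare import AniParams, pairwise_matrices
from .io import Genome, RunConfig, derive_seed, write_table
from .pathways import load_pathway_defs, split_annotations, summarize_functions
from .proteome import acidic_peak, pi_profile
from .recruitment import RecruitmentParams, profile_community
from .synthetic import (CommunitySpec, GenomeSpec, ProteomeSpec,
                        generate_annotation_table, generate_genome,
                        generate_proteome, simulate_reads)

logger = logging.getLogger("halomag")


def _header(config: RunConfig, stage: str) -> str:
    return (f"halomag {__version__} | stage={stage} | seed={config.seed} | "
            f"min_identity={config.min_identity} min_aligned={config.min_aligned} "
            f"subsample_n={config.subsample_n} fragment_length={config.fragment_length} "
            f"bin_width={config.bin_width} top_n={config.top_n}")


def _matrix_frame(mat: pd.DataFrame) -> pd.DataFrame:
    out = mat.copy()
    out.insert(0, "mag", out.index)
    return out.reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full demo pipeline; returns the report bundle.

    The bundle maps table name -> DataFrame; every table is also written
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(levelname)s %(message)s")
    log_lines = [f"halomag {__version__} started "
                 f"{datetime.datetime.now().isoformat(timespec='seconds')}",
                 f"config: {config}"]
    bundle: dict[str, pd.DataFrame] = {}

    def emit(name: str, df: pd.DataFrame, stage: str) -> None:
        bundle[name] = df
        write_table(df, out / f"{name}.tsv", comment=_header(config, stage))
        log_lines.append(f"stage {stage}: wrote {name}.tsv ({len(df)} rows)")

    try:
        # ---- synthetic community ------------------------------------------
        stage = "simulate"
        rng = np.random.default_rng(derive_seed(config.seed, stage))
        genomes: list[Genome] = []
        for i in range(config.n_genomes):
            spec = GenomeSpec(id=f"MAG{i + 1:03d}", length=config.genome_length,
                              gc=config.gc, seed=derive_seed(config.seed, f"genome{i}"))
            genomes.append(generate_genome(spec))
        genome_map = {g.id: g for g in genomes}
        read_sets = {}
        for d_i, dataset in enumerate(sorted(config.datasets)):
            weights = tuple((g.id, float(w)) for g, w in
                            zip(genomes, rng.uniform(0.2, 5.0, size=len(genomes))))
            spec = CommunitySpec(members=weights, n_reads=config.n_reads_per_dataset,
                                 read_length=config.read_length,
                                 error_rate=config.error_rate,
                                 seed=derive_seed(config.seed, f"reads:{dataset}"))
            read_sets[dataset], _ = simulate_reads(spec, genome_map)

        # ---- quality tiering ----------------------------------------------
        stage = "quality"
        qrng = np.random.default_rng(derive_seed(config.seed, stage))
        quality = pd.DataFrame({
            "mag": [g.id for g in genomes],
            "completeness": np.round(qrng.uniform(50, 100, len(genomes)), 2),
            "contamination": np.round(qrng.uniform(0, 9, len(genomes)), 2),
        })
        emit("quality_tiers", tier_table(quality), stage)

        # ---- recruitment / RPKG -------------------------------------------
        stage = "recruit"
        rparams = RecruitmentParams(min_identity=config.min_identity,
                                    min_aligned=config.min_aligned,
                                    subsample_n=config.subsample_n,
                                    seed=derive_seed(config.seed, stage))
        profile = profile_community(read_sets, genomes, rparams)
        emit("abundance_rpkg", profile.table, stage)

        # ---- salinity preference ------------------------------------------
        stage = "salinity"
        scores = salinity_preference_scores(profile, config.datasets)
        emit("salinity_scores", scores, stage)

        # ---- ANI on the top-N subset --------------------------------------
        stage = "ani"
        subset = sorted({mag for dataset in read_sets
                         for mag in top_n_abundant(profile, dataset, config.top_n)})
        aparams = AniParams(fragment_length=config.fragment_length)
        ani, condna, decision = pairwise_matrices(
            [genome_map[m] for m in subset], aparams)
        emit("ani_matrix", _matrix_frame(ani), stage)
        emit("condna_matrix", _matrix_frame(condna), stage)
        emit("decision_matrix", _matrix_frame(decision), stage)

        # ---- species-averaged abundance -----------------------------------
        stage = "aggregate"
        emit("species_averaged", aggregate_species(profile, decision, subset), stage)

        # ---- pI profiles ---------------------------------------------------
        stage = "pi"
        rows = []
        for i, g in enumerate(genomes):
            enrichment = 0.4 if i % 2 == 0 else 0.1  # mix salt-in and neutral
            proteome = generate_proteome(ProteomeSpec(
                n_proteins=60, length_range=(120, 400),
                acidic_enrichment=enrichment, id=g.id,
                seed=derive_seed(config.seed, f"proteome:{g.id}")))
            prof = pi_profile(proteome, bin_width=config.bin_width, proteome_id=g.id)
            call, summary = acidic_peak(prof)
            rows.append({"mag": g.id, "n_proteins": prof.n_proteins,
                         "median_pi": round(prof.median_pi, 4),
                         "acidic_fraction": round(prof.acidic_fraction, 4),
                         "modal_bin_center": summary["modal_bin_center"],
                         "acidic_peak": int(call)})
        emit("pi_profiles", pd.DataFrame(rows), stage)

        # ---- pathway matrix ------------------------------------------------
        stage = "pathways"
        defs = load_pathway_defs()
        fractions = [1.0, 0.5, 0.0]
        plan = {(g.id, pid): fractions[(i + j) % 3]
                for i, g in enumerate(genomes)
                for j, pid in enumerate(sorted(defs))}
        annot, _ = generate_annotation_table([g.id for g in genomes], defs, plan,
                                             seed=derive_seed(config.seed, stage))
        presence, _ = summarize_functions(split_annotations(annot), defs)
        emit("pathway_presence", presence.reset_index(names="genome"), stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_lines.append(f"finished {datetime.datetime.now().isoformat(timespec='seconds')}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return bundle
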