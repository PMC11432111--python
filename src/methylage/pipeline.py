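"""End-to-end orchestration of the marker-discovery funnel.

Runs the stages in the order of the study design: differential expression
(p < 0.05 prefilter) -> PLS-DA -> VIP >= 1 discriminant transcripts;
differential methylation (p < 0.05) -> PLS-DA -> VIP >= 1 discriminant
windows; overlap through promoter/gene-body links; GO-BP enrichment of the
overlap set; 75%-rule interplay classification (opposite-trend set
retained); ancestor incidence; multifunction (>= 4 processes) filter;
regulatory-region filter -> final candidate biological-age markers.

Every stage writes a TSV, and the run log records seed, thresholds and
stage counts of the funnel.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_expression as dex
from . import diff_methylation as dme
from . import discriminant as disc
from . import enrichment as enr
from . import genome_annotation as ga
from . import integration as integ
from . import synthetic_data as synth

logger = logging.getLogger("methylage")


@dataclass
class PipelineConfig:
    """Thresholds, PLS-DA settings and input paths of one run."""

    # inputs (optional when running on an in-memory dataset)
    genome: str | None = None
    gff: str | None = None
    counts: str | None = None
    methylation: str | None = None
    sample_sheet: str | None = None
    ontology: str | None = None
    annotation: str | None = None
    # thresholds
    de_p: float = 0.05
    de_fdr: float = 0.05
    dm_p: float = 0.05
    vip: float = 1.0
    opposite_frac: float = 0.75
    min_functions: int = 4
    enrichment_fdr: float = 0.05
    ancestor_level: int = 2
    # PLS-DA settings
    n_components: int = 2
    n_folds: int = 7
    n_perm: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_p", "de_fdr", "dm_p", "opposite_frac", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.vip < 0 or self.min_functions < 0:
            raise ValueError("vip and min_functions must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


@dataclass
class PipelineReport:
    """All stage products plus the funnel counts."""

    config: PipelineConfig
    de_table: pd.DataFrame
    de_model: disc.PLSDAModel
    discriminant_de: pd.DataFrame
    dm_table: pd.DataFrame
    dm_model: disc.PLSDAModel
    discriminant_dm: pd.DataFrame
    overlap_records: list[integ.OverlapRecord]
    enriched_terms: pd.DataFrame
    ancestor_table: pd.DataFrame
    incidence: enr.IncidenceTable | None
    markers: list[enr.CandidateMarker]
    counts_funnel: dict[str, int] = field(default_factory=dict)
    correlation: dict[str, float] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_sample_sheet(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def transcript_lengths(gene_models: list[ga.GeneModel]) -> pd.Series:
    return pd.Series(
        {
            gm.transcript_id: sum(e - s for s, e in gm.exons)
            for gm in gene_models
        },
        name="length",
    )


def gene_symbol_map(gene_models: list[ga.GeneModel]) -> pd.Series:
    return pd.Series(
        {gm.transcript_id: gm.gene_symbol for gm in gene_models}, name="gene_symbol"
    )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    dataset: synth.SyntheticDataset | None = None,
) -> PipelineReport:
    """Execute the full funnel and write all intermediate tables.

    Inputs come either from ``dataset`` (in-memory synthetic experiment)
    or from the file paths in ``config``.  Any stage failure aborts with a
    stage-labelled error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")
    config.to_yaml(outdir / "effective_config.yaml")
    logger.info("thresholds: %s", {
        k: getattr(config, k)
        for k in ("de_p", "de_fdr", "dm_p", "vip", "opposite_frac",
                  "min_functions", "enrichment_fdr", "n_components",
                  "n_folds", "n_perm", "seed")
    })

    try:
        if dataset is not None:
            counts = dataset.counts
            meth = dataset.methylation
            groups = pd.Series(
                dataset.config.sample_sheet()["group"].to_numpy(),
                index=dataset.config.sample_sheet()["sample_id"],
            )
            gene_models = dataset.gene_models
            links = dataset.window_links
            annotation_df = dataset.annotation
            ontology_text = synth.mini_ontology_text()
        else:
            counts = _read_matrix(config.counts)
            meth = _read_matrix(config.methylation)
            groups = read_sample_sheet(config.sample_sheet)
            genome = ga.read_genome(config.genome)
            gene_models = ga.read_gff3(config.gff)
            windows = []
            for chrom, seq in genome.items():
                windows.extend(ga.make_windows(seq, chrom))
            islands = [
                isl
                for chrom, seq in genome.items()
                for isl in ga.detect_cpg_islands(seq, chrom)
            ]
            chrom_lengths = {c: len(s) for c, s in genome.items()}
            training = ga.build_training_sets(gene_models, islands, chrom_lengths)
            windows = ga.classify_windows(
                windows, gene_models, training, chrom_lengths
            )
            links = ga.window_links_frame(windows)
            annotation_df = pd.read_csv(
                config.annotation, sep="\t", header=None, names=["gene", "term"]
            )
            ontology_text = Path(config.ontology).read_text()
    except Exception as e:  # noqa: BLE001
        raise StageError("load_inputs", e) from e

    symbols = gene_symbol_map(gene_models)
    lengths = transcript_lengths(gene_models)

    # ---- stage 1: differential expression -------------------------------
    try:
        de_table = dex.wald_test_de(counts, groups)
        de_table.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        de_sig = de_table[de_table["pvalue"] < config.de_p]
        logger.info(
            "DE: %d transcripts at p<%.3g (%d at FDR<%.3g)",
            len(de_sig), config.de_p,
            int((de_table["fdr"] < config.de_fdr).sum()), config.de_fdr,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("diff_expression", e) from e

    # ---- stage 2: PLS-DA on DE-filtered expression ----------------------
    try:
        fpkm = dex.fpkm(counts, lengths)
        de_X = fpkm.loc[de_sig["transcript_id"]]
        de_model = disc.fit_validated_plsda(
            de_X, groups, config.n_components, config.n_folds,
            config.n_perm, config.seed,
        )
        de_selected = set(disc.select_vip(de_model, config.vip))
        discriminant_de = de_sig[de_sig["transcript_id"].isin(de_selected)]
        discriminant_de.to_csv(outdir / "discriminant_de.tsv", sep="\t", index=False)
        logger.info(
            "PLS-DA (RNA): R2Y=%.3f Q2=%.3f pR2Y=%.4g pQ2=%.4g, %d VIP>=%g",
            de_model.r2y, de_model.q2, de_model.perm_p_r2y,
            de_model.perm_p_q2, len(de_selected), config.vip,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("plsda_expression", e) from e

    # ---- stage 3: differential methylation ------------------------------
    try:
        rpkm = dme.rpkm(meth)
        dm_table = dme.t_test_dm(rpkm, groups)
        dm_table.to_csv(outdir / "dm_results.tsv", sep="\t", index=False)
        dm_sig = dm_table[dm_table["pvalue"] < config.dm_p]
        logger.info("DM: %d windows at p<%.3g", len(dm_sig), config.dm_p)
    except Exception as e:  # noqa: BLE001
        raise StageError("diff_methylation", e) from e

    # ---- stage 4: PLS-DA on DM-filtered methylation ---------------------
    try:
        dm_X = rpkm.loc[dm_sig["window"]]
        dm_model = disc.fit_validated_plsda(
            dm_X, groups, config.n_components, config.n_folds,
            config.n_perm, config.seed,
        )
        dm_selected = set(disc.select_vip(dm_model, config.vip))
        discriminant_dm = dm_sig[dm_sig["window"].isin(dm_selected)]
        discriminant_dm.to_csv(outdir / "discriminant_dm.tsv", sep="\t", index=False)
        logger.info(
            "PLS-DA (meth): R2Y=%.3f Q2=%.3f pR2Y=%.4g pQ2=%.4g, %d VIP>=%g",
            dm_model.r2y, dm_model.q2, dm_model.perm_p_r2y,
            dm_model.perm_p_q2, len(dm_selected), config.vip,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("plsda_methylation", e) from e

    # ---- stage 5: overlap -----------------------------------------------
    try:
        records = integ.overlap_de_dm(
            discriminant_de, discriminant_dm, links, symbols
        )
        logger.info("overlap: %d DE transcripts with discriminant DM windows",
                    len(records))
    except Exception as e:  # noqa: BLE001
        raise StageError("overlap", e) from e

    # ---- stage 6: enrichment of the overlap set -------------------------
    try:
        dag, names = _load_ontology_text(ontology_text)
        term_genes: dict[str, set[str]] = {}
        for r in annotation_df.itertuples(index=False):
            term_genes.setdefault(str(r.term), set()).add(str(r.gene))
        annotation = enr.GOAnnotation(dag, term_genes, names)
        background = set(symbols.loc[counts.index].astype(str))
        overlap_genes = {r.gene_symbol for r in records}
        enriched_all = enr.hypergeometric_enrichment(
            overlap_genes & background, background, annotation,
            config.enrichment_fdr,
        )
        enriched = (
            enriched_all[enriched_all["significant"]]
            if not enriched_all.empty
            else enriched_all
        )
        enriched_all.to_csv(outdir / "enriched_terms.tsv", sep="\t", index=False)
        logger.info("enrichment: %d terms at FDR<%.3g", len(enriched),
                    config.enrichment_fdr)
    except Exception as e:  # noqa: BLE001
        raise StageError("enrichment", e) from e

    # ---- stage 7: interplay classification ------------------------------
    try:
        integ.classify_records(records, config.opposite_frac)
        overlap_frame = integ.records_to_frame(records)
        overlap_frame.to_csv(outdir / "overlap_records.tsv", sep="\t", index=False)
        opposite = [r for r in records if r.interplay is integ.Interplay.OPPOSITE]
        correlation: dict[str, float] = {}
        try:
            r, p = integ.methylation_expression_correlation(
                records, integ.Interplay.OPPOSITE
            )
            correlation = {"pearson_r": r, "pearson_p": p}
            logger.info("opposite-set correlation: r=%.3f p=%.3g", r, p)
        except ValueError as ve:
            logger.warning("correlation not computed: %s", ve)
        logger.info("interplay: %s", {
            row["interplay"]: int(row["n_transcripts"])
            for _, row in integ.summarize_interplay(records).iterrows()
        })
    except Exception as e:  # noqa: BLE001
        raise StageError("interplay", e) from e

    # ---- stage 8: incidence + marker selection --------------------------
    try:
        opposite_genes = sorted({r.gene_symbol for r in opposite})
        gene_direction = pd.Series(
            {r.gene_symbol: r.de_direction for r in opposite}
        )
        gene_regulatory = pd.Series(
            {r.gene_symbol: r.has_regulatory_window for r in opposite}
        )
        if enriched.empty or not opposite_genes:
            incidence = None
            markers: list[enr.CandidateMarker] = []
        else:
            ancestors = enr.collapse_to_ancestors(
                enriched, dag, config.ancestor_level,
                gene_directions=gene_direction, term_names=names,
            )
            ancestors.to_csv(outdir / "ancestor_table.tsv", sep="\t", index=False)
            incidence = enr.build_incidence(
                ancestors, opposite_genes, gene_direction, gene_regulatory
            )
            incidence.membership.astype(int).to_csv(
                outdir / "incidence.tsv", sep="\t"
            )
            markers = enr.select_markers(
                incidence, config.min_functions, require_regulatory=True
            )
        marker_frame = pd.DataFrame(
            [dataclasses.asdict(m) for m in markers],
            columns=["gene_symbol", "direction", "n_functions", "regulatory"],
        )
        marker_frame.to_csv(outdir / "candidate_markers.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("marker_selection", e) from e

    multifunction = (
        enr.multifunction_genes(incidence, config.min_functions)
        if incidence is not None
        else []
    )
    funnel = {
        "de_significant": int(len(de_sig)),
        "de_discriminant": int(len(discriminant_de)),
        "dm_significant": int(len(dm_sig)),
        "dm_discriminant": int(len(discriminant_dm)),
        "overlap_transcripts": len(records),
        "opposite_transcripts": len(opposite),
        "opposite_genes": len(opposite_genes),
        "multifunction_genes": len(multifunction),
        "final_markers": len(markers),
    }
    logger.info("funnel: %s", funnel)
    pd.Series(funnel, name="count").rename_axis("stage").to_csv(
        outdir / "summary.tsv", sep="\t"
    )
    return PipelineReport(
        config=config,
        de_table=de_table,
        de_model=de_model,
        discriminant_de=discriminant_de,
        dm_table=dm_table,
        dm_model=dm_model,
        discriminant_dm=discriminant_dm,
        overlap_records=records,
        enriched_terms=enriched,
        ancestor_table=ancestors if incidence is not None else pd.DataFrame(),
        incidence=incidence,
        markers=markers,
        counts_funnel=funnel,
        correlation=correlation,
    )


def demo_tables(
    min_functions: int = 4,
) -> tuple[list[str], list[enr.CandidateMarker]]:
    """Reproduce the fixture funnel: multifunction filter then regulatory.

    Returns (multifunction gene list, final candidate markers) computed
    from the packaged process-incidence fixture.
    """
    incidence = synth.fixture_incidence()
    multi = enr.multifunction_genes(incidence, min_functions)
    markers = enr.select_markers(incidence, min_functions, require_regulatory=True)
    return multi, markers


def _load_ontology_text(text: str):
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".obo", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        return enr.load_obo(path)
    finally:
        Path(path).unlink(missing_ok=True)


def _setup_logging(logfile: Path) -> None:
    logger.setLevel(logging.INFO)
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    filehandler = logging.FileHandler(logfile, mode="w")
    # no timestamps in the file log: run outputs stay byte-reproducible
    filehandler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers = [stream, filehandler]
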