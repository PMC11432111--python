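"""Synthetic inputs with planted ground truth for the integrative pipeline.

Generates every input the marker-discovery pipeline needs: a toy genome
(FASTA) with embedded high-GC CpG islands and soft-masked repeats,
multi-exon gene models on both strands (GFF3), a transcripts x samples
negative-binomial count matrix, and a windows x samples methylated-read
count matrix for two groups of seven fish (one- vs three-year-old,
S1/S3).  The planted conditions mirror the study design the pipeline
emulates: most age-affected transcripts are down-regulated (75%), most
age-affected methylation windows are hypo-methylated in the older group
(58.5%), and a configurable set of genes carries regulatory-region
methylation changes opposing their expression change.

Also ships the packaged fixtures transcribed from the published summary
tables (functional process -> gene incidence; gene -> function count with
regulatory flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_annotation as ga
from .integration import Interplay

GROUPS = ("S1", "S3")

_PREAMBLE_BP = 10_000
_MIN_SLOT_BP = 9_000
_CGI_LENGTH = 400
_MASK_LENGTH = 500

# leaf annotation terms of the packaged mini ontology, keyed by the
# supra-category ancestors they collapse to
_LEAF_TERMS = (
    "TOY:0000100", "TOY:0000101", "TOY:0000102", "TOY:0000103",
    "TOY:0000104", "TOY:0000105", "TOY:0000106", "TOY:0000107",
    "TOY:0000108", "TOY:0000109",
)
# one leaf per distinct ancestor group, used to guarantee multifunction
_LEAF_SPREAD = (
    "TOY:0000100",  # system development
    "TOY:0000102",  # anatomical structure development
    "TOY:0000104",  # tissue development
    "TOY:0000105",  # nitrogen compound metabolic process
    "TOY:0000106",  # regulation of cellular / developmental process
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic two-age-group experiment.

    Defaults encode the emulated design: 7 fish per age class, ~75% of
    age-affected transcripts down-regulated, and 58.5% of age-affected
    methylation windows hypo-methylated in the older group.  Genome sizing,
    library-size range and NB dispersion are desk-scale conventions (the
    emulated design does not fix them).
    """

    seed: int = 0
    n_per_group: int = 7
    n_transcripts: int = 120
    n_chromosomes: int = 2
    genome_length_bp: int = 600_000          # per chromosome
    frac_de: float = 0.25
    frac_de_down: float = 0.75
    lfc_magnitude: float = 2.0
    lfc_jitter: float = 0.2
    # bulk (non-marker) age-affected transcripts span a range of effect
    # sizes, as in real ageing transcriptomes; planted markers sit at
    # lfc_magnitude, the top of this range
    de_lfc_low: float = 0.5
    de_lfc_high: float = 2.0
    nb_dispersion: float = 0.1
    frac_dm_windows: float = 0.05
    frac_dm_hypo: float = 0.585
    dm_lfc_magnitude: float = 2.0
    n_planted_opposite: int = 10
    n_planted_down_hypo: int = 8
    n_cgi_per_chromosome: int = 3
    n_mask_per_chromosome: int = 2
    gc_background: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "frac_de", "frac_de_down", "frac_dm_windows",
            "frac_dm_hypo", "gc_background",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_transcripts < 0 or self.n_chromosomes < 1:
            raise ValueError("invalid sizing")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{g}_{i + 1}" for g in GROUPS for i in range(self.n_per_group)
        ]

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_names,
                "group": [g for g in GROUPS for _ in range(self.n_per_group)],
            }
        )


@dataclass
class PlantedMarker:
    gene_symbol: str
    transcript_id: str
    interplay: Interplay
    expression_lfc: float
    methylation_sign: int          # +1 hyper, -1 hypo (S+3 vs S+1)
    window_keys: list[str]
    regulatory_window_keys: list[str]


@dataclass
class GroundTruth:
    """Planted effects of one synthetic dataset."""

    de_transcripts: dict[str, float] = field(default_factory=dict)
    dm_windows: dict[str, float] = field(default_factory=dict)
    planted_markers: list[PlantedMarker] = field(default_factory=list)

    def validate(self, window_keys: set[str]) -> None:
        for m in self.planted_markers:
            if m.transcript_id not in self.de_transcripts:
                raise AssertionError(
                    f"planted marker {m.gene_symbol} is not a DE transcript"
                )
            missing = set(m.window_keys) - window_keys
            if missing:
                raise AssertionError(
                    f"planted marker {m.gene_symbol} has unknown windows {missing}"
                )
            if m.interplay is Interplay.OPPOSITE and not m.regulatory_window_keys:
                raise AssertionError(
                    f"opposite-trend marker {m.gene_symbol} lacks a "
                    "regulatory DM window"
                )


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[ga.GeneModel]]:
    """Toy genome with embedded CpG islands, soft-masks, and gene models.

    Each chromosome starts with an intergenic preamble holding the
    high-GC island segments (GC 80%, obs/exp ~ 1) and lowercase
    soft-masked repeats, followed by evenly spaced gene slots.  Every gene
    has 3 exons (so a first intron exists), a strand drawn at random, and
    a start codon placed a few bases into its first exon, leaving 5 kb of
    clear upstream sequence for the promoter.
    """
    rng = np.random.default_rng(config.seed)
    genes_per_chrom = [
        config.n_transcripts // config.n_chromosomes
        + (1 if c < config.n_transcripts % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    genome: dict[str, str] = {}
    models: list[ga.GeneModel] = []
    for c, n_genes in enumerate(genes_per_chrom):
        chrom = f"chr{c + 1}"
        L = config.genome_length_bp
        seq = _random_sequence(rng, L, config.gc_background)
        if n_genes:
            slot = (L - _PREAMBLE_BP) // n_genes
            if slot < _MIN_SLOT_BP:
                raise ValueError(
                    f"genome too short: {L} bp leaves {slot} bp per gene "
                    f"slot on {chrom}, need >= {_MIN_SLOT_BP}"
                )
        # embedded islands and soft-masked repeats in the preamble
        for i in range(config.n_cgi_per_chromosome):
            start = 1000 + i * (_CGI_LENGTH + 800)
            if start + _CGI_LENGTH > min(L, _PREAMBLE_BP):
                break
            seq[start : start + _CGI_LENGTH] = _random_sequence(
                rng, _CGI_LENGTH, 0.80
            )
        for i in range(config.n_mask_per_chromosome):
            start = 6000 + i * (_MASK_LENGTH + 500)
            if start + _MASK_LENGTH > min(L, _PREAMBLE_BP):
                break
            seg = seq[start : start + _MASK_LENGTH]
            seq[start : start + _MASK_LENGTH] = seg + 32  # to lowercase
        for g in range(n_genes):
            slot_start = _PREAMBLE_BP + g * slot
            strand = "+" if rng.random() < 0.5 else "-"
            exon_lens = rng.integers(150, 301, size=3)
            intron_lens = rng.integers(300, 701, size=2)
            span = int(exon_lens.sum() + intron_lens.sum())
            # + strand genes sit after their 5 kb promoter; - strand genes
            # sit at the slot start with the promoter extending rightwards
            gene_start = slot_start + (5500 if strand == "+" else 1000)
            exons = []
            pos = gene_start
            for k in range(3):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < 2:
                    pos += int(intron_lens[k])
            offset = int(rng.integers(10, 60))
            if strand == "+":
                cds_start = exons[0][0] + offset
            else:
                cds_start = exons[-1][1] - 1 - offset
            idx = len(models)
            symbol = f"g{idx + 1:04d}"
            models.append(
                ga.GeneModel(
                    transcript_id=f"t_{symbol}",
                    gene_symbol=symbol,
                    chromosome=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    cds_start=cds_start,
                )
            )
        genome[chrom] = seq.tobytes().decode("ascii")
    return genome, models


def null_transcript_models(n: int, chromosome: str = "chrNull") -> list[ga.GeneModel]:
    """Minimal single-exon gene models for count-only simulations.

    Useful for large null calibration runs where no genome is needed.
    """
    models = []
    for i in range(n):
        start = i * 1000
        models.append(
            ga.GeneModel(
                transcript_id=f"t_null{i + 1:05d}",
                gene_symbol=f"null{i + 1:05d}",
                chromosome=chromosome,
                strand="+",
                exons=((start, start + 900),),
                cds_start=start + 10,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(
    gene_models: list[ga.GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    forced_de: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """NB count matrix with a planted fraction of age-affected transcripts.

    ``frac_de`` of transcripts receive a log2 fold change drawn uniformly
    from [de_lfc_low, de_lfc_high], down-regulated in the older group with
    probability ``frac_de_down``.  ``forced_de`` pins specific transcripts
    to specific signed log2FCs (used to plant marker genes at
    ``lfc_magnitude``) and counts toward the DE fraction.  Library sizes
    vary log-uniformly within 2-fold.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    tids = [gm.transcript_id for gm in gene_models]
    n = len(tids)
    n_samples = 2 * config.n_per_group
    truth = GroundTruth()

    base = 10 ** rng.uniform(1.0, 3.0, size=n)
    lfc = np.zeros(n)
    forced_de = forced_de or {}
    tid_index = {t: i for i, t in enumerate(tids)}
    for tid, value in forced_de.items():
        lfc[tid_index[tid]] = value
    n_de = int(round(config.frac_de * n))
    free = [i for i, t in enumerate(tids) if t not in forced_de]
    extra = max(0, n_de - len(forced_de))
    chosen = rng.choice(len(free), size=min(extra, len(free)), replace=False)
    for j in chosen:
        i = free[int(j)]
        sign = -1.0 if rng.random() < config.frac_de_down else 1.0
        lfc[i] = sign * rng.uniform(config.de_lfc_low, config.de_lfc_high)
    truth.de_transcripts = {t: float(lfc[i]) for t, i in tid_index.items() if lfc[i] != 0}

    # per-sample depth factors within 2-fold; planted group-mean ratios
    # are exactly 2^lfc on the depth-normalized scale
    depth = 2 ** rng.uniform(-0.5, 0.5, size=n_samples)
    half = config.n_per_group
    mu = base[:, None] * depth[None, :]
    mu[:, half:] *= (2.0**lfc)[:, None]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    frame = pd.DataFrame(counts, index=tids, columns=config.sample_names)
    return frame, truth


# ---------------------------------------------------------------------------
# Methylation counts
# ---------------------------------------------------------------------------

def simulate_methylation(
    windows: list[ga.GenomicWindow],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    marker_windows: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Window x sample methylated-read counts with planted DM effects.

    ``frac_dm_windows`` of windows receive a ``dm_lfc_magnitude`` log2
    effect, hypo-methylated in the older group with probability
    ``frac_dm_hypo``.  ``marker_windows`` maps window keys to a forced
    effect sign (+1 hyper / -1 hypo) for the planted marker genes; those
    windows are excluded from the random draw.
    """
    if not windows:
        raise ValueError("window set is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    marker_windows = marker_windows or {}
    keys = [w.key for w in windows]
    n = len(keys)
    n_samples = 2 * config.n_per_group
    cpg = np.array([w.cpg_count for w in windows], dtype=float)

    base = 10 ** rng.uniform(0.8, 2.0, size=n) * (cpg / cpg.mean())
    lfc = np.zeros(n)
    truth = GroundTruth()
    key_index = {k: i for i, k in enumerate(keys)}
    for k, sign in marker_windows.items():
        lfc[key_index[k]] = sign * config.dm_lfc_magnitude

    free = np.array([i for i, k in enumerate(keys) if k not in marker_windows])
    n_dm = int(round(config.frac_dm_windows * n))
    chosen = rng.choice(free.size, size=min(n_dm, free.size), replace=False)
    for j in chosen:
        i = int(free[j])
        sign = -1.0 if rng.random() < config.frac_dm_hypo else 1.0
        lfc[i] = sign * config.dm_lfc_magnitude * 2 ** rng.normal(0, config.lfc_jitter)
        truth.dm_windows[keys[i]] = float(lfc[i])

    depth = 2 ** rng.uniform(-0.5, 0.5, size=n_samples)
    half = config.n_per_group
    mu = base[:, None] * depth[None, :]
    mu[:, half:] *= (2.0**lfc)[:, None]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    frame = pd.DataFrame(counts, index=keys, columns=config.sample_names)
    return frame, truth


# ---------------------------------------------------------------------------
# Annotation (gene -> ontology leaf terms)
# ---------------------------------------------------------------------------

def simulate_annotation(
    gene_models: list[ga.GeneModel],
    marker_genes: list[str],
    rng: np.random.Generator,
    n_marker_terms: int = 5,
    background_rate: float = 0.5,
) -> pd.DataFrame:
    """Gene -> leaf-term annotation over the packaged mini ontology.

    Marker genes get one leaf from each of the five distinct ancestor
    groups (guaranteeing the multifunction property); background genes are
    sparsely annotated with 1-2 random leaves.
    """
    rows = []
    marker_set = set(marker_genes)
    for gm in gene_models:
        g = gm.gene_symbol
        if g in marker_set:
            terms = list(_LEAF_SPREAD[:n_marker_terms])
        elif rng.random() < background_rate:
            k = int(rng.integers(1, 3))
            terms = list(rng.choice(_LEAF_TERMS, size=k, replace=False))
        else:
            terms = []
        for t in terms:
            rows.append({"gene": g, "term": t})
    return pd.DataFrame(rows, columns=["gene", "term"])


# ---------------------------------------------------------------------------
# Full dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    gene_models: list[ga.GeneModel]
    windows: list[ga.GenomicWindow]
    window_links: pd.DataFrame
    counts: pd.DataFrame
    methylation: pd.DataFrame
    annotation: pd.DataFrame
    truth: GroundTruth


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic experiment.

    Marker genes are chosen among genes with enough regulatory CpG
    windows; their expression effects are planted with ``simulate_counts``
    (sign split mirroring ``frac_de_down``) and their methylation effects
    planted window-wise: opposite-trend markers get regulatory-window
    effects opposing expression, down+hypo markers get concordant hypo
    effects on all their windows.
    """
    rng = np.random.default_rng(config.seed)
    genome, gene_models = generate_genome(config)
    windows: list[ga.GenomicWindow] = []
    for chrom, seq in genome.items():
        windows.extend(ga.make_windows(seq, chrom))
    islands = [
        isl
        for chrom, seq in genome.items()
        for isl in ga.detect_cpg_islands(seq, chrom)
    ]
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    training = ga.build_training_sets(gene_models, islands, chrom_lengths)
    windows = ga.classify_windows(windows, gene_models, training, chrom_lengths)
    links = ga.window_links_frame(windows)

    # candidate marker genes need regulatory windows (opposite markers)
    # or any linked windows (down+hypo markers)
    reg_count = links[links["regulatory"]].groupby("transcript_id").size()
    any_count = links.groupby("transcript_id").size()
    eligible_reg = sorted(reg_count.index[reg_count >= 2])
    eligible_any = sorted(any_count.index[any_count >= 2])
    n_opp = config.n_planted_opposite
    n_dh = config.n_planted_down_hypo
    if len(eligible_reg) < n_opp:
        raise ValueError(
            f"only {len(eligible_reg)} genes have >= 2 regulatory windows; "
            f"cannot plant {n_opp} opposite-trend markers"
        )
    opp_tids = list(
        rng.choice(eligible_reg, size=n_opp, replace=False)
    )
    remaining = [t for t in eligible_any if t not in set(opp_tids)]
    if len(remaining) < n_dh:
        raise ValueError(
            f"only {len(remaining)} genes available for {n_dh} down+hypo markers"
        )
    dh_tids = list(rng.choice(remaining, size=n_dh, replace=False))

    by_tid = {gm.transcript_id: gm for gm in gene_models}
    forced_de: dict[str, float] = {}
    markers: list[PlantedMarker] = []
    for k, tid in enumerate(opp_tids):
        # keep the planted sign split aligned with the down fraction
        sign = -1.0 if (k / max(n_opp, 1)) < config.frac_de_down else 1.0
        expr_lfc = sign * config.lfc_magnitude * 2 ** rng.normal(0, config.lfc_jitter)
        forced_de[tid] = float(expr_lfc)
        sub = links[links["transcript_id"] == tid]
        reg_keys = sorted(sub[sub["regulatory"]]["window"])
        markers.append(
            PlantedMarker(
                gene_symbol=by_tid[tid].gene_symbol,
                transcript_id=tid,
                interplay=Interplay.OPPOSITE,
                expression_lfc=float(expr_lfc),
                methylation_sign=+1 if sign < 0 else -1,
                window_keys=sorted(sub["window"]),
                regulatory_window_keys=reg_keys,
            )
        )
    for tid in dh_tids:
        expr_lfc = -config.lfc_magnitude * 2 ** rng.normal(0, config.lfc_jitter)
        forced_de[tid] = float(expr_lfc)
        sub = links[links["transcript_id"] == tid]
        markers.append(
            PlantedMarker(
                gene_symbol=by_tid[tid].gene_symbol,
                transcript_id=tid,
                interplay=Interplay.DOWN_HYPO,
                expression_lfc=float(expr_lfc),
                methylation_sign=-1,
                window_keys=sorted(sub["window"]),
                regulatory_window_keys=sorted(sub[sub["regulatory"]]["window"]),
            )
        )

    counts, truth = simulate_counts(
        gene_models, config, np.random.default_rng(config.seed + 1), forced_de
    )
    marker_windows: dict[str, int] = {}
    for m in markers:
        target = (
            m.regulatory_window_keys
            if m.interplay is Interplay.OPPOSITE
            else m.window_keys
        )
        for k in target:
            marker_windows[k] = m.methylation_sign
    methylation, dm_truth = simulate_methylation(
        windows, config, np.random.default_rng(config.seed + 2), marker_windows
    )
    truth.dm_windows = dm_truth.dm_windows
    truth.planted_markers = markers
    truth.validate({w.key for w in windows})

    annotation = simulate_annotation(
        gene_models,
        [m.gene_symbol for m in markers if m.interplay is Interplay.OPPOSITE],
        np.random.default_rng(config.seed + 3),
    )
    return SyntheticDataset(
        config=config,
        genome=genome,
        gene_models=gene_models,
        windows=windows,
        window_links=links,
        counts=counts,
        methylation=methylation,
        annotation=annotation,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/GFF3/TSV inputs for a file-based pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "counts": outdir / "counts.tsv",
        "methylation": outdir / "methylation_counts.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "ontology": outdir / "ontology.obo",
    }
    ga.write_genome(dataset.genome, paths["genome"])
    ga.write_gff3(dataset.gene_models, paths["gff"])
    dataset.counts.rename_axis("transcript_id").to_csv(paths["counts"], sep="\t")
    dataset.methylation.rename_axis("window").to_csv(
        paths["methylation"], sep="\t"
    )
    dataset.config.sample_sheet().to_csv(paths["sample_sheet"], sep="\t", index=False)
    dataset.annotation.to_csv(paths["annotation"], sep="\t", index=False, header=False)
    paths["ontology"].write_text(mini_ontology_text())
    return paths


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("methylage.data").joinpath(name)


def mini_ontology_text() -> str:
    return _data_path("mini_go.obo").read_text()


def load_table_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged process-incidence and gene summary fixtures.

    Returns ``(processes, genes)``: 18 functional-process rows with their
    member genes and up-regulated subset, and 14 multifunction gene rows
    with function counts, expression direction and the regulatory-mark
    flag.
    """
    with resources.as_file(_data_path("table1_processes.tsv")) as p:
        processes = pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)
    with resources.as_file(_data_path("table2_genes.tsv")) as p:
        genes = pd.read_csv(p, sep="\t", comment="#")
    genes["regulatory"] = genes["regulatory"].astype(bool)
    return processes, genes


def fixture_incidence():
    """IncidenceTable built from the packaged fixtures.

    Membership comes from the process table (all 33 genes); directions come
    from the per-row up-gene annotation; regulatory flags from the gene
    table (genes absent from it are not multifunctional and carry no flag).
    """
    from .enrichment import IncidenceTable

    processes, genes = load_table_fixtures()
    all_genes: set[str] = set()
    up_genes: set[str] = set()
    members: dict[str, set[str]] = {}
    for r in processes.itertuples():
        gs = {g.strip() for g in str(r.genes).split(",") if g.strip()}
        members[r.process] = gs
        all_genes |= gs
        if r.up_genes:
            up_genes |= {g.strip() for g in str(r.up_genes).split(",") if g.strip()}
    cols = sorted(all_genes)
    membership = pd.DataFrame(
        {g: [g in members[p] for p in processes["process"]] for g in cols},
        index=processes["process"],
    ).astype(bool)
    direction = pd.Series(
        {g: ("up" if g in up_genes else "down") for g in cols}, name="direction"
    )
    regulatory = pd.Series(False, index=cols, name="regulatory")
    for r in genes.itertuples():
        regulatory[r.gene] = bool(r.regulatory)
    return IncidenceTable(membership, direction, regulatory)
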