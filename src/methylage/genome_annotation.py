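"""Genomic feature annotation for the methylation analysis.

Builds the five genomic training sets (exon, intron, promoter, CGI-promoter,
CGI-intergenic), detects CpG islands with EMBOSS ``newcpgreport``-style
parameters, tiles chromosomes into 25 bp CpG-containing windows (the unit of
methylation quantification), and classifies each window, including the
regulatory-region flag (promoter / first exon / first intron of a linked
transcript).

Coordinates are 0-based half-open throughout; GFF3 I/O converts to and from
the 1-based inclusive convention of that format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_SIZE = 25
PROMOTER_BP = 5000

CGI_SCAN_WINDOW = 100
CGI_MIN_GC = 0.50
CGI_MIN_OBS_EXP = 0.60
CGI_MIN_LENGTH = 200

WINDOW_LABELS = (
    "promoter",
    "exon",
    "intron",
    "cgi_promoter",
    "cgi_intergenic",
    "intergenic",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A transcript model with strand-aware derived regulatory elements.

    ``exons`` are stored ascending by genomic coordinate regardless of
    strand; "first" exon/intron means 5'-most in transcript orientation.
    ``cds_start`` is the genomic position of the start codon's first base.
    """

    transcript_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: gene model needs >=1 exon")
        ex = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", ex)
        if not any(s <= self.cds_start < e for s, e in ex):
            raise ValueError(
                f"{self.transcript_id}: cds_start {self.cds_start} not in an exon"
            )

    @property
    def body(self) -> tuple[int, int]:
        """Gene body: first exon start to last exon end (genomic order)."""
        return self.exons[0][0], self.exons[-1][1]

    def promoter(self, chrom_length: int | None = None) -> tuple[int, int]:
        """5 kb upstream of the start codon, strand-aware, clipped to bounds."""
        if self.strand == "+":
            start, end = self.cds_start - PROMOTER_BP, self.cds_start
        else:
            start, end = self.cds_start + 1, self.cds_start + 1 + PROMOTER_BP
        start = max(start, 0)
        if chrom_length is not None:
            end = min(end, chrom_length)
        return start, max(start, end)

    @property
    def first_exon(self) -> tuple[int, int]:
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def first_intron(self) -> tuple[int, int] | None:
        """5'-most intron, or None for single-exon models."""
        if len(self.exons) < 2:
            return None
        if self.strand == "+":
            return self.exons[0][1], self.exons[1][0]
        return self.exons[-2][1], self.exons[-1][0]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )


@dataclass(frozen=True)
class CpGIsland:
    chromosome: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_ratio: float
    context: str = "intergenic"  # promoter | intergenic

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomicWindow:
    """A 25 bp CpG-containing bin with annotation labels and links."""

    chromosome: str
    start: int
    end: int
    cpg_count: int
    labels: frozenset[str] = field(default_factory=frozenset)
    regulatory: bool = False
    linked_transcripts: tuple[str, ...] = ()
    # per-transcript regulatory flags, parallel to linked_transcripts;
    # ``regulatory`` is their OR
    linked_regulatory: tuple[bool, ...] = ()

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# CpG island detection
# ---------------------------------------------------------------------------

def _base_indicators(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position indicators for C, G and a CG dinucleotide starting here."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cg = np.zeros(arr.size, dtype=bool)
    if arr.size >= 2:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, is_cg


def _region_stats(
    is_c: np.ndarray, is_g: np.ndarray, is_cg: np.ndarray, start: int, end: int
) -> tuple[float, float]:
    """(gc_fraction, obs_exp_ratio) over [start, end); CG pairs fully inside."""
    length = end - start
    n_c = int(is_c[start:end].sum())
    n_g = int(is_g[start:end].sum())
    n_cg = int(is_cg[start : end - 1].sum())
    gc = (n_c + n_g) / length if length else 0.0
    obs_exp = (n_cg * length) / (n_c * n_g) if n_c and n_g else 0.0
    return gc, obs_exp


def detect_cpg_islands(
    sequence: str,
    chromosome: str = "chr",
    window: int = CGI_SCAN_WINDOW,
    min_gc: float = CGI_MIN_GC,
    min_obs_exp: float = CGI_MIN_OBS_EXP,
    min_length: int = CGI_MIN_LENGTH,
) -> list[CpGIsland]:
    """Detect CpG islands by sliding-window scan and merge.

    A 100 bp window qualifies when its C+G content is >= 50% and its
    observed/expected CpG ratio, ``count(CG) * L / (count(C) * count(G))``,
    is >= 0.60.  Overlapping or book-ended qualifying windows are merged and
    merged regions shorter than 200 bp are discarded.  Case (soft-masking)
    is ignored for detection.
    """
    n = len(sequence)
    if n < window:
        return []
    is_c, is_g, is_cg = _base_indicators(sequence)
    cum_c = np.concatenate(([0], np.cumsum(is_c)))
    cum_g = np.concatenate(([0], np.cumsum(is_g)))
    cum_cg = np.concatenate(([0], np.cumsum(is_cg)))

    starts = np.arange(n - window + 1)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    # CG dinucleotides fully inside the window: start position in [s, s+w-1)
    n_cg = cum_cg[starts + window - 1] - cum_cg[starts]
    gc_ok = (n_c + n_g) >= min_gc * window
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(n_c * n_g > 0, n_cg * window / (n_c * n_g), 0.0)
    qualify = gc_ok & (obs_exp >= min_obs_exp)

    islands: list[CpGIsland] = []
    q = np.flatnonzero(qualify)
    if q.size == 0:
        return islands
    # merge qualifying windows whose spans overlap or touch
    breaks = np.flatnonzero(np.diff(q) > window)
    group_starts = np.concatenate(([0], breaks + 1))
    group_ends = np.concatenate((breaks, [q.size - 1]))
    for gs, ge in zip(group_starts, group_ends):
        start, end = int(q[gs]), int(q[ge]) + window
        if end - start < min_length:
            continue
        gc, oe = _region_stats(is_c, is_g, is_cg, start, end)
        islands.append(CpGIsland(chromosome, start, end, gc, oe))
    return islands


# ---------------------------------------------------------------------------
# 25 bp window construction
# ---------------------------------------------------------------------------

def make_windows(
    sequence: str,
    chromosome: str = "chr",
    mask_policy: str = "exclude",
    window_size: int = WINDOW_SIZE,
) -> list[GenomicWindow]:
    """Tile a chromosome into consecutive 25 bp bins and keep CpG bins.

    Bins are anchored at position 0 and non-overlapping; a trailing partial
    bin is dropped.  A CG dinucleotide belongs to the bin containing its C,
    so a pair straddling a bin boundary counts for the left bin.  A bin is
    retained iff it contains >= 1 CG.  With ``mask_policy="exclude"``, bins
    whose sequence is entirely soft-masked (lowercase) are dropped;
    ``"include"`` keeps them.
    """
    if mask_policy not in ("exclude", "include"):
        raise ValueError(f"unknown mask_policy {mask_policy!r}")
    n = len(sequence)
    n_bins = n // window_size
    if n_bins == 0:
        return []
    _, _, is_cg = _base_indicators(sequence)
    cum_cg = np.concatenate(([0], np.cumsum(is_cg)))
    starts = np.arange(n_bins) * window_size
    counts = cum_cg[starts + window_size] - cum_cg[starts]
    keep = counts >= 1
    if mask_policy == "exclude":
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        is_lower = (arr >= ord("a")) & (arr <= ord("z"))
        cum_low = np.concatenate(([0], np.cumsum(is_lower)))
        n_low = cum_low[starts + window_size] - cum_low[starts]
        keep &= n_low < window_size
    return [
        GenomicWindow(chromosome, int(s), int(s) + window_size, int(c))
        for s, c in zip(starts[keep], counts[keep])
    ]


# ---------------------------------------------------------------------------
# Training sets
# ---------------------------------------------------------------------------

@dataclass
class TrainingSets:
    """The five labelled interval sets used to localise methylated reads.

    Intervals are ``(chromosome, start, end, name)`` tuples, 0-based
    half-open.
    """

    promoter: list[tuple[str, int, int, str]]
    exon: list[tuple[str, int, int, str]]
    intron: list[tuple[str, int, int, str]]
    cgi_promoter: list[tuple[str, int, int, str]]
    cgi_intergenic: list[tuple[str, int, int, str]]

    def as_dict(self) -> dict[str, list[tuple[str, int, int, str]]]:
        return {
            "promoter": self.promoter,
            "exon": self.exon,
            "intron": self.intron,
            "cgi_promoter": self.cgi_promoter,
            "cgi_intergenic": self.cgi_intergenic,
        }


def build_training_sets(
    gene_models: Sequence[GeneModel],
    islands: Sequence[CpGIsland] = (),
    chrom_lengths: Mapping[str, int] | None = None,
) -> TrainingSets:
    """Derive promoter/exon/intron sets and split CGIs by promoter overlap.

    The promoter is the 5000 bp upstream of the start codon on the coding
    strand, clipped to chromosome bounds.  An island overlapping any
    promoter interval by >= 1 bp is classed ``cgi_promoter``, otherwise
    ``cgi_intergenic``.
    """
    promoters: list[tuple[str, int, int, str]] = []
    exons: list[tuple[str, int, int, str]] = []
    introns: list[tuple[str, int, int, str]] = []
    for gm in gene_models:
        clen = None if chrom_lengths is None else chrom_lengths.get(gm.chromosome)
        if clen is not None and not (0 <= gm.cds_start < clen):
            raise ValueError(
                f"{gm.transcript_id}: cds_start {gm.cds_start} outside "
                f"chromosome {gm.chromosome} of length {clen}"
            )
        ps, pe = gm.promoter(clen)
        if pe > ps:
            promoters.append((gm.chromosome, ps, pe, gm.transcript_id))
        for s, e in gm.exons:
            exons.append((gm.chromosome, s, e, gm.transcript_id))
        for s, e in gm.introns:
            introns.append((gm.chromosome, s, e, gm.transcript_id))

    cgi_promoter: list[tuple[str, int, int, str]] = []
    cgi_intergenic: list[tuple[str, int, int, str]] = []
    for i, isl in enumerate(islands):
        name = f"CGI_{i + 1}"
        in_promoter = any(
            c == isl.chromosome and isl.start < e and s < isl.end
            for c, s, e, _ in promoters
        )
        target = cgi_promoter if in_promoter else cgi_intergenic
        target.append((isl.chromosome, isl.start, isl.end, name))
    return TrainingSets(promoters, exons, introns, cgi_promoter, cgi_intergenic)


def classify_islands(
    islands: Sequence[CpGIsland], training: TrainingSets
) -> list[CpGIsland]:
    """Return islands with their promoter/intergenic context filled in."""
    promo = {(c, s, e) for c, s, e, _ in training.cgi_promoter}
    return [
        CpGIsland(
            i.chromosome,
            i.start,
            i.end,
            i.gc_fraction,
            i.obs_exp_ratio,
            "promoter" if (i.chromosome, i.start, i.end) in promo else "intergenic",
        )
        for i in islands
    ]


# ---------------------------------------------------------------------------
# Window classification
# ---------------------------------------------------------------------------

def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def classify_windows(
    windows: Sequence[GenomicWindow],
    gene_models: Sequence[GeneModel],
    training: TrainingSets,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicWindow]:
    """Label windows, link transcripts, and set the regulatory flag.

    A window receives every label whose interval set it overlaps by >= 1 bp
    (``intergenic`` when it overlaps no promoter, exon or intron).  Linked
    transcripts are those whose promoter or gene body overlaps the window.
    ``regulatory`` is true iff the window overlaps a linked transcript's
    promoter, first exon, or first intron (5'-most in transcript
    orientation); it is evaluated per transcript then OR-reduced.
    """
    # bucket gene models per chromosome, order-independent processing
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in sorted(gene_models, key=lambda g: g.transcript_id):
        by_chrom.setdefault(gm.chromosome, []).append(gm)

    cgi_sets = {
        "cgi_promoter": training.cgi_promoter,
        "cgi_intergenic": training.cgi_intergenic,
    }
    out: list[GenomicWindow] = []
    for w in windows:
        labels: set[str] = set()
        linked: list[str] = []
        linked_reg: list[bool] = []
        for gm in by_chrom.get(w.chromosome, []):
            clen = None if chrom_lengths is None else chrom_lengths.get(w.chromosome)
            ps, pe = gm.promoter(clen)
            in_promoter = _overlaps(w.start, w.end, ps, pe)
            bs, be = gm.body
            in_body = _overlaps(w.start, w.end, bs, be)
            if in_promoter:
                labels.add("promoter")
            if in_body:
                if any(_overlaps(w.start, w.end, s, e) for s, e in gm.exons):
                    labels.add("exon")
                if any(_overlaps(w.start, w.end, s, e) for s, e in gm.introns):
                    labels.add("intron")
            if in_promoter or in_body:
                linked.append(gm.transcript_id)
                reg_intervals = [(ps, pe), gm.first_exon]
                fi = gm.first_intron
                if fi is not None:
                    reg_intervals.append(fi)
                linked_reg.append(
                    any(_overlaps(w.start, w.end, s, e) for s, e in reg_intervals)
                )
        for label, intervals in cgi_sets.items():
            if any(
                c == w.chromosome and _overlaps(w.start, w.end, s, e)
                for c, s, e, _ in intervals
            ):
                labels.add(label)
        if not labels & {"promoter", "exon", "intron"}:
            labels.add("intergenic")
        out.append(
            GenomicWindow(
                w.chromosome,
                w.start,
                w.end,
                w.cpg_count,
                frozenset(labels),
                any(linked_reg),
                tuple(linked),
                tuple(linked_reg),
            )
        )
    return out


def window_links_frame(windows: Sequence[GenomicWindow]) -> pd.DataFrame:
    """Long-form window -> transcript link table with regulatory flags."""
    rows = []
    for w in windows:
        for tid, reg in zip(w.linked_transcripts, w.linked_regulatory):
            rows.append({"window": w.key, "transcript_id": tid, "regulatory": reg})
    return pd.DataFrame(rows, columns=["window", "transcript_id", "regulatory"])


# ---------------------------------------------------------------------------
# FASTA / GFF3 / BED I/O
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into a name -> sequence dict (case preserved)."""
    from pyfaidx import Fasta

    with Fasta(str(path), read_long_names=False, rebuild=False) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(gene_models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for gm in gene_models:
        gid = f"gene:{gm.gene_symbol}:{gm.transcript_id}"
        bs, be = gm.body
        lines.append(
            "\t".join(
                [
                    gm.chromosome, "methylage", "gene", str(bs + 1), str(be),
                    ".", gm.strand, ".",
                    f"ID={gid};Name={gm.gene_symbol}",
                ]
            )
        )
        lines.append(
            "\t".join(
                [
                    gm.chromosome, "methylage", "mRNA", str(bs + 1), str(be),
                    ".", gm.strand, ".",
                    f"ID={gm.transcript_id};Parent={gid};gene_symbol={gm.gene_symbol}",
                ]
            )
        )
        for k, (s, e) in enumerate(gm.exons, 1):
            lines.append(
                "\t".join(
                    [
                        gm.chromosome, "methylage", "exon", str(s + 1), str(e),
                        ".", gm.strand, ".",
                        f"ID={gm.transcript_id}.exon{k};Parent={gm.transcript_id}",
                    ]
                )
            )
        # CDS records the start codon: its strand-aware 5' end is cds_start
        if gm.strand == "+":
            cs, ce = gm.cds_start, gm.cds_start + 3
        else:
            cs, ce = gm.cds_start - 2, gm.cds_start + 1
        lines.append(
            "\t".join(
                [
                    gm.chromosome, "methylage", "CDS", str(cs + 1), str(ce),
                    ".", gm.strand, "0",
                    f"ID={gm.transcript_id}.cds;Parent={gm.transcript_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 written by :func:`write_gff3`.

    Any GFF3 with mRNA/exon/CDS features and ``Parent`` links works; the
    start codon is taken as the strand-aware 5'-most CDS base.
    """
    text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            continue
        rows.append(f)
    if not rows:
        return []
    df = pd.DataFrame(
        rows,
        columns=[
            "seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
    )
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)

    transcripts: dict[str, dict] = {}
    for _, r in df[df["type"] == "mRNA"].iterrows():
        attrs = _gff_attrs(r["attributes"])
        tid = attrs["ID"]
        transcripts[tid] = {
            "chromosome": r["seqid"],
            "strand": r["strand"],
            "gene_symbol": attrs.get("gene_symbol", attrs.get("Name", tid)),
            "exons": [],
            "cds": [],
        }
    for _, r in df[df["type"].isin(["exon", "CDS"])].iterrows():
        attrs = _gff_attrs(r["attributes"])
        parent = attrs.get("Parent", "")
        if parent not in transcripts:
            continue
        key = "exons" if r["type"] == "exon" else "cds"
        transcripts[parent][key].append((r["start"], r["end"]))
    models = []
    for tid, t in transcripts.items():
        if not t["exons"]:
            continue
        if t["cds"]:
            if t["strand"] == "+":
                cds_start = min(s for s, _ in t["cds"])
            else:
                cds_start = max(e for _, e in t["cds"]) - 1
        else:  # fall back to transcript 5' end
            ex = sorted(t["exons"])
            cds_start = ex[0][0] if t["strand"] == "+" else ex[-1][1] - 1
        models.append(
            GeneModel(
                tid,
                t["gene_symbol"],
                t["chromosome"],
                t["strand"],
                tuple(t["exons"]),
                cds_start,
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name) records as 4-column BED."""
    buf = io.StringIO()
    for chrom, start, end, name in intervals:
        buf.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    Path(path).write_text(buf.getvalue())


def windows_to_bed(windows: Sequence[GenomicWindow], path: str | Path) -> None:
    write_bed(
        (
            (w.chromosome, w.start, w.end, ",".join(sorted(w.labels)) or ".")
            for w in windows
        ),
        path,
    )


def islands_to_bed(islands: Sequence[CpGIsland], path: str | Path) -> None:
    write_bed(((i.chromosome, i.start, i.end, i.context) for i in islands), path)
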