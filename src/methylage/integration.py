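"""Methylation-expression integration of the discriminant feature sets.

Matches discriminant differentially expressed (DE) transcripts with the
discriminant differentially methylated (DM) windows linked to them through
their promoter or gene body, classifies each transcript's interplay with
the 75% rules (OPPOSITE: methylation opposing expression; DOWN_HYPO:
down-regulated with mostly hypo-methylated windows), and quantifies the
relationship as a Pearson correlation of the two log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

OPPOSITE_FRACTION = 0.75


class Interplay(str, Enum):
    OPPOSITE = "OPPOSITE"
    DOWN_HYPO = "DOWN_HYPO"
    OTHER = "OTHER"


@dataclass
class OverlapRecord:
    transcript_id: str
    gene_symbol: str
    de_log2fc: float
    de_direction: str                 # up | down
    dm_log2fcs: list[float]           # one per linked discriminant window
    dm_directions: list[str]          # hypo | hyper
    dm_regulatory: list[bool]
    dm_window_keys: list[str]
    interplay: Interplay | None = None

    @property
    def n_windows(self) -> int:
        return len(self.dm_log2fcs)

    @property
    def has_regulatory_window(self) -> bool:
        return any(self.dm_regulatory)


def overlap_de_dm(
    de_table: pd.DataFrame,
    dm_table: pd.DataFrame,
    window_links: pd.DataFrame,
    gene_symbols: pd.Series | None = None,
) -> list[OverlapRecord]:
    """One record per DE transcript with >= 1 linked discriminant DM window.

    Parameters
    ----------
    de_table
        Discriminant DE transcripts (columns transcript_id, log2fc).
    dm_table
        Discriminant DM windows (columns window, log2fc).
    window_links
        Long-form window -> transcript links with the regulatory flag
        (columns window, transcript_id, regulatory); a window linked to two
        transcripts contributes to both records.
    gene_symbols
        Optional transcript_id -> gene symbol map (default: identity).
    """
    dm_by_window = dm_table.set_index("window")
    links = window_links[window_links["window"].isin(dm_by_window.index)]
    by_transcript: dict[str, list[tuple[str, bool]]] = {}
    for r in links.itertuples():
        by_transcript.setdefault(r.transcript_id, []).append(
            (r.window, bool(r.regulatory))
        )
    records = []
    for r in de_table.itertuples():
        linked = by_transcript.get(r.transcript_id)
        if not linked:
            continue
        linked = sorted(set(linked))
        lfcs = [float(dm_by_window.loc[w, "log2fc"]) for w, _ in linked]
        records.append(
            OverlapRecord(
                transcript_id=r.transcript_id,
                gene_symbol=(
                    str(gene_symbols.get(r.transcript_id, r.transcript_id))
                    if gene_symbols is not None
                    else r.transcript_id
                ),
                de_log2fc=float(r.log2fc),
                de_direction="down" if r.log2fc < 0 else "up",
                dm_log2fcs=lfcs,
                dm_directions=["hypo" if x < 0 else "hyper" for x in lfcs],
                dm_regulatory=[reg for _, reg in linked],
                dm_window_keys=[w for w, _ in linked],
            )
        )
    return records


def classify_interplay(
    record: OverlapRecord, min_fraction: float = OPPOSITE_FRACTION
) -> Interplay:
    """Apply the 75% interplay rules to one overlap record.

    OPPOSITE when >= 75% of the transcript's DM windows change in the
    direction opposite to its expression (hyper with down-regulation or
    hypo with up-regulation); otherwise DOWN_HYPO when the transcript is
    down-regulated and >= 75% of its windows are hypo-methylated; else
    OTHER.  OPPOSITE is evaluated first.
    """
    if record.n_windows == 0:
        raise ValueError(f"{record.transcript_id}: record has no DM windows")
    n = record.n_windows
    opp = "hyper" if record.de_direction == "down" else "hypo"
    frac_opposite = sum(d == opp for d in record.dm_directions) / n
    if frac_opposite >= min_fraction:
        return Interplay.OPPOSITE
    if record.de_direction == "down":
        frac_hypo = sum(d == "hypo" for d in record.dm_directions) / n
        if frac_hypo >= min_fraction:
            return Interplay.DOWN_HYPO
    return Interplay.OTHER


def classify_records(
    records: list[OverlapRecord], min_fraction: float = OPPOSITE_FRACTION
) -> list[OverlapRecord]:
    for rec in records:
        rec.interplay = classify_interplay(rec, min_fraction)
    return records


def methylation_expression_correlation(
    records: list[OverlapRecord],
    class_filter: Interplay | None = None,
    summary: str = "mean",
) -> tuple[float, float]:
    """Pearson correlation of methylation vs expression log2FC.

    Each transcript contributes one point: its expression log2FC against
    the mean (or median) log2FC of its DM windows.  Requires >= 3 records
    after filtering and non-constant values on both axes.
    """
    if class_filter is not None:
        records = [r for r in records if r.interplay == class_filter]
    if len(records) < 3:
        raise ValueError(
            f"need >= 3 records for a correlation, got {len(records)}"
        )
    agg = np.mean if summary == "mean" else np.median
    meth = np.array([agg(r.dm_log2fcs) for r in records])
    expr = np.array([r.de_log2fc for r in records])
    if np.allclose(meth, meth[0]) or np.allclose(expr, expr[0]):
        raise ValueError("correlation undefined: zero variance on one axis")
    r, p = stats.pearsonr(meth, expr)
    return float(r), float(p)


def summarize_interplay(records: list[OverlapRecord]) -> pd.DataFrame:
    """Per-class transcript and window counts."""
    rows = []
    for cls in Interplay:
        recs = [r for r in records if r.interplay == cls]
        rows.append(
            {
                "interplay": cls.value,
                "n_transcripts": len(recs),
                "n_genes": len({r.gene_symbol for r in recs}),
                "n_windows": sum(r.n_windows for r in recs),
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    """Flat overlap table (one row per transcript)."""
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "de_log2fc": [r.de_log2fc for r in records],
            "de_direction": [r.de_direction for r in records],
            "n_dm_windows": [r.n_windows for r in records],
            "n_hyper": [r.dm_directions.count("hyper") for r in records],
            "n_hypo": [r.dm_directions.count("hypo") for r in records],
            "n_regulatory": [sum(r.dm_regulatory) for r in records],
            "mean_dm_log2fc": [float(np.mean(r.dm_log2fcs)) for r in records],
            "interplay": [
                r.interplay.value if r.interplay else "" for r in records
            ],
        }
    )
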