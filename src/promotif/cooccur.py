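"""Windowed motif co-occurrence around an anchor motif (the matrix
combination search).

A secondary site co-occurs with an anchor site when both lie in the same
gene promoter and the gap between their inclusive intervals is at most W
bases (default 100), counted on either side of the anchor with an
inclusive boundary.  Overlapping intervals have gap 0 and co-occur, as in
the Caspase1 promoter where the P53 site (-117..-98) overlaps the HIPPI
binding site (-119..-111).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .motifs import PWM
from .scan import scan_set
from .sequences import SequenceSet, truncate_to_extent
from .stats import enrichment_table

COOCCURRENCE_COLUMNS = [
    "gene_id",
    "anchor_motif_id",
    "anchor_start",
    "anchor_end",
    "anchor_strand",
    "secondary_motif_id",
    "secondary_start",
    "secondary_end",
    "secondary_strand",
    "gap",
]


@dataclass(frozen=True)
class WindowSpec:
    """Search window: W bp on either side of the anchor, boundary inclusive."""

    width: int = 100

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValidationError(f"window width must be >= 0, got {self.width}")


def gap_between(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Bases strictly between two inclusive intervals; 0 when they overlap."""
    return max(0, start_b - end_a - 1, start_a - end_b - 1)


def _check_convention(hits: pd.DataFrame, label: str) -> None:
    if len(hits) and (hits["start"] >= 0).any():
        raise ValidationError(
            f"{label} hit table contains non-negative start positions; "
            "all coordinates must be TSS-relative (negative)"
        )


def find_cooccurrences(
    anchor_hits: pd.DataFrame,
    secondary_hits: pd.DataFrame,
    window: WindowSpec | int = WindowSpec(),
) -> pd.DataFrame:
    """All (anchor, secondary) same-gene pairs within the window.

    Self-pairing of the identical hit (same motif, interval and strand) is
    excluded; every other pair whose intervals overlap or whose gap is at
    most W yields one record.
    """
    if isinstance(window, int):
        window = WindowSpec(window)
    _check_convention(anchor_hits, "anchor")
    _check_convention(secondary_hits, "secondary")
    if not len(anchor_hits) or not len(secondary_hits):
        return pd.DataFrame(columns=COOCCURRENCE_COLUMNS)
    a = anchor_hits.rename(
        columns={
            "motif_id": "anchor_motif_id",
            "start": "anchor_start",
            "end": "anchor_end",
            "strand": "anchor_strand",
        }
    )[["gene_id", "anchor_motif_id", "anchor_start", "anchor_end", "anchor_strand"]]
    s = secondary_hits.rename(
        columns={
            "motif_id": "secondary_motif_id",
            "start": "secondary_start",
            "end": "secondary_end",
            "strand": "secondary_strand",
        }
    )[
        [
            "gene_id",
            "secondary_motif_id",
            "secondary_start",
            "secondary_end",
            "secondary_strand",
        ]
    ]
    pairs = a.merge(s, on="gene_id")
    if not len(pairs):
        return pd.DataFrame(columns=COOCCURRENCE_COLUMNS)
    gap = np.maximum(
        0,
        np.maximum(
            pairs["secondary_start"] - pairs["anchor_end"] - 1,
            pairs["anchor_start"] - pairs["secondary_end"] - 1,
        ),
    )
    pairs["gap"] = gap.astype(np.int64)
    identical = (
        (pairs["anchor_motif_id"] == pairs["secondary_motif_id"])
        & (pairs["anchor_start"] == pairs["secondary_start"])
        & (pairs["anchor_end"] == pairs["secondary_end"])
        & (pairs["anchor_strand"] == pairs["secondary_strand"])
    )
    kept = pairs.loc[(pairs["gap"] <= window.width) & ~identical]
    return kept[COOCCURRENCE_COLUMNS].reset_index(drop=True)


def cooccurrence_enrichment(
    target: SequenceSet,
    background: SequenceSet,
    anchor: PWM,
    secondary_library: Sequence[PWM],
    anchor_cutoff: float = 1.0,
    secondary_cutoff: float = 0.9,
    window: WindowSpec | int = WindowSpec(),
    alpha: float = 0.05,
    extent: int | None = None,
    universe: str = "anchored",
) -> pd.DataFrame:
    """Per secondary motif: over-representation of in-window co-occurrence
    in the target versus the background.

    k / K count target / background genes with at least one co-occurrence;
    n / N are by default the genes with at least one anchor hit
    (``universe="anchored"``, co-occurrence being undefined without an
    anchor), or all genes with ``universe="all"``.
    """
    if isinstance(window, int):
        window = WindowSpec(window)
    if universe not in ("anchored", "all"):
        raise ValidationError(f"universe must be 'anchored' or 'all', got {universe!r}")
    if not background.is_superset_of(target):
        raise ValidationError("target set must be a subset of the background set")
    if not secondary_library:
        raise ValidationError("empty secondary motif library")
    bg = truncate_to_extent(background, extent) if extent else background
    target_ids = set(target.gene_ids)

    anchor_scan = scan_set(anchor, bg, anchor_cutoff)
    anchored_ids = anchor_scan.genes_with_hit
    anchored_target = anchored_ids & target_ids
    if not anchored_target:
        raise ValidationError("no anchored genes in the target set")
    if universe == "anchored":
        n, N = len(anchored_target), len(anchored_ids)
    else:
        n, N = len(target_ids), len(bg)

    anchored_set = bg.subset(anchored_ids, name="anchored")
    ids, ks, Ks = [], [], []
    for pwm in secondary_library:
        sec = scan_set(pwm, anchored_set, secondary_cutoff)
        records = find_cooccurrences(anchor_scan.hits, sec.hits, window)
        genes = set(records["gene_id"]) if len(records) else set()
        ids.append(pwm.motif_id)
        Ks.append(len(genes))
        ks.append(len(genes & target_ids))
    return enrichment_table(ids, ks, n, Ks, N, alpha=alpha)


def write_cooccurrences(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
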