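"""Both-strand PWM scanning of upstream sequence sets (the matrix search).

Every window position on each requested strand whose similarity score
reaches the cutoff becomes one hit; overlapping hits are all reported and
a palindromic site matching both strands at one offset yields two hits.
Hits are reported as inclusive TSS-relative intervals of the matched
sense-strand bases; minus-strand windows are scored on the reverse
complement but the interval refers to the sense coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .motifs import PWM, encode
from .sequences import SequenceSet, UpstreamSequence

logger = logging.getLogger(__name__)

HIT_COLUMNS = ["gene_id", "motif_id", "start", "end", "strand", "score"]


class MotifHit(NamedTuple):
    """One motif match: inclusive TSS-relative interval on a strand."""

    gene_id: str
    motif_id: str
    start: int
    end: int
    strand: str
    score: float


def _check_cutoff(cutoff: float) -> None:
    if not 0.0 <= cutoff <= 1.0:
        raise ValidationError(f"cutoff must be in [0, 1], got {cutoff}")


def _window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Normalised similarity scores for all windows along the last axis."""
    length = len(pwm)
    n_win = codes.shape[-1] - length + 1
    s = np.zeros(codes.shape[:-1] + (n_win,))
    for j in range(length):
        s += pwm.lookup[codes[..., j : j + n_win], j]
    return (s - pwm.s_min) / (pwm.s_max - pwm.s_min)


def _strand_list(strands: str) -> list[str]:
    if strands == "both":
        return ["+", "-"]
    if strands == "plus":
        return ["+"]
    if strands == "minus":
        return ["-"]
    raise ValidationError(f"strands must be both/plus/minus, got {strands!r}")


def scan_sequence(
    pwm: PWM,
    seq: UpstreamSequence,
    cutoff: float,
    strands: str = "both",
) -> list[MotifHit]:
    """All hits of one motif in one sequence, sorted by start position."""
    _check_cutoff(cutoff)
    wanted = _strand_list(strands)
    m, length = len(seq), len(pwm)
    if length > m:
        return []
    codes = encode(seq.sequence)
    hits: list[MotifHit] = []
    for strand in wanted:
        matrix = pwm if strand == "+" else pwm.reverse_complement()
        scores = _window_scores(matrix, codes)
        for i in np.nonzero(scores >= cutoff)[0]:
            hits.append(
                MotifHit(
                    gene_id=seq.gene_id,
                    motif_id=pwm.motif_id,
                    start=int(i) - m,
                    end=int(i) + length - 1 - m,
                    strand=strand,
                    score=float(scores[i]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass
class ScanResult:
    """Hit table plus the gene-level summary of one scan."""

    hits: pd.DataFrame
    n_genes: int
    genes_with_hit: set = field(default_factory=set)

    @property
    def n_with_hit(self) -> int:
        return len(self.genes_with_hit)

    @property
    def pct_with_hit(self) -> float:
        return 100.0 * self.n_with_hit / self.n_genes if self.n_genes else 0.0

    def summary(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_with_hit": self.n_with_hit,
            "pct_with_hit": self.pct_with_hit,
            "n_hits": int(len(self.hits)),
        }


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": pd.Series(dtype=object),
            "motif_id": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "score": pd.Series(dtype=float),
        }
    )


def _encoded_matrix(sset: SequenceSet) -> np.ndarray | None:
    """Stacked uint8 code matrix when all records share one length."""
    lengths = {len(rec) for rec in sset}
    if len(lengths) != 1:
        return None
    cached = sset.__dict__.get("_codes")
    if cached is not None and cached.shape[0] == len(sset):
        return cached
    codes = np.vstack([encode(rec.sequence) for rec in sset])
    sset.__dict__["_codes"] = codes
    return codes


def scan_set(
    pwm: PWM,
    sset: SequenceSet,
    cutoff: float,
    strands: str = "both",
) -> ScanResult:
    """Scan every record of a set; summarise genes with at least one hit."""
    if len(sset) == 0:
        raise ValidationError("cannot scan an empty sequence set")
    _check_cutoff(cutoff)
    wanted = _strand_list(strands)
    length = len(pwm)
    codes = _encoded_matrix(sset)
    if codes is not None and codes.shape[1] >= length:
        m = codes.shape[1]
        ids = np.asarray(sset.gene_ids, dtype=object)
        frames = []
        for strand in wanted:
            matrix = pwm if strand == "+" else pwm.reverse_complement()
            scores = _window_scores(matrix, codes)
            rows, cols = np.nonzero(scores >= cutoff)
            frames.append(
                pd.DataFrame(
                    {
                        "_row": rows,
                        "gene_id": ids[rows],
                        "motif_id": pwm.motif_id,
                        "start": cols.astype(np.int64) - m,
                        "end": cols.astype(np.int64) + length - 1 - m,
                        "strand": strand,
                        "score": scores[rows, cols],
                    }
                )
            )
        hits = pd.concat(frames, ignore_index=True)
        hits = hits.sort_values(
            ["_row", "start", "strand"], kind="stable", ignore_index=True
        ).drop(columns="_row")
    else:
        rows = []
        for rec in sset:
            rows.extend(scan_sequence(pwm, rec, cutoff, strands=strands))
        hits = pd.DataFrame(rows, columns=HIT_COLUMNS) if rows else _empty_hits()
    genes = set(hits["gene_id"]) if len(hits) else set()
    return ScanResult(hits=hits, n_genes=len(sset), genes_with_hit=genes)


def scan_library(
    pwms: list[PWM],
    sset: SequenceSet,
    cutoff: float,
    strands: str = "both",
) -> pd.DataFrame:
    """Concatenated hit table of a motif library over one set.

    An empty library yields an empty table.
    """
    if not pwms:
        return _empty_hits()
    frames = [scan_set(p, sset, cutoff, strands=strands).hits for p in pwms]
    return pd.concat(frames, ignore_index=True)


@dataclass
class PositionalHistogram:
    """Hit counts in fixed-width distance bins upstream of the TSS.

    Bin j covers the inclusive interval [-(j+1)*w, -j*w - 1]; a hit is
    assigned to the bin of its start (5'-most sense base).  The per-kb
    frequency normalises counts by the number of sequences scanned and by
    the bin width in kb; raw counts are always retained because either
    normalisation of a "frequency per kb" axis is defensible.
    """

    counts: np.ndarray
    bin_width: int
    extent: int
    n_sequences: int
    n_dropped: int = 0

    @property
    def freq_per_kb(self) -> np.ndarray:
        return self.counts / self.n_sequences / (self.bin_width / 1000.0)

    def to_frame(self) -> pd.DataFrame:
        j = np.arange(len(self.counts))
        return pd.DataFrame(
            {
                "bin_start": -(j + 1) * self.bin_width,
                "bin_end": -j * self.bin_width - 1,
                "count": self.counts,
                "freq_per_kb": self.freq_per_kb,
            }
        )


def positional_distribution(
    hits: pd.DataFrame,
    n_sequences: int,
    bin_width: int = 1000,
    extent: int = 10000,
) -> PositionalHistogram:
    """Bin hit start positions into distance-from-TSS windows."""
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    if extent <= 0 or extent % bin_width != 0:
        raise ValidationError(
            f"bin_width {bin_width} must divide extent {extent}"
        )
    if n_sequences < 1:
        raise ValidationError("n_sequences must be >= 1")
    n_bins = extent // bin_width
    starts = hits["start"].to_numpy(dtype=np.int64, copy=True)
    in_range = starts >= -extent
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info(
            "positional_distribution: dropped %d hit(s) beyond -%d bp",
            n_dropped,
            extent,
        )
    binned = (-starts[in_range] - 1) // bin_width
    counts = np.bincount(binned, minlength=n_bins).astype(np.int64)
    return PositionalHistogram(
        counts=counts,
        bin_width=bin_width,
        extent=extent,
        n_sequences=n_sequences,
        n_dropped=n_dropped,
    )


def write_hits(hits: pd.DataFrame, path) -> None:
    """Write hits as a BED-like 6-column TSV in TSS-relative coordinates."""
    out = hits[["gene_id", "start", "end", "motif_id", "score", "strand"]]
    out.to_csv(path, sep="\t", index=False)


def hits_with_offsets(hits: pd.DataFrame, sset: SequenceSet) -> pd.DataFrame:
    """Add 0-based half-open offsets from each sequence's 5' end."""
    lengths = hits["gene_id"].map(lambda g: len(sset[g]))
    out = hits.copy()
    out["offset_start"] = hits["start"] + lengths
    out["offset_end"] = hits["end"] + lengths + 1
    return out


def write_histogram(hist: PositionalHistogram, path) -> None:
    hist.to_frame().to_csv(path, sep="\t", index=False)
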