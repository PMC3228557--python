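"""Motif models: bracketed consensus strings and position weight matrices.

Both motif kinds are scored through a single similarity score.  For a PWM
with per-column base frequencies f_i, a window w of the motif's length L
gets the additive score S = sum_i f_i(w_i), which is min-max normalised:

    score = (S - S_min) / (S_max - S_min)

with S_max = sum_i max_b f_i(b) and S_min = sum_i min_b f_i(b).  The score
lies in [0, 1] and equals 1.0 exactly when every window base carries its
column's maximal frequency, so for consensus-derived matrices "score 1.0"
is literally a perfect match to the degenerate pattern.  An N in the
window contributes the column minimum (worst case), so N-rich sequence
cannot generate hits.  No pseudocounts and no log-odds are used: the score
is compared against absolute cutoffs, not likelihood ratios.
"""

from __future__ import annotations

import itertools
import os
import re
from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import motifs as bio_motifs

from .errors import ParseError, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4

#: maps ASCII codes of A/C/G/T/N to 0..4 (255 elsewhere)
ENCODING = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    ENCODING[ord(_b)] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as a uint8 vector (A=0,C=1,G=2,T=3,N=4)."""
    codes = ENCODING[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise ValidationError(
            f"illegal character {sequence[bad]!r} at position {bad}"
        )
    return codes


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate consensus: one allowed-base set per position."""

    motif_id: str
    pattern: tuple[frozenset, ...]
    source_text: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise ValidationError(f"motif {self.motif_id!r}: empty pattern")
        for i, posset in enumerate(self.pattern):
            if not posset or not set(posset) <= set(BASES):
                raise ValidationError(
                    f"motif {self.motif_id!r}: invalid position set at {i}"
                )

    def __len__(self) -> int:
        return len(self.pattern)

    def to_bracket(self) -> str:
        """Canonical bracket rendering (bases in A,C,G,T order)."""
        parts = []
        for posset in self.pattern:
            ordered = [b for b in BASES if b in posset]
            if len(ordered) == 1:
                parts.append(ordered[0])
            else:
                parts.append("[" + "/".join(ordered) + "]")
        return "".join(parts)

    @property
    def n_expansions(self) -> int:
        n = 1
        for posset in self.pattern:
            n *= len(posset)
        return n


def parse_consensus(text: str, motif_id: str | None = None) -> ConsensusMotif:
    """Parse a bracketed consensus such as ``AAAGA[G/C]A[A/C/T][T/G]``."""
    pattern: list[frozenset] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in BASES:
            pattern.append(frozenset(ch))
            i += 1
        elif ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise ParseError(f"unclosed bracket at offset {i} in {text!r}")
            group = text[i + 1 : end]
            bases = group.split("/")
            if not group or any(b not in BASES for b in bases):
                raise ParseError(
                    f"invalid bracket group {group!r} at offset {i} in {text!r}"
                )
            pattern.append(frozenset(bases))
            i = end + 1
        else:
            raise ParseError(
                f"unexpected character {ch!r} at offset {i} in {text!r}"
            )
    if not pattern:
        raise ParseError(f"empty consensus pattern {text!r}")
    return ConsensusMotif(motif_id or text, tuple(pattern), text)


def expand_consensus(motif: ConsensusMotif, max_expansions: int = 65536) -> set:
    """All exact strings matched by the pattern (the Cartesian product)."""
    if motif.n_expansions > max_expansions:
        raise ValidationError(
            f"motif {motif.motif_id!r}: {motif.n_expansions} expansions exceed "
            f"the bound {max_expansions}"
        )
    ordered = [sorted(posset) for posset in motif.pattern]
    return {"".join(choice) for choice in itertools.product(*ordered)}


class PWM:
    """A position weight matrix with min-max-normalised similarity scoring.

    ``matrix`` has shape (4, L): rows are A, C, G, T frequencies; every
    column sums to 1.  A matrix whose columns are all uniform has
    S_max == S_min and is rejected as unscorable.
    """

    def __init__(self, motif_id: str, matrix: np.ndarray, name: str = ""):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != 4 or matrix.shape[1] < 1:
            raise ValidationError(
                f"PWM {motif_id!r}: matrix must be 4 x L, got {matrix.shape}"
            )
        if (matrix < 0).any():
            raise ValidationError(f"PWM {motif_id!r}: negative frequencies")
        colsums = matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValidationError(
                f"PWM {motif_id!r}: column frequencies must sum to 1"
            )
        self.motif_id = motif_id
        self.name = name or motif_id
        self.matrix = matrix
        self.col_max = matrix.max(axis=0)
        self.col_min = matrix.min(axis=0)
        self.s_max = float(self.col_max.sum())
        self.s_min = float(self.col_min.sum())
        if not self.s_max > self.s_min:
            raise ValidationError(
                f"PWM {motif_id!r}: all columns uniform (S_max == S_min), "
                "unscorable"
            )
        # row 4 holds the worst-case contribution used for N bases
        self.lookup = np.vstack([matrix, self.col_min[None, :]])

    def __len__(self) -> int:
        return self.matrix.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PWM({self.motif_id!r}, L={len(self)})"

    def reverse_complement(self) -> "PWM":
        """The PWM scoring the reverse-complement strand.

        Columns are reversed and base rows complemented (A<->T, C<->G), so
        scanning the sense strand with it is equivalent to scoring the
        reverse complement of each window with the original matrix.
        """
        rc = self.matrix[::-1, ::-1]
        return PWM(self.motif_id, rc, name=self.name)


def consensus_to_pwm(motif: ConsensusMotif) -> PWM:
    """Uniform-frequency PWM over each position's allowed bases."""
    matrix = np.zeros((4, len(motif)))
    for j, posset in enumerate(motif.pattern):
        for b in posset:
            matrix[_BASE_INDEX[b], j] = 1.0 / len(posset)
    return PWM(motif.motif_id, matrix, name=motif.source_text)


def score_window(pwm: PWM, window: str) -> float:
    """Similarity score of one window of exactly the motif's length."""
    if len(window) != len(pwm):
        raise ValidationError(
            f"window length {len(window)} != motif length {len(pwm)}"
        )
    codes = encode(window)
    s = float(pwm.lookup[codes, np.arange(len(pwm))].sum())
    return (s - pwm.s_min) / (pwm.s_max - pwm.s_min)


_TRANSFAC_ROW = re.compile(r"^\d\d")


def _validate_transfac_text(text: str, origin: str) -> None:
    """Raise the errors Bio.motifs would swallow or report opaquely."""
    block, row_no = 1, 0
    terminated = True
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line == "//":
            terminated = True
            block += 1
            row_no = 0
            continue
        terminated = False
        if _TRANSFAC_ROW.match(line):
            row_no += 1
            fields = line.split()
            values = fields[1:]
            # an optional trailing consensus letter is ignored
            if values and not _is_number(values[-1]):
                values = values[:-1]
            if len(values) != 4 or not all(_is_number(v) for v in values):
                raise ParseError(
                    f"{origin}: block {block}, matrix row {row_no} "
                    f"(line {lineno}) does not have 4 numeric fields: {line!r}"
                )
    if not terminated:
        raise ParseError(f"{origin}: final block {block} lacks '//' terminator")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_transfac(path: str | os.PathLike) -> list:
    """Parse a TRANSFAC-style flat file into a list of PWMs.

    Expected blocks: AC/ID identifier lines, a ``P0 A C G T`` header,
    numbered count rows (optionally with a trailing consensus letter),
    terminated by ``//``.  Counts are normalised per column to
    frequencies; motif_id comes from AC, name from ID.
    """
    with open(path) as handle:
        text = handle.read()
    _validate_transfac_text(text, str(path))
    try:
        records = bio_motifs.parse(StringIO(text), "TRANSFAC")
    except Exception as exc:  # malformed headers etc.
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no TRANSFAC matrix blocks found")
    pwms = []
    for bi, rec in enumerate(records, 1):
        motif_id = rec.get("AC") or rec.get("ID") or f"block{bi}"
        name = rec.get("ID") or motif_id
        counts = np.array(
            [list(rec.counts[b]) for b in BASES], dtype=float
        )
        colsums = counts.sum(axis=0)
        zero_cols = np.nonzero(colsums == 0)[0]
        if zero_cols.size:
            raise ParseError(
                f"{path}: block {bi} ({motif_id}): all-zero count column "
                f"at matrix row {int(zero_cols[0]) + 1}"
            )
        pwms.append(PWM(motif_id, counts / colsums, name=name))
    return pwms


def read_consensus_tsv(path: str | os.PathLike) -> list:
    """Read a two-column TSV (motif_id, bracket pattern) of consensus motifs."""
    out = []
    seen = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            motif_id, pattern = fields[0].strip(), fields[1].strip()
            if motif_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate motif_id {motif_id!r}")
            seen.add(motif_id)
            out.append(parse_consensus(pattern, motif_id=motif_id))
    if not out:
        raise ParseError(f"{path}: no consensus motifs found")
    return out


#: the 9 bp HIPPI binding site consensus, the pipeline's canonical anchor
HBS_CONSENSUS = "AAAGA[G/C]A[A/C/T][T/G]"


def hbs_motif() -> ConsensusMotif:
    """The HIPPI binding site (HBS) consensus motif."""
    return parse_consensus(HBS_CONSENSUS, motif_id="HBS")
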