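"""Synthetic promoter sets with planted motifs and known ground truth.

The generator emulates the structure of a promoter-motif study without any
external data: i.i.d. background sequence with a single GC-content dial,
degenerate motif instances overwritten (never inserted, so lengths and TSS
anchoring are preserved) at controlled rates, positions and strands,
co-occurring motif pairs with gaps inside a window, flat annotation maps
with one designed enriched term, and differential-expression tables with a
known true-positive fraction.  Every function is deterministic given its
seed.

Planting rates for a target-versus-background design are specified as
*observed frequencies*: the target stratum is planted at its stated rate,
and the non-target remainder at the residual rate that makes the whole
background's motif frequency equal the stated background rate (see
``stratified_rates``).  A background rate equal to the target rate is
therefore a null design, and a design like "60 of 100 target genes versus
100 of 1000 background genes" is reproduced exactly in expectation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .motifs import ConsensusMotif, expand_consensus, HBS_CONSENSUS
from .sequences import SequenceSet, UpstreamSequence, reverse_complement

#: AP-1-style degenerate 7-mer used as the default synthetic secondary motif
SECONDARY_CONSENSUS = "TGA[C/G]TCA"

TRUTH_COLUMNS = ["gene_id", "motif_id", "start", "end", "strand", "site"]


@dataclass
class SimulationConfig:
    """Parameters of the full synthetic study (the CLI ``simulate`` stage).

    ``plant_rate_background`` is the motif frequency over the whole
    background set; ``plant_rate_target`` the frequency within the target
    subset.  ``position_model`` is one of ``fixed`` (at ``fixed_start``),
    ``uniform`` (over the sequence) or ``proximal`` (fraction
    ``proximal_fraction`` within ``proximal_extent`` bp of the TSS).
    """

    n_background: int = 2000
    n_target: int = 200
    length: int = 1000
    gc: float = 0.5
    seed: int = 0
    plant_rate_target: float = 0.5
    plant_rate_background: float = 0.05
    position_model: str = "uniform"
    fixed_start: int = -500
    proximal_fraction: float = 0.7
    proximal_extent: int = 2000
    strand_prob: float = 0.5
    window: int = 100
    anchor_pattern: str = HBS_CONSENSUS
    secondary_pattern: str = SECONDARY_CONSENSUS
    in_window_rate_target: float = 0.5
    in_window_rate_background: float = 0.05
    n_terms: int = 20
    enriched_target_coverage: float = 0.8
    enriched_background_coverage: float = 0.1
    n_de_genes: int = 2000
    de_true_fraction: float = 0.05

    def __post_init__(self) -> None:
        probs = [
            self.gc,
            self.plant_rate_target,
            self.plant_rate_background,
            self.strand_prob,
            self.proximal_fraction,
            self.in_window_rate_target,
            self.in_window_rate_background,
            self.enriched_target_coverage,
            self.enriched_background_coverage,
            self.de_true_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.n_target > self.n_background:
            raise ValidationError("n_target must not exceed n_background")
        if self.length < 1 or self.window < 0:
            raise ValidationError("invalid length or window")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def generate_promoters(
    n: int,
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    prefix: str = "g",
    name: str = "synthetic",
) -> SequenceSet:
    """n i.i.d. promoter sequences with P(G) + P(C) = gc, split evenly."""
    if not 0.0 <= gc <= 1.0:
        raise ValidationError(f"gc must lie in [0, 1], got {gc}")
    if n < 1 or length < 1:
        raise ValidationError("n and length must be >= 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    if gc == 0.5:
        codes = rng.integers(0, 4, size=(n, length))
    else:
        codes = rng.choice(4, size=(n, length), p=probs)
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    records = [
        UpstreamSequence(f"{prefix}{i + 1:06d}", letters[i].tobytes().decode("ascii"))
        for i in range(n)
    ]
    return SequenceSet(records, name=name)


def stratified_rates(
    gene_ids: list,
    target_ids: set,
    rate_target: float,
    rate_background: float,
) -> dict:
    """Per-gene planting rates realising the stated observed frequencies.

    Target genes get ``rate_target``; the remainder gets the residual rate
    that brings the whole set's expected frequency to ``rate_background``
    (clamped at 0 when the target stratum alone exceeds it).
    """
    n_total = len(gene_ids)
    n_target = sum(1 for g in gene_ids if g in target_ids)
    if n_target == n_total:
        return {g: rate_target for g in gene_ids}
    residual = (n_total * rate_background - n_target * rate_target) / (
        n_total - n_target
    )
    residual = min(1.0, max(0.0, residual))
    return {
        g: (rate_target if g in target_ids else residual) for g in gene_ids
    }


def _occupied_from_truth(truth: pd.DataFrame | None) -> dict:
    occupied: dict[str, list] = {}
    if truth is not None and len(truth):
        for gene, start, end in zip(truth["gene_id"], truth["start"], truth["end"]):
            occupied.setdefault(gene, []).append((int(start), int(end)))
    return occupied


def _overlaps(occupied: list, start: int, end: int) -> bool:
    return any(s <= end and start <= e for s, e in occupied)


def _plant_site(
    sequence: str,
    index: int,
    word: str,
    minus: bool,
) -> tuple[str, str]:
    site = reverse_complement(word) if minus else word
    return sequence[:index] + site + sequence[index + len(word) :], site


def plant_motif(
    sset: SequenceSet,
    motif: ConsensusMotif,
    rate,
    position_model: str = "uniform",
    fixed_start: int | None = None,
    proximal_fraction: float = 0.7,
    proximal_extent: int = 2000,
    strand_prob: float = 0.0,
    seed: int = 0,
    avoid: pd.DataFrame | None = None,
    max_retries: int = 100,
) -> tuple[SequenceSet, pd.DataFrame]:
    """Overwrite one motif instance into a Bernoulli-selected subset.

    ``rate`` is a probability or a per-gene mapping.  Each selected
    sequence receives one uniformly chosen expansion of the motif at a
    position drawn from the position model, reverse-complemented with
    probability ``strand_prob``.  Positions colliding with sites already
    planted (including those listed in ``avoid``) are resampled up to
    ``max_retries`` times.  Returns the new set plus a truth table of
    planted sites in TSS-relative coordinates.
    """
    rng = np.random.default_rng(seed)
    words = sorted(expand_consensus(motif))
    length = len(motif)
    occupied = _occupied_from_truth(avoid)
    rates = rate if isinstance(rate, dict) else {g: rate for g in sset.gene_ids}
    new_records = []
    truth_rows = []
    for rec in sset:
        gene_rate = rates.get(rec.gene_id, 0.0)
        if rng.random() >= gene_rate:
            new_records.append(rec)
            continue
        m = len(rec)
        if length > m:
            raise ValidationError(
                f"motif {motif.motif_id!r} (L={length}) does not fit in "
                f"record {rec.gene_id!r} (M={m})"
            )
        occ = occupied.setdefault(rec.gene_id, [])
        placed = False
        for _ in range(max_retries):
            index = _sample_position(
                rng,
                m,
                length,
                position_model,
                fixed_start,
                proximal_fraction,
                proximal_extent,
            )
            start, end = index - m, index + length - 1 - m
            if _overlaps(occ, start, end):
                continue
            word = words[rng.integers(len(words))]
            minus = rng.random() < strand_prob
            new_seq, site = _plant_site(rec.sequence, index, word, minus)
            new_records.append(UpstreamSequence(rec.gene_id, new_seq))
            truth_rows.append(
                {
                    "gene_id": rec.gene_id,
                    "motif_id": motif.motif_id,
                    "start": start,
                    "end": end,
                    "strand": "-" if minus else "+",
                    "site": site,
                }
            )
            occ.append((start, end))
            placed = True
            break
        if not placed:
            raise ValidationError(
                f"could not place motif {motif.motif_id!r} in record "
                f"{rec.gene_id!r} after {max_retries} retries"
            )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth["start"] = truth["start"].astype(np.int64)
    truth["end"] = truth["end"].astype(np.int64)
    return SequenceSet(new_records, name=sset.name), truth


def _sample_position(
    rng: np.random.Generator,
    m: int,
    length: int,
    model: str,
    fixed_start: int | None,
    proximal_fraction: float,
    proximal_extent: int,
) -> int:
    last = m - length  # largest admissible 0-based start index
    if model == "fixed":
        if fixed_start is None:
            raise ValidationError("position_model 'fixed' needs fixed_start")
        index = m + fixed_start
        if not 0 <= index <= last:
            raise ValidationError(
                f"fixed_start {fixed_start} does not fit a length-{length} "
                f"motif in a length-{m} sequence"
            )
        return index
    if model == "uniform":
        return int(rng.integers(0, last + 1))
    if model == "proximal":
        boundary = max(0, m - proximal_extent)
        if boundary == 0 or boundary > last:
            raise ValidationError(
                f"proximal model needs sequence length > proximal_extent "
                f"({m} vs {proximal_extent})"
            )
        if rng.random() < proximal_fraction:
            return int(rng.integers(boundary, last + 1))
        return int(rng.integers(0, boundary))
    raise ValidationError(f"unknown position model {model!r}")


COOCCUR_TRUTH_COLUMNS = TRUTH_COLUMNS + ["role", "gap"]


def plant_cooccurring(
    sset: SequenceSet,
    anchor: ConsensusMotif,
    secondary: ConsensusMotif,
    anchor_rate,
    in_window_rate,
    window: int = 100,
    strand_prob: float = 0.5,
    seed: int = 0,
) -> tuple[SequenceSet, pd.DataFrame]:
    """Plant anchor sites and, in a fraction of anchored genes, a secondary
    site with a gap uniform on [0, window] on a random side of the anchor.

    Both rates may be scalars or per-gene mappings.  Anchors are placed
    uniformly within the interior margin that guarantees the secondary
    fits on either side; anchor and secondary never overlap (gap >= 0).
    """
    if window < 0:
        raise ValidationError(f"window must be >= 0, got {window}")
    rng = np.random.default_rng(seed)
    a_words = sorted(expand_consensus(anchor))
    s_words = sorted(expand_consensus(secondary))
    l1, l2 = len(anchor), len(secondary)
    margin = window + l2
    a_rates = (
        anchor_rate
        if isinstance(anchor_rate, dict)
        else {g: anchor_rate for g in sset.gene_ids}
    )
    w_rates = (
        in_window_rate
        if isinstance(in_window_rate, dict)
        else {g: in_window_rate for g in sset.gene_ids}
    )
    new_records = []
    truth_rows = []
    for rec in sset:
        if rng.random() >= a_rates.get(rec.gene_id, 0.0):
            new_records.append(rec)
            continue
        m = len(rec)
        if m < l1 + 2 * margin:
            raise ValidationError(
                f"record {rec.gene_id!r} (M={m}) too short for anchor+window "
                f"design (needs {l1 + 2 * margin})"
            )
        i1 = int(rng.integers(margin, m - l1 - margin + 1))
        word = a_words[rng.integers(len(a_words))]
        minus = rng.random() < strand_prob
        seq, site = _plant_site(rec.sequence, i1, word, minus)
        truth_rows.append(
            {
                "gene_id": rec.gene_id,
                "motif_id": anchor.motif_id,
                "start": i1 - m,
                "end": i1 + l1 - 1 - m,
                "strand": "-" if minus else "+",
                "site": site,
                "role": "anchor",
                "gap": np.nan,
            }
        )
        if rng.random() < w_rates.get(rec.gene_id, 0.0):
            gap = int(rng.integers(0, window + 1))
            if rng.random() < 0.5:  # 3' of the anchor
                i2 = i1 + l1 + gap
            else:  # 5' of the anchor
                i2 = i1 - gap - l2
            s_word = s_words[rng.integers(len(s_words))]
            s_minus = rng.random() < strand_prob
            seq, s_site = _plant_site(seq, i2, s_word, s_minus)
            truth_rows.append(
                {
                    "gene_id": rec.gene_id,
                    "motif_id": secondary.motif_id,
                    "start": i2 - m,
                    "end": i2 + l2 - 1 - m,
                    "strand": "-" if s_minus else "+",
                    "site": s_site,
                    "role": "secondary",
                    "gap": float(gap),
                }
            )
        new_records.append(UpstreamSequence(rec.gene_id, seq))
    truth = pd.DataFrame(truth_rows, columns=COOCCUR_TRUTH_COLUMNS)
    if len(truth):
        truth["start"] = truth["start"].astype(np.int64)
        truth["end"] = truth["end"].astype(np.int64)
    return SequenceSet(new_records, name=sset.name), truth


def generate_annotation(
    genes: list,
    n_terms: int,
    target_genes,
    enriched_coverage: tuple = (0.8, 0.1),
    base_coverage: float = 0.1,
    seed: int = 0,
) -> tuple[dict, str]:
    """A flat term -> genes map with one designed enriched term.

    The enriched term covers ``enriched_coverage[0]`` of the target subset
    and ``enriched_coverage[1]`` of the remaining genes; the other
    n_terms - 1 terms sample ``base_coverage`` of all genes uniformly.
    Returns the map and the enriched term's id.
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    t_frac, b_frac = enriched_coverage
    for frac in (t_frac, b_frac, base_coverage):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("coverage fractions must lie in [0, 1]")
    genes = list(genes)
    target = [g for g in genes if g in set(target_genes)]
    rest = [g for g in genes if g not in set(target_genes)]
    if len(target) != len(set(target_genes)):
        raise ValidationError("target_genes must all be members of genes")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_terms)))
    enriched_id = f"T{1:0{width}d}"
    mapping: dict[str, set] = {}
    covered = set(rng.choice(target, size=round(t_frac * len(target)), replace=False))
    if rest:
        covered |= set(
            rng.choice(rest, size=round(b_frac * len(rest)), replace=False)
        )
    mapping[enriched_id] = covered
    for t in range(2, n_terms + 1):
        size = round(base_coverage * len(genes))
        mapping[f"T{t:0{width}d}"] = set(
            rng.choice(genes, size=size, replace=False)
        )
    return mapping, enriched_id


def generate_de_table(
    n_genes: int,
    true_fraction: float,
    alt_p=1e-4,
    alt_fold: float = 2.0,
    null_fold_sd: float = 0.05,
    null_p_min: float = 0.0,
    seed: int = 0,
    prefix: str = "g",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A differential-expression table with a known true-positive subset.

    True genes receive p-values from ``alt_p`` (a constant, or a callable
    ``(rng, size) -> array``) and fold changes away from 1 (alternating up
    at ``alt_fold`` and down at 1/``alt_fold``, with mild lognormal
    jitter); null genes get p uniform on [``null_p_min``, 1] and fold
    changes near 1.  The default ``null_p_min`` of 0 gives the fully
    uniform null; a positive value constructs a table whose nulls are
    provably outside any step-up selection at alpha below it, so that
    selection recovers the true subset exactly.  Returns (table, truth)
    where truth carries ``is_true`` and ``direction``.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if not 0.0 <= true_fraction <= 1.0:
        raise ValidationError("true_fraction must lie in [0, 1]")
    if not 0.0 <= null_p_min < 1.0:
        raise ValidationError("null_p_min must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    gene_ids = [f"{prefix}{i + 1:06d}" for i in range(n_genes)]
    n_true = round(true_fraction * n_genes)
    true_idx = set(rng.choice(n_genes, size=n_true, replace=False).tolist())
    if callable(alt_p):
        alt_values = iter(np.atleast_1d(alt_p(rng, n_true)))
    else:
        alt_values = iter(np.full(n_true, float(alt_p)))
    rows = []
    truth_rows = []
    up_next = True
    for i, gene in enumerate(gene_ids):
        if i in true_idx:
            p = float(next(alt_values))
            jitter = float(np.exp(rng.normal(0.0, 0.1)))
            fold = alt_fold * jitter if up_next else jitter / alt_fold
            direction = "up" if up_next else "down"
            up_next = not up_next
            truth_rows.append(
                {"gene_id": gene, "is_true": True, "direction": direction}
            )
        else:
            p = float(rng.uniform(null_p_min, 1.0))
            fold = float(np.exp(rng.normal(0.0, null_fold_sd)))
            truth_rows.append(
                {"gene_id": gene, "is_true": False, "direction": "none"}
            )
        rows.append({"gene_id": gene, "fold_change": fold, "p_value": p})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def derive_common_table(
    table_a: pd.DataFrame,
    truth_a: pd.DataFrame,
    diminished_fraction: float = 0.5,
    diminish: float = 0.3,
    jitter_sd: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A second-condition table in which a known subset of the truly
    altered genes shows a diminished fold change.

    Each true gene is flagged diminished with probability
    ``diminished_fraction``; its alteration magnitude is multiplied by
    ``1 - diminish`` (up genes' folds shrink, down genes' folds move
    toward 1).  All other folds get mild lognormal jitter.  Returns
    (table_b, truth) where truth marks the diminished genes.
    """
    if not 0.0 <= diminished_fraction <= 1.0 or not 0.0 < diminish < 1.0:
        raise ValidationError("invalid diminished_fraction or diminish")
    rng = np.random.default_rng(seed)
    is_true = dict(zip(truth_a["gene_id"], truth_a["is_true"]))
    rows = []
    truth_rows = []
    for gene, fold, p in zip(
        table_a["gene_id"], table_a["fold_change"], table_a["p_value"]
    ):
        diminished = bool(is_true.get(gene, False)) and (
            rng.random() < diminished_fraction
        )
        if diminished:
            if fold >= 1:
                new_fold = fold * (1.0 - diminish)
            else:
                new_fold = fold / (1.0 - diminish)
        else:
            new_fold = fold * float(np.exp(rng.normal(0.0, jitter_sd)))
        rows.append({"gene_id": gene, "fold_change": new_fold, "p_value": p})
        truth_rows.append({"gene_id": gene, "diminished": diminished})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_study(config: SimulationConfig) -> dict:
    """Generate the full synthetic study behind the pipeline stages.

    Returns a dict with the planted background SequenceSet, the target
    gene ids, the planted-site truth table, the annotation map and its
    enriched term, and the two differential tables with their truths.
    Seeds for the sub-generators are derived deterministically from
    ``config.seed``.
    """
    from .motifs import parse_consensus

    promoters = generate_promoters(
        config.n_background,
        config.length,
        gc=config.gc,
        seed=config.seed,
        name="background",
    )
    gene_ids = promoters.gene_ids
    target_ids = gene_ids[: config.n_target]
    anchor = parse_consensus(config.anchor_pattern, motif_id="anchor")
    secondary = parse_consensus(config.secondary_pattern, motif_id="secondary")
    anchor_rates = stratified_rates(
        gene_ids,
        set(target_ids),
        config.plant_rate_target,
        config.plant_rate_background,
    )
    window_rates = stratified_rates(
        gene_ids,
        set(target_ids),
        config.in_window_rate_target,
        config.in_window_rate_background,
    )
    planted, site_truth = plant_cooccurring(
        promoters,
        anchor,
        secondary,
        anchor_rate=anchor_rates,
        in_window_rate=window_rates,
        window=config.window,
        strand_prob=config.strand_prob,
        seed=config.seed + 1,
    )
    annotation, enriched_term = generate_annotation(
        gene_ids,
        config.n_terms,
        target_ids,
        enriched_coverage=(
            config.enriched_target_coverage,
            config.enriched_background_coverage,
        ),
        seed=config.seed + 2,
    )
    de_a, de_truth = generate_de_table(
        config.n_de_genes,
        config.de_true_fraction,
        seed=config.seed + 3,
    )
    de_b, common_truth = derive_common_table(
        de_a, de_truth, seed=config.seed + 4
    )
    return {
        "config": config,
        "sequences": planted,
        "target_ids": target_ids,
        "site_truth": site_truth,
        "anchor": anchor,
        "secondary": secondary,
        "annotation": annotation,
        "enriched_term": enriched_term,
        "de_table_a": de_a,
        "de_truth": de_truth,
        "de_table_b": de_b,
        "common_truth": common_truth,
    }
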