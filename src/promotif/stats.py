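"""Enrichment statistics: cumulative hypergeometric test, 2x2 chi-square,
Benjamini-Hochberg correction, and the gene-set analyses built on them.

All counting is at the gene level: k genes of an n-gene target set carry
a site (or annotation term) against K of the N-gene background, and the
target is always a subset of the background (nested urn).  The chi-square
test, whose textbook form wants two disjoint samples, contrasts the
target against the background excluding the target.  A motif or term is
called enriched when either the cumulative hypergeometric p or the
chi-square p falls below alpha; the BH-adjusted hypergeometric p across
the whole library is reported alongside.
"""

from __future__ import annotations

import logging
import os
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .motifs import PWM
from .scan import scan_set
from .sequences import SequenceSet, truncate_to_extent

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "item_id",
    "k",
    "n",
    "K",
    "N",
    "dataset_frequency",
    "background_frequency",
    "ratio",
    "p_hypergeom",
    "p_chisq",
    "p_adj",
    "significant",
    "flagged",
]


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValidationError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}: "
            "need 0 <= k <= min(n, K), n <= N, K <= N"
        )


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability that a uniform draw of n genes from an N-gene urn
    containing K successes yields at least the k successes observed.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(sp_stats.hypergeom.sf(k - 1, N, K, n))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table.

    Rows are target (a with site, b without) and background excluding the
    target (c, d).  A zero row or column margin makes the statistic
    undefined and is an error.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValidationError("chi-square counts must be non-negative")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValidationError(
            f"degenerate table ({a}, {b}, {c}, {d}): zero margin"
        )
    stat = n * (a * d - b * c) ** 2 / (
        margins[0] * margins[1] * margins[2] * margins[3]
    )
    return float(stat), float(sp_stats.chi2.sf(stat, df=1))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order.

    Sorted ascending, q_(i) = p_(i) * m / i with the running minimum
    enforced from the largest rank down and values capped at 1; ties share
    their rank block's adjusted value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    item_ids: Sequence[str],
    ks: Sequence[int],
    n: int,
    Ks: Sequence[int],
    N: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble enrichment records from gene-level counts.

    One row per item with dataset/background frequencies (%), the nested
    frequency ratio (k/n)/(K/N), both test p-values, the BH-adjusted
    hypergeometric p across items, and the either-test significance call.
    Items absent from the whole background (K = 0) are flagged: their
    ratio is undefined (NaN) and p is 1.
    """
    if len(item_ids) != len(ks) or len(item_ids) != len(Ks):
        raise ValidationError("item_ids, ks and Ks must have equal length")
    rows = []
    for item, k, K in zip(item_ids, ks, Ks):
        k, K = int(k), int(K)
        _check_counts(k, K, n, N)
        flagged = K == 0
        p_hyp = 1.0 if flagged else hypergeom_tail(k, K, n, N)
        try:
            _, p_chi = chi_square_2x2(k, n - k, K - k, (N - n) - (K - k))
        except ValidationError:
            p_chi = np.nan
        rows.append(
            {
                "item_id": item,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "dataset_frequency": 100.0 * k / n if n else np.nan,
                "background_frequency": 100.0 * K / N,
                "ratio": (k / n) / (K / N) if not flagged and n else np.nan,
                "p_hypergeom": p_hyp,
                "p_chisq": p_chi,
                "flagged": flagged,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p_hypergeom"].to_numpy())
    table["significant"] = (table["p_hypergeom"] < alpha) | (
        table["p_chisq"] < alpha
    )
    table.loc[table["flagged"], "significant"] = False
    return table[ENRICHMENT_COLUMNS].sort_values(
        ["p_hypergeom", "item_id"], kind="stable", ignore_index=True
    )


def motif_set_enrichment(
    target_genes: Iterable[str],
    background: SequenceSet,
    motif_library: Sequence[PWM],
    cutoff: float,
    extent: int | None = None,
    alpha: float = 0.05,
    strands: str = "both",
) -> pd.DataFrame:
    """Per-motif over-representation of sites in a target gene set.

    The background set (a superset of the target) is scanned once per
    motif on ``extent``-truncated sequences; k and K count genes with at
    least one hit.
    """
    target = set(target_genes)
    if not target:
        raise ValidationError("empty target gene set")
    universe = set(background.gene_ids)
    missing = target - universe
    if missing:
        raise ValidationError(
            f"target genes absent from background: {sorted(missing)[:5]}"
        )
    if not motif_library:
        raise ValidationError("empty motif library")
    sset = truncate_to_extent(background, extent) if extent else background
    ids, ks, Ks = [], [], []
    for pwm in motif_library:
        result = scan_set(pwm, sset, cutoff, strands=strands)
        ids.append(pwm.motif_id)
        Ks.append(len(result.genes_with_hit))
        ks.append(len(result.genes_with_hit & target))
    return enrichment_table(ids, ks, len(target), Ks, len(sset), alpha=alpha)


def annotation_enrichment(
    target_genes: Iterable[str],
    annotation: dict,
    background_genes: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term-by-term over-representation of a flat annotation map.

    ``annotation`` maps term id -> collection of gene ids (all within the
    background); the selection rule is BH-adjusted hypergeometric
    p < alpha, reported in the ``selected`` column.
    """
    if not annotation:
        raise ValidationError("empty annotation map")
    background = set(background_genes)
    target = set(target_genes)
    if not target <= background:
        raise ValidationError("target genes must be a subset of the background")
    stray = set().union(*annotation.values()) - background
    if stray:
        raise ValidationError(
            f"annotation genes absent from background: {sorted(stray)[:5]}"
        )
    terms = sorted(annotation)
    ks = [len(target & set(annotation[t])) for t in terms]
    Ks = [len(background & set(annotation[t])) for t in terms]
    table = enrichment_table(
        terms, ks, len(target), Ks, len(background), alpha=alpha
    )
    table["selected"] = table["p_adj"] < alpha
    return table


def read_annotation(path: str | os.PathLike) -> dict:
    """Read a flat term -> genes map.

    Two dialects are accepted: three-column TSV (term_id, term_name,
    gene_id — one pair per line) or two-column (term_id,
    comma-separated gene ids).
    """
    mapping: dict[str, set] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                term, _name, gene = fields
                mapping.setdefault(term, set()).add(gene.strip())
            elif len(fields) == 2:
                term, genes = fields
                mapping.setdefault(term, set()).update(
                    g.strip() for g in genes.split(",") if g.strip()
                )
            else:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns"
                )
    if not mapping:
        raise ValidationError(f"no annotation entries found in {path}")
    return mapping


# ---------------------------------------------------------------------------
# differential-expression list preparation


def read_differential_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV with header (gene_id, fold_change, p_value)."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fold_change", "p_value"}
    if not required <= set(table.columns):
        raise ValidationError(
            f"{path}: differential table needs columns {sorted(required)}"
        )
    return validate_differential_table(table)


def validate_differential_table(table: pd.DataFrame) -> pd.DataFrame:
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r} in differential table")
    p = table["p_value"]
    if ((p < 0) | (p > 1)).any() or p.isna().any():
        raise ValidationError("p_value column must lie in [0, 1]")
    return table


def _as_ratio(fold: float) -> float:
    """Normalise a fold change to the ratio scale (neutral = 1).

    Positive values are ratios already; negative values follow the signed
    convention -r == 1/r (r-fold down).  Zero is invalid.
    """
    if fold > 0:
        return fold
    if fold < 0:
        return -1.0 / fold
    raise ValidationError("fold_change of 0 is not a valid ratio")


def select_differential(
    table: pd.DataFrame,
    alpha: float = 0.05,
    correct: bool = True,
) -> tuple[set, set]:
    """Split the significantly altered genes into up- and down-regulated.

    When ``correct`` is true the p column is BH-adjusted first; genes with
    (adjusted) p < alpha are kept and split by fold-change direction.  A
    neutral fold change (exactly 1) with significant p belongs to neither
    direction and is counted in the log.
    """
    table = validate_differential_table(table)
    p = table["p_value"].to_numpy()
    if correct:
        p = benjamini_hochberg(p)
    selected = table.loc[p < alpha]
    up: set = set()
    down: set = set()
    neutral = 0
    for gene, fold in zip(selected["gene_id"], selected["fold_change"]):
        ratio = _as_ratio(float(fold))
        if ratio > 1:
            up.add(gene)
        elif ratio < 1:
            down.add(gene)
        else:
            neutral += 1
    if neutral:
        logger.info(
            "select_differential: %d significant gene(s) with neutral fold "
            "change assigned to neither direction",
            neutral,
        )
    return up, down


def select_common_set(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    cutoff_fraction: float = 0.10,
    alpha: float = 0.05,
    correct: bool = True,
) -> tuple[set, set]:
    """Genes whose alteration in condition A is diminished in condition B.

    A gene significantly up in A joins ``common_up`` when its fold change
    in B is reduced by at least ``cutoff_fraction`` relative to A
    (fold_B / fold_A <= 1 - cutoff_fraction); a gene significantly down in
    A joins ``common_down`` symmetrically on magnitudes
    (fold_A / fold_B <= 1 - cutoff_fraction).  Genes absent from B are
    excluded with a logged count.
    """
    if not 0 < cutoff_fraction < 1:
        raise ValidationError(
            f"cutoff_fraction must be in (0, 1), got {cutoff_fraction}"
        )
    up_a, down_a = select_differential(table_a, alpha=alpha, correct=correct)
    folds_b = {
        g: _as_ratio(float(f))
        for g, f in zip(table_b["gene_id"], table_b["fold_change"])
    }
    folds_a = {
        g: _as_ratio(float(f))
        for g, f in zip(table_a["gene_id"], table_a["fold_change"])
    }
    missing = 0
    common_up: set = set()
    common_down: set = set()
    for gene in up_a:
        if gene not in folds_b:
            missing += 1
            continue
        if folds_b[gene] / folds_a[gene] <= 1 - cutoff_fraction:
            common_up.add(gene)
    for gene in down_a:
        if gene not in folds_b:
            missing += 1
            continue
        if folds_a[gene] / folds_b[gene] <= 1 - cutoff_fraction:
            common_down.add(gene)
    if missing:
        logger.info(
            "select_common_set: %d selected gene(s) missing from the second "
            "table were excluded",
            missing,
        )
    return common_up, common_down


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
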