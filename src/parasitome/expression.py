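"""Count normalization, regulation sets, enrichment and ortholog comparison.

Normalization is the median-of-ratios size-factor scheme: per-gene geometric
means across samples form a pseudo-reference, and each sample's size factor
is the median ratio of its counts to that reference over genes with a
positive geometric mean.  Fold-change thresholds are strict ("more than
two-fold"); a gene expressed only during infection gets an infinite fold
change and belongs to every up-regulation set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from parasitome._util import pct, round_half_up
from parasitome.annotation import GeneFlags
from parasitome.clusters import classify_ssp

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Genes x samples counts plus (after normalization) size factors."""

    counts: pd.DataFrame
    conditions: Mapping[str, str]  # sample -> condition label
    species: Mapping[str, str] | None = None
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_for(self, condition: str) -> list[str]:
        out = [s for s in self.counts.columns if self.conditions[s] == condition]
        if not out:
            raise ValueError(f"no samples with condition {condition!r}")
        return out

    def condition_means(self, condition: str) -> pd.Series:
        if self.normalized is None:
            raise ValueError("table not normalized; call normalize_counts first")
        return self.normalized[self.samples_for(condition)].mean(axis=1)


@dataclass(frozen=True)
class RegulationSets:
    up2: frozenset[str]
    down2: frozenset[str]
    up10: frozenset[str]
    down10: frozenset[str]
    fold_change: Mapping[str, float]  # may contain inf; undefined genes absent
    top_decile: frozenset[str] = frozenset()

    def with_top_decile(self, genes: Iterable[str]) -> "RegulationSets":
        return replace(self, top_decile=frozenset(genes))


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    expr_a: float
    expr_b: float
    qvalue: float | None = None

    @property
    def ratio(self) -> float | None:
        if self.expr_b > 0:
            return self.expr_a / self.expr_b
        return math.inf if self.expr_a > 0 else None


def normalize_counts(table: ExpressionTable) -> ExpressionTable:
    """Median-of-ratios size factors; errors if a sample is all zeros."""
    counts = table.counts
    zero_samples = [s for s in counts.columns if (counts[s] == 0).all()]
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples}")
    with np.errstate(divide="ignore"):
        logs = np.log(counts.values.astype(float))
    log_geomean = logs.mean(axis=1)  # -inf for genes with any zero count
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = np.exp(logs[usable] - log_geomean[usable, None])
    size_factors = pd.Series(
        np.median(ratios, axis=0), index=counts.columns, name="size_factor"
    )
    normalized = counts / size_factors
    return ExpressionTable(
        counts=counts,
        conditions=table.conditions,
        species=table.species,
        size_factors=size_factors,
        normalized=normalized,
    )


def regulation_sets(
    table: ExpressionTable,
    control_label: str,
    infection_label: str,
) -> RegulationSets:
    """Fold-change gene sets: FC = mean normalized infection / control.

    Strict thresholds: up2 iff FC > 2, up10 iff FC > 10; down sets use the
    reciprocal.  Genes with both means zero are excluded; control-only zeros
    give FC = +inf (member of both up sets).
    """
    if table.normalized is None:
        table = normalize_counts(table)
    control = table.condition_means(control_label)
    infection = table.condition_means(infection_label)
    up2, down2, up10, down10 = set(), set(), set(), set()
    fold_change: dict[str, float] = {}
    for gid in table.counts.index:
        c, i = control[gid], infection[gid]
        if c == 0 and i == 0:
            continue
        fc = math.inf if c == 0 else i / c
        fold_change[gid] = fc
        if fc > 2:
            up2.add(gid)
            if fc > 10:
                up10.add(gid)
        elif fc < 0.5:
            down2.add(gid)
            if fc < 0.1:
                down10.add(gid)
    return RegulationSets(
        up2=frozenset(up2),
        down2=frozenset(down2),
        up10=frozenset(up10),
        down10=frozenset(down10),
        fold_change=fold_change,
    )


def top_expressed(
    table: ExpressionTable, condition_label: str, fraction: float = 0.10
) -> frozenset[str]:
    """The top floor(fraction * n_expressed) genes by mean normalized
    expression in the condition; ties broken by ascending gene_id."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if table.normalized is None:
        table = normalize_counts(table)
    means = table.condition_means(condition_label)
    expressed = means[means > 0]
    n = math.floor(fraction * len(expressed))
    ranked = sorted(expressed.items(), key=lambda kv: (-kv[1], kv[0]))
    return frozenset(gid for gid, _ in ranked[:n])


def enrichment_test(
    hits_in_set: int, set_size: int, hits_in_background: int, background_size: int
) -> float:
    """Upper-tail hypergeometric P(X >= hits_in_set)."""
    if not 0 <= hits_in_set <= set_size <= background_size:
        raise ValueError("inconsistent set sizes")
    if hits_in_set > hits_in_background or hits_in_background > background_size:
        raise ValueError("inconsistent hit counts")
    return float(
        hypergeom.sf(hits_in_set - 1, background_size, hits_in_background, set_size)
    )


def infection_report(
    sets: RegulationSets,
    flags: Mapping[str, GeneFlags],
    alpha: float = 0.001,
    max_len_aa: int = 300,
) -> dict:
    """Composition of the focal infection set (up10 ∩ top decile).

    Counts and percentages of secreted, SSP, expanded-family and category
    membership among the focal genes, with upper-tail hypergeometric
    enrichment P-values against the full flags universe.
    """
    focal = sorted(set(sets.up10) & set(sets.top_decile))
    background = list(flags)
    is_ssp, n_secreted_bg, n_ssp_bg = classify_ssp(flags, max_len_aa)
    n_expanded_bg = sum(1 for f in flags.values() if f.expanded_family)
    n_focal = len(focal)

    def class_stats(hits_focal: int, hits_bg: int, ndigits: int) -> dict:
        entry = {
            "n": hits_focal,
            "pct": pct(hits_focal, n_focal, ndigits) if n_focal else None,
        }
        if n_focal and hits_bg:
            entry["p_enrichment"] = enrichment_test(
                hits_focal, n_focal, hits_bg, len(background)
            )
            entry["significant"] = entry["p_enrichment"] < alpha
        else:
            entry["p_enrichment"] = None
            entry["significant"] = None
        return entry

    n_sec = sum(1 for gid in focal if flags[gid].secreted)
    n_ssp = sum(1 for gid in focal if is_ssp[gid])
    n_exp = sum(1 for gid in focal if flags[gid].expanded_family)
    report = {
        "n_focal": n_focal,
        "secreted": class_stats(n_sec, n_secreted_bg, 0),
        "ssp": class_stats(n_ssp, n_ssp_bg, 0),
        "expanded_family": class_stats(n_exp, n_expanded_bg, 0),
        "categories": {},
    }
    for category in ("core", "lineage_specific", "species_specific", "unclassified"):
        hits_focal = sum(1 for gid in focal if flags[gid].category == category)
        hits_bg = sum(1 for f in flags.values() if f.category == category)
        report["categories"][category] = class_stats(hits_focal, hits_bg, 1)
    return report


def ortholog_compare(
    pairs: Sequence[OrthologPair],
    fold_threshold: float = 10.0,
    qvalue_cutoff: float = 0.01,
) -> tuple[dict[tuple[str, str], str], dict]:
    """Classify ortholog pairs by cross-species expression ratio.

    ``a_up`` iff ratio > fold_threshold (strict), ``b_up`` iff ratio <
    1/fold_threshold, else ``neither``.  Pairs with both expressions zero
    are excluded with a warning.  The significant-pair percentage uses the
    provided q-value column when present, rounded to zero decimals.
    """
    classes: dict[tuple[str, str], str] = {}
    n_sig = 0
    any_q = False
    for pair in pairs:
        ratio = pair.ratio
        if ratio is None:
            logger.warning(
                "ortholog pair (%s, %s) has zero expression in both species; excluded",
                pair.gene_a,
                pair.gene_b,
            )
            continue
        if ratio > fold_threshold:
            cls = "a_up"
        elif ratio < 1.0 / fold_threshold:
            cls = "b_up"
        else:
            cls = "neither"
        classes[(pair.gene_a, pair.gene_b)] = cls
        if pair.qvalue is not None:
            any_q = True
            if pair.qvalue < qvalue_cutoff:
                n_sig += 1
    n_pairs = len(classes)
    summary = {
        "n_pairs": n_pairs,
        "n_a_up": sum(1 for c in classes.values() if c == "a_up"),
        "n_b_up": sum(1 for c in classes.values() if c == "b_up"),
        "n_neither": sum(1 for c in classes.values() if c == "neither"),
        "n_significant": n_sig if any_q else None,
        "pct_significant": pct(n_sig, n_pairs, 0) if any_q and n_pairs else None,
    }
    return classes, summary


def read_counts_tsv(
    path: str, design: Mapping[str, str]
) -> ExpressionTable:
    """Read a gene x sample counts TSV (first column gene_id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(counts=counts, conditions=dict(design))


def write_counts_tsv(table: ExpressionTable, path: str) -> None:
    table.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_ortholog_pairs_tsv(path: str) -> list[OrthologPair]:
    """Two-column (gene_a, gene_b) TSV with optional expr_a/expr_b/qvalue."""
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            OrthologPair(
                gene_a=str(row.gene_a),
                gene_b=str(row.gene_b),
                expr_a=float(getattr(row, "expr_a", 0.0)),
                expr_b=float(getattr(row, "expr_b", 0.0)),
                qvalue=None
                if not hasattr(row, "qvalue") or pd.isna(row.qvalue)
                else float(row.qvalue),
            )
        )
    return pairs
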