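"""Tandem-duplication detection, permutation null, TE proximity, duplicates.

Tandem duplication: two or more genes adjacent in the start-sorted gene
order of a contig sharing the same (non-null) family id.  The permutation
null shuffles family labels over gene positions (contig gene counts fixed)
and uses the add-one Monte-Carlo estimator P = (1 + k) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from parasitome._util import pct
from parasitome.annotation import GenomeAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TandemRun:
    contig: str
    gene_ids: tuple[str, ...]
    family_id: str


@dataclass(frozen=True)
class TandemResult:
    pairs: tuple[tuple[str, str], ...]
    runs: tuple[TandemRun, ...]
    n_pairs: int
    n_genes: int  # distinct genes involved in pairs
    pct_genes: float | None  # percent of all genes, rounded half-up 1 decimal
    p_value: float | None


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity: float
    aligned_length: int


def find_tandem_pairs(ann: GenomeAnnotation, same_strand: bool = False) -> TandemResult:
    """Scan start-sorted gene lists for adjacent same-family pairs and runs."""
    pairs: list[tuple[str, str]] = []
    runs: list[TandemRun] = []
    for contig, genes in ann.genes_by_contig.items():
        current: list = []

        def close() -> None:
            if len(current) >= 2:
                runs.append(
                    TandemRun(
                        contig=contig,
                        gene_ids=tuple(g.gene_id for g in current),
                        family_id=ann.flags[current[0].gene_id].family_id,
                    )
                )
                for a, b in itertools.pairwise(current):
                    pairs.append((a.gene_id, b.gene_id))
            current.clear()

        for gene in genes:
            fam = ann.flags[gene.gene_id].family_id
            if current:
                prev = current[-1]
                prev_fam = ann.flags[prev.gene_id].family_id
                joined = fam is not None and fam == prev_fam
                if joined and same_strand and gene.strand != prev.strand:
                    joined = False
                if joined:
                    current.append(gene)
                    continue
                close()
            if fam is not None:
                current.append(gene)
        close()

    n_genes = sum(len(r.gene_ids) for r in runs)
    return TandemResult(
        pairs=tuple(pairs),
        runs=tuple(runs),
        n_pairs=len(pairs),
        n_genes=n_genes,
        pct_genes=pct(n_genes, ann.n_genes, 1),
        p_value=None,
    )


def _family_codes(ann: GenomeAnnotation) -> tuple[np.ndarray, list[int]]:
    """Integer family labels in gene order; null families get unique codes
    (so they can never form a pair), plus per-contig gene counts."""
    labels: list[int] = []
    sizes: list[int] = []
    fam_code: dict[str, int] = {}
    next_singleton = -1
    for contig, genes in ann.genes_by_contig.items():
        sizes.append(len(genes))
        for gene in genes:
            fam = ann.flags[gene.gene_id].family_id
            if fam is None:
                labels.append(next_singleton)
                next_singleton -= 1
            else:
                labels.append(fam_code.setdefault(fam, len(fam_code)))
    return np.asarray(labels, dtype=np.int64), sizes


def _count_pairs_matrix(mat: np.ndarray, valid: np.ndarray) -> np.ndarray:
    eq = (mat[:, 1:] == mat[:, :-1]) & valid
    return eq.sum(axis=1)


def tandem_permutation_test(
    ann: GenomeAnnotation,
    n_perm: int = 1000,
    seed: int = 0,
    per_contig: bool = False,
    batch: int = 250,
) -> float:
    """Monte-Carlo P-value for the observed number of tandem pairs.

    Family labels are shuffled uniformly over all gene positions genome-wide
    by default (``per_contig=True`` restricts shuffling within each contig);
    contig gene counts are fixed either way.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels, sizes = _family_codes(ann)
    n = len(labels)
    if n < 2:
        return 1.0
    # adjacent positions that straddle a contig boundary never pair
    valid = np.ones(n - 1, dtype=bool)
    boundary = np.cumsum(sizes)[:-1]
    valid[boundary - 1] = False

    observed = int(_count_pairs_matrix(labels[None, :], valid)[0])
    rng = np.random.default_rng(seed)
    k = 0
    remaining = n_perm
    while remaining > 0:
        b = min(batch, remaining)
        mat = np.tile(labels, (b, 1))
        if per_contig:
            start = 0
            for size in sizes:
                mat[:, start : start + size] = rng.permuted(
                    mat[:, start : start + size], axis=1
                )
                start += size
        else:
            mat = rng.permuted(mat, axis=1)
        k += int(np.sum(_count_pairs_matrix(mat, valid) >= observed))
        remaining -= b
    return (1 + k) / (1 + n_perm)


# ---------------------------------------------------------------------------
# TE proximity
# ---------------------------------------------------------------------------


def interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Edge-to-edge distance of two 1-based inclusive intervals; 0 on overlap."""
    if a[1] < b[0]:
        return b[0] - a[1]
    if b[1] < a[0]:
        return a[0] - b[1]
    return 0


def te_proximity(
    ann: GenomeAnnotation,
    result: TandemResult,
    te_intervals: Mapping[str, Sequence[tuple[int, int]]],
    max_dist_bp: int = 10000,
) -> tuple[int, dict[str, bool]]:
    """Count tandem genes within ``max_dist_bp`` (strict) of a TE interval."""
    known = set(ann.genes_by_contig)
    for contig in te_intervals:
        if contig not in known:
            logger.warning("TE intervals on unknown contig %s ignored", contig)
    tandem_ids = {gid for run in result.runs for gid in run.gene_ids}
    near: dict[str, bool] = {}
    by_gene = {g.gene_id: g for g in ann.iter_genes()}
    for gid in sorted(tandem_ids):
        gene = by_gene[gid]
        intervals = te_intervals.get(gene.contig, ())
        near[gid] = any(
            interval_distance((gene.start, gene.end), te) < max_dist_bp
            for te in intervals
        )
    return sum(near.values()), near


def read_te_intervals(path: str, fmt: str | None = None) -> dict[str, list[tuple[int, int]]]:
    """Read TE intervals from BED (0-based half-open) or GFF3 (1-based incl.).

    Format inferred from the extension unless ``fmt`` is 'bed' or 'gff3'.
    Returned intervals are 1-based inclusive.
    """
    if fmt is None:
        fmt = "bed" if str(path).lower().endswith(".bed") else "gff3"
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if fmt == "bed":
                contig, start, end = cols[0], int(cols[1]) + 1, int(cols[2])
            else:
                contig, start, end = cols[0], int(cols[3]), int(cols[4])
            out.setdefault(contig, []).append((start, end))
    return out


# ---------------------------------------------------------------------------
# Pairwise identity (affine-gap global alignment)
# ---------------------------------------------------------------------------

_SCORE_SHIFT = 40
_MATCH_SHIFT = 20
_COL_MASK = (1 << _MATCH_SHIFT) - 1
_NEG = -(1 << 58)
_MAX_LEN = (1 << 19) - 4


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
) -> tuple[float, int]:
    """Global alignment identity: matches / alignment columns.

    ``gap_open`` is the cost of a gap's first position, ``gap_extend`` of
    each subsequent one.  Among optimal-score alignments the one with the
    most matches (then fewest columns) defines identity — the whole
    optimization is one lexicographic dynamic program over packed integers
    (score, matches, -columns).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) + len(seq_b) > _MAX_LEN:
        raise ValueError("sequences too long for packed alignment DP")
    a = np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)
    n, m = len(a), len(b)

    go_step = (gap_open << _SCORE_SHIFT) - 1
    ge_step = (gap_extend << _SCORE_SHIFT) - 1
    match_step = (match << _SCORE_SHIFT) + (1 << _MATCH_SHIFT) - 1
    mismatch_step = (mismatch << _SCORE_SHIFT) - 1

    # row 0
    M_prev = np.full(m + 1, _NEG, dtype=np.int64)
    X_prev = np.full(m + 1, _NEG, dtype=np.int64)
    Y_prev = np.full(m + 1, _NEG, dtype=np.int64)
    M_prev[0] = 0
    j_idx = np.arange(1, m + 1, dtype=np.int64)
    Y_prev[1:] = go_step + (j_idx - 1) * ge_step

    x_head = _NEG  # X[i][0]
    for i in range(1, n + 1):
        diag = np.where(b == a[i - 1], match_step, mismatch_step)
        best_prev = np.maximum(np.maximum(M_prev, X_prev), Y_prev)

        M_cur = np.full(m + 1, _NEG, dtype=np.int64)
        M_cur[1:] = best_prev[:-1] + diag

        X_cur = np.maximum(
            np.maximum(M_prev, Y_prev) + go_step, X_prev + ge_step
        )
        x_head = go_step if i == 1 else x_head + ge_step
        X_cur[0] = x_head

        # Y_cur[j] = max(max(M_cur, X_cur)[j-1] + go, Y_cur[j-1] + ge): a scan
        B = np.maximum(M_cur, X_cur) + go_step
        C = np.maximum.accumulate(B[:-1] - j_idx * ge_step)
        Y_cur = np.full(m + 1, _NEG, dtype=np.int64)
        Y_cur[1:] = C + j_idx * ge_step

        M_prev, X_prev, Y_prev = M_cur, X_cur, Y_cur

    final = int(max(M_prev[m], X_prev[m], Y_prev[m]))
    packed = final + (1 << _MATCH_SHIFT)  # un-borrow the columns component
    score = packed >> _SCORE_SHIFT
    rem = packed - (score << _SCORE_SHIFT)
    matches = rem >> _MATCH_SHIFT
    columns = (1 << _MATCH_SHIFT) - (rem & _COL_MASK)
    return matches / columns, columns


def recent_duplicates(
    ann: GenomeAnnotation,
    min_len_bp: int = 400,
    min_identity: float = 0.80,
    gene_ids: Sequence[str] | None = None,
) -> list[DuplicatePair]:
    """All unordered gene pairs with both CDS > ``min_len_bp`` (strict) and
    alignment identity >= ``min_identity`` (inclusive), by descending identity."""
    genes = [
        g
        for g in ann.iter_genes()
        if len(g.cds) > min_len_bp and (gene_ids is None or g.gene_id in set(gene_ids))
    ]
    out: list[DuplicatePair] = []
    for ga, gb in itertools.combinations(genes, 2):
        identity, aligned = pairwise_identity(ga.cds, gb.cds)
        if identity >= min_identity:
            out.append(
                DuplicatePair(
                    gene_a=ga.gene_id,
                    gene_b=gb.gene_id,
                    identity=identity,
                    aligned_length=aligned,
                )
            )
    out.sort(key=lambda p: (-p.identity, p.gene_a, p.gene_b))
    return out
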