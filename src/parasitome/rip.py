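"""Dinucleotide counting, RIP indices, stop-codon bias and fold changes.

Two indices are computed per sequence:

- ``tpa_apt``: N(TA)/N(AT); values >= 0.89 are called RIP-affected
  (enrichment in mutation products);
- ``composite``: (N(CA)+N(TG))/(N(AC)+N(GT)); values <= 1.03 are called
  RIP-affected (depletion of mutation targets).

Both are strand-symmetric: TA and AT are their own reverse complements and
{CA,TG} / {AC,GT} are reverse-complement-closed pairs, so the orientation
of the input sequence is immaterial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from parasitome._util import pct, round_half_up
from parasitome.annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

TPA_APT_THRESHOLD = 0.89  # affected iff index >= threshold
COMPOSITE_THRESHOLD = 1.03  # affected iff index <= threshold

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

# byte-value -> base code; anything not ACGT (incl. N) -> 4 and is skipped
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


@dataclass(frozen=True)
class RipResult:
    """Per-sequence dinucleotide counts, both indices and threshold calls."""

    seq_id: str
    dinucleotide_counts: Mapping[str, int]
    tpa_apt: float | None
    composite: float | None
    affected_tpa: str  # affected | unaffected | undefined
    affected_composite: str


@dataclass(frozen=True)
class RipScan:
    results: tuple[RipResult, ...]
    index: str
    n_affected: int
    n_total: int
    pct_affected: float | None  # percent, rounded half-up


@dataclass(frozen=True)
class StopCodonCensus:
    n_genes: int
    taa: int
    tag: int
    tga: int
    other: int
    taa_tga_ratio: float | None  # rounded half-up, 1 decimal
    tag_tga_ratio: float | None


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Counts of all 16 dinucleotides over overlapping width-2 windows.

    Windows containing a non-ACGT character (e.g. N) are skipped; counting
    is case-insensitive.  Sequences shorter than 2 give all zeros.
    """
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    if len(seq) < 2:
        return counts
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    a, b = codes[:-1], codes[1:]
    valid = (a < 4) & (b < 4)
    pair_codes = a[valid].astype(np.intp) * 4 + b[valid]
    binned = np.bincount(pair_codes, minlength=16)
    for i, dn in enumerate(DINUCLEOTIDES):
        counts[dn] = int(binned[i])
    return counts


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def tpa_apt_index(seq: str) -> float | None:
    """N(TA)/N(AT); None (undefined) when N(AT) = 0."""
    c = dinucleotide_counts(seq)
    return _ratio(c["TA"], c["AT"])


def composite_rip_index(seq: str) -> float | None:
    """(N(CA)+N(TG))/(N(AC)+N(GT)); None when the denominator is 0."""
    c = dinucleotide_counts(seq)
    return _ratio(c["CA"] + c["TG"], c["AC"] + c["GT"])


def rip_result(seq_id: str, seq: str) -> RipResult:
    c = dinucleotide_counts(seq)
    tpa = _ratio(c["TA"], c["AT"])
    comp = _ratio(c["CA"] + c["TG"], c["AC"] + c["GT"])
    if tpa is None:
        call_tpa = "undefined"
    else:
        call_tpa = "affected" if tpa >= TPA_APT_THRESHOLD else "unaffected"
    if comp is None:
        call_comp = "undefined"
    else:
        call_comp = "affected" if comp <= COMPOSITE_THRESHOLD else "unaffected"
    return RipResult(seq_id, c, tpa, comp, call_tpa, call_comp)


def classify_rip_genes(
    ann: GenomeAnnotation,
    index: str = "tpa_apt",
    gene_ids: Iterable[str] | None = None,
    ndigits: int = 1,
) -> RipScan:
    """Per-gene RIP calls on CDS sequences plus the affected fraction.

    Genes with an undefined index (or no CDS) count in the denominator but
    are never called affected.  The fraction is a percent rounded half-up.
    """
    if index not in ("tpa_apt", "composite"):
        raise ValueError(f"unknown index {index!r}")
    universe = set(gene_ids) if gene_ids is not None else None
    results: list[RipResult] = []
    for gene in ann.iter_genes():
        if universe is not None and gene.gene_id not in universe:
            continue
        if not gene.cds:
            logger.warning("gene %s has no CDS; RIP index undefined", gene.gene_id)
        results.append(rip_result(gene.gene_id, gene.cds))
    attr = "affected_tpa" if index == "tpa_apt" else "affected_composite"
    n_aff = sum(1 for r in results if getattr(r, attr) == "affected")
    return RipScan(
        results=tuple(results),
        index=index,
        n_affected=n_aff,
        n_total=len(results),
        pct_affected=pct(n_aff, len(results), ndigits),
    )


def stop_codon_census(
    ann: GenomeAnnotation, gene_set: Iterable[str] | None = None
) -> StopCodonCensus:
    """Census of terminal stop codons (final 3 nt of each CDS, uppercased)."""
    universe = set(gene_set) if gene_set is not None else None
    taa = tag = tga = other = 0
    for gene in ann.iter_genes():
        if universe is not None and gene.gene_id not in universe:
            continue
        stop = gene.cds[-3:].upper() if len(gene.cds) >= 3 else ""
        if stop == "TAA":
            taa += 1
        elif stop == "TAG":
            tag += 1
        elif stop == "TGA":
            tga += 1
        else:
            other += 1
    n = taa + tag + tga + other
    return StopCodonCensus(
        n_genes=n,
        taa=taa,
        tag=tag,
        tga=tga,
        other=other,
        taa_tga_ratio=round_half_up(taa / tga, 1) if tga else None,
        tag_tga_ratio=round_half_up(tag / tga, 1) if tga else None,
    )


def dinucleotide_foldchange(
    target_seqs: Sequence[str], control_seqs: Sequence[str]
) -> dict[str, float | None]:
    """log10 fold change of pooled dinucleotide frequencies, target/control.

    Frequencies are pooled counts over each set divided by the pooled number
    of valid windows; the fold change is None when either frequency is 0.
    """
    if not target_seqs or not control_seqs:
        raise ValueError("both sequence sets must be non-empty")

    def pooled(seqs: Sequence[str]) -> tuple[dict[str, int], int]:
        total = dict.fromkeys(DINUCLEOTIDES, 0)
        for s in seqs:
            for dn, c in dinucleotide_counts(s).items():
                total[dn] += c
        return total, sum(total.values())

    t_counts, t_tot = pooled(target_seqs)
    c_counts, c_tot = pooled(control_seqs)
    if t_tot == 0 or c_tot == 0:
        raise ValueError("sequence set contains no countable windows")
    out: dict[str, float | None] = {}
    for dn in DINUCLEOTIDES:
        ft = t_counts[dn] / t_tot
        fc = c_counts[dn] / c_tot
        out[dn] = math.log10(ft / fc) if ft > 0 and fc > 0 else None
    return out


def compare_rip_fractions(
    affected_a: int, total_a: int, affected_b: int, total_b: int
) -> float:
    """One-sided Fisher exact P that fraction a exceeds fraction b."""
    for aff, tot in ((affected_a, total_a), (affected_b, total_b)):
        if tot == 0:
            raise ValueError("total must be positive")
        if not 0 <= aff <= tot:
            raise ValueError("affected count outside [0, total]")
    table = [
        [affected_a, total_a - affected_a],
        [affected_b, total_b - affected_b],
    ]
    return float(fisher_exact(table, alternative="greater")[1])
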