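"""SSP classification and secreted-protein gene-cluster detection.

A cluster is a maximal chain of secreted genes on one contig in which
consecutive secreted genes are separated by at most one non-secreted gene,
reported when the chain holds at least three secreted genes.  Cluster
members run from the first to the last secreted gene inclusive, so clusters
always start and end on secreted genes and never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from parasitome._util import pct
from parasitome.annotation import GeneFlags, GenomeAnnotation

SSP_MAX_LEN_AA = 300  # SSP iff secreted and protein length strictly below


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: int
    contig: str
    member_gene_ids: tuple[str, ...]  # genomic order, first/last secreted
    n_secreted: int
    n_nonsecreted: int
    n_ssp: int

    @property
    def span_genes(self) -> int:
        return self.n_secreted + self.n_nonsecreted


def classify_ssp(
    flags: Mapping[str, GeneFlags], max_len_aa: int = SSP_MAX_LEN_AA
) -> tuple[dict[str, bool], int, int]:
    """Per-gene SSP call plus (n_secreted, n_ssp) totals.

    SSP iff secreted and protein_length < max_len_aa (strict).
    """
    is_ssp = {
        gid: f.secreted and f.protein_length < max_len_aa for gid, f in flags.items()
    }
    n_secreted = sum(1 for f in flags.values() if f.secreted)
    return is_ssp, n_secreted, sum(is_ssp.values())


def cysteine_rich(
    flags: Mapping[str, GeneFlags], gene_set: Iterable[str], min_cys: int = 5
) -> int:
    """Number of genes in ``gene_set`` with at least ``min_cys`` cysteines."""
    return sum(1 for gid in set(gene_set) if flags[gid].cysteines >= min_cys)


def detect_clusters(
    ann: GenomeAnnotation, max_len_aa: int = SSP_MAX_LEN_AA
) -> list[GeneCluster]:
    """Detect secreted-protein gene clusters (gap <= 1, >= 3 secreted)."""
    is_ssp, _, _ = classify_ssp(ann.flags, max_len_aa)
    clusters: list[GeneCluster] = []
    for contig, genes in ann.genes_by_contig.items():
        secreted_idx = [
            i for i, g in enumerate(genes) if ann.flags[g.gene_id].secreted
        ]
        chain: list[int] = []

        def close() -> None:
            if len(chain) >= 3:
                members = genes[chain[0] : chain[-1] + 1]
                ids = tuple(g.gene_id for g in members)
                n_sec = len(chain)
                clusters.append(
                    GeneCluster(
                        cluster_id=len(clusters) + 1,
                        contig=contig,
                        member_gene_ids=ids,
                        n_secreted=n_sec,
                        n_nonsecreted=len(ids) - n_sec,
                        n_ssp=sum(1 for gid in ids if is_ssp[gid]),
                    )
                )
            chain.clear()

        for i in secreted_idx:
            if chain and i - chain[-1] - 1 > 1:
                close()
            chain.append(i)
        close()
    return clusters


def validate_cluster(cluster: GeneCluster, ann: GenomeAnnotation) -> None:
    """Independent post-hoc check of the cluster invariants; raises ValueError."""
    flags = ann.flags
    ids = cluster.member_gene_ids
    if not flags[ids[0]].secreted or not flags[ids[-1]].secreted:
        raise ValueError(f"cluster {cluster.cluster_id}: ends not secreted")
    if cluster.n_secreted < 3:
        raise ValueError(f"cluster {cluster.cluster_id}: fewer than 3 secreted")
    n_sec = sum(1 for gid in ids if flags[gid].secreted)
    if n_sec != cluster.n_secreted or len(ids) - n_sec != cluster.n_nonsecreted:
        raise ValueError(f"cluster {cluster.cluster_id}: member counts inconsistent")
    gap = 0
    for gid in ids[1:]:
        if flags[gid].secreted:
            gap = 0
        else:
            gap += 1
            if gap > 1:
                raise ValueError(
                    f"cluster {cluster.cluster_id}: gap of {gap} non-secreted genes"
                )
    contig_ids = [g.gene_id for g in ann.genes_by_contig[cluster.contig]]
    start = contig_ids.index(ids[0])
    if tuple(contig_ids[start : start + len(ids)]) != ids:
        raise ValueError(f"cluster {cluster.cluster_id}: members not contiguous")


def cluster_summary(
    clusters: list[GeneCluster],
    flags: Mapping[str, GeneFlags],
    upregulated: Iterable[str] | None = None,
    max_len_aa: int = SSP_MAX_LEN_AA,
) -> dict:
    """Cluster fractions relative to genome-wide secreted/SSP totals.

    Percentages are rounded half-up to one decimal; a zero-count class
    yields None (printed as NA).
    """
    is_ssp, n_secreted_total, n_ssp_total = classify_ssp(flags, max_len_aa)
    members = [gid for cl in clusters for gid in cl.member_gene_ids]
    secreted_in = [gid for gid in members if flags[gid].secreted]
    ssp_in = [gid for gid in members if is_ssp[gid]]
    n_clusters_with_ssp = sum(1 for cl in clusters if cl.n_ssp > 0)
    summary = {
        "n_clusters": len(clusters),
        "n_secreted_total": n_secreted_total,
        "n_ssp_total": n_ssp_total,
        "n_secreted_in_clusters": len(secreted_in),
        "pct_secreted_in_clusters": pct(len(secreted_in), n_secreted_total, 1),
        "n_ssp_in_clusters": len(ssp_in),
        "pct_ssp_in_clusters": pct(len(ssp_in), n_ssp_total, 1),
        "n_clusters_with_ssp": n_clusters_with_ssp,
    }
    if upregulated is not None:
        up = set(upregulated)
        n_up = sum(1 for gid in secreted_in if gid in up)
        summary["n_upregulated_secreted_in_clusters"] = n_up
        summary["pct_upregulated_secreted_in_clusters"] = pct(
            n_up, len(secreted_in), 1
        )
    return summary
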