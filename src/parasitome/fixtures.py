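"""Constructed benchmark fixtures for the worked-example summary statistics.

Each builder assembles an annotation (or table) from explicit counts so a
detector/summary operation can be run end-to-end and its printed statistic
recomputed.  Builders are deterministic and need no random seed.
"""

from __future__ import annotations

from parasitome.annotation import GeneFlags, GeneModel, GenomeAnnotation
from parasitome.expression import OrthologPair, RegulationSets

# TpA/ApT above threshold: "TA"*60 -> N(TA)=60, N(AT)=59, index ~1.017
_CDS_HIGH_TPA = "TA" * 60
# below threshold: "ATC"*40 -> N(TA)=0, N(AT)=40, index 0.0
_CDS_LOW_TPA = "ATC" * 40


def _linear_annotation(
    specs: list[dict], contig: str = "ctg_1", gene_bp: int = 120, gap_bp: int = 60
) -> GenomeAnnotation:
    """Lay genes out left-to-right on one contig from per-gene spec dicts."""
    genes: list[GeneModel] = []
    flags: dict[str, GeneFlags] = {}
    pos = 0
    for i, spec in enumerate(specs):
        gid = spec.get("gene_id", f"g{i + 1:05d}")
        cds = spec.get("cds", "")
        length = len(cds) or gene_bp
        start = pos + gap_bp + 1
        end = start + length - 1
        pos = end
        genes.append(
            GeneModel(
                gene_id=gid, contig=contig, start=start, end=end, strand="+", cds=cds
            )
        )
        flags[gid] = GeneFlags(
            gene_id=gid,
            secreted=spec.get("secreted", False),
            protein_length=spec.get("protein_length", max(1, length // 3)),
            family_id=spec.get("family_id"),
        )
    return GenomeAnnotation(genes, flags=flags)


def tandem_fixture(
    n_genes: int = 10959, runs_len2: int = 103, runs_len3: int = 22
) -> GenomeAnnotation:
    """One-contig annotation with planted adjacent same-family runs; all
    remaining genes are singletons (null family)."""
    specs: list[dict] = []
    fam = 0
    for run_len, n_runs in ((2, runs_len2), (3, runs_len3)):
        for _ in range(n_runs):
            fam += 1
            for _ in range(run_len):
                specs.append({"family_id": f"fam_{fam:04d}"})
            specs.append({})  # singleton spacer between runs
    if len(specs) > n_genes:
        raise ValueError("planted runs exceed gene budget")
    specs.extend({} for _ in range(n_genes - len(specs)))
    return _linear_annotation(specs)


def rip_index_fixture(
    n_above: int, n_below: int, secreted: bool = False
) -> GenomeAnnotation:
    """CDS fixtures with exactly ``n_above`` sequences over the TpA/ApT
    threshold and ``n_below`` under it."""
    specs = [
        {"cds": _CDS_HIGH_TPA, "secreted": secreted, "protein_length": 40}
        for _ in range(n_above)
    ]
    specs += [
        {"cds": _CDS_LOW_TPA, "secreted": secreted, "protein_length": 40}
        for _ in range(n_below)
    ]
    return _linear_annotation(specs)


def stop_codon_fixture(n_taa: int, n_tag: int, n_tga: int) -> GenomeAnnotation:
    """CDS fixtures whose termini are planted with the given stop codons."""
    specs = []
    for stop, n in (("TAA", n_taa), ("TAG", n_tag), ("TGA", n_tga)):
        specs.extend({"cds": "ATGGCCGCC" + stop} for _ in range(n))
    return _linear_annotation(specs)


def cluster_fixture(
    n_secreted_total: int = 1666,
    n_clusters: int = 121,
    secreted_in_clusters: int = 453,
    n_ssp_total: int = 695,
    ssp_in_clusters: int = 192,
    clusters_with_ssp: int = 103,
) -> GenomeAnnotation:
    """Annotation with planted pure-secreted clusters plus isolated secreted
    genes, with SSP lengths assigned to hit the requested SSP placement."""
    if secreted_in_clusters < 3 * n_clusters:
        raise ValueError("clusters need >= 3 secreted members each")
    # cluster sizes: as many size-4 clusters as the total allows, rest size 3
    extra = secreted_in_clusters - 3 * n_clusters
    if extra > n_clusters:
        raise ValueError("fixture only plants clusters of size 3 or 4")
    sizes = [4] * extra + [3] * (n_clusters - extra)
    # SSP placement inside clusters: fill the chosen clusters greedily
    ssp_per_cluster = [0] * n_clusters
    remaining = ssp_in_clusters
    for ci in range(clusters_with_ssp):
        quota = min(sizes[ci], remaining - (clusters_with_ssp - ci - 1))
        quota = max(1, quota)
        ssp_per_cluster[ci] = quota
        remaining -= quota
    if remaining != 0:
        raise ValueError("cannot place requested in-cluster SSPs")

    specs: list[dict] = []
    for ci, size in enumerate(sizes):
        for k in range(size):
            is_ssp = k < ssp_per_cluster[ci]
            specs.append(
                {"secreted": True, "protein_length": 100 if is_ssp else 400}
            )
        specs.extend([{}, {}])  # gap of two non-secreted breaks the chain

    n_isolated = n_secreted_total - secreted_in_clusters
    ssp_outside = n_ssp_total - ssp_in_clusters
    if ssp_outside > n_isolated:
        raise ValueError("not enough isolated secreted genes for outside SSPs")
    for j in range(n_isolated):
        specs.append(
            {"secreted": True, "protein_length": 100 if j < ssp_outside else 400}
        )
        specs.extend([{}, {}])
    return _linear_annotation(specs)


def focal_set_fixture(
    n_focal: int = 117,
    n_secreted: int = 75,
    n_expanded: int = 36,
    n_background: int = 10959,
) -> tuple[RegulationSets, dict[str, GeneFlags]]:
    """A focal infection gene set (up10 = top decile) over a larger universe."""
    flags: dict[str, GeneFlags] = {}
    focal = [f"g{i + 1:05d}" for i in range(n_focal)]
    for i in range(n_background):
        gid = f"g{i + 1:05d}"
        flags[gid] = GeneFlags(
            gene_id=gid,
            secreted=i < n_secreted,
            protein_length=400,
            expanded_family=i < n_expanded,
        )
    sets = RegulationSets(
        up2=frozenset(focal),
        down2=frozenset(),
        up10=frozenset(focal),
        down10=frozenset(),
        fold_change={gid: 20.0 for gid in focal},
        top_decile=frozenset(focal),
    )
    return sets, flags


def ortholog_fixture(
    n_pairs: int = 8121, n_significant: int = 2599, qvalue_cutoff: float = 0.01
) -> list[OrthologPair]:
    """Ortholog pairs with exactly ``n_significant`` q-values below cutoff."""
    pairs = []
    for i in range(n_pairs):
        q = qvalue_cutoff / 10 if i < n_significant else 0.5
        pairs.append(
            OrthologPair(
                gene_a=f"a{i + 1:05d}",
                gene_b=f"b{i + 1:05d}",
                expr_a=1.0,
                expr_b=1.0,
                qvalue=q,
            )
        )
    return pairs
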