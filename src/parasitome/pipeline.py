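"""One-command orchestration of all analysis stages with a JSON report.

Every stage draws its randomness from a substream derived from the single
config seed and the stage name, so stages are individually reproducible and
re-running a config yields byte-identical outputs (timings go to the log
only, never into the JSON).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from parasitome._util import derive_seed
from parasitome.annotation import (
    GenomeAnnotation,
    load_annotation,
    write_annotation,
)
from parasitome.clusters import classify_ssp, cluster_summary, cysteine_rich, detect_clusters
from parasitome.duplication import (
    find_tandem_pairs,
    read_te_intervals,
    recent_duplicates,
    tandem_permutation_test,
    te_proximity,
)
from parasitome.expression import (
    ExpressionTable,
    infection_report,
    normalize_counts,
    ortholog_compare,
    read_counts_tsv,
    read_ortholog_pairs_tsv,
    regulation_sets,
    top_expressed,
    write_counts_tsv,
)
from parasitome.rip import classify_rip_genes, stop_codon_census
from parasitome.synth import (
    ExpressionConfig,
    GenomeConfig,
    generate_expression,
    generate_genome,
)

logger = logging.getLogger(__name__)

REPORT_VERSION = 1


@dataclass
class Thresholds:
    n_permutations: int = 1000
    max_te_dist_bp: int = 10000
    ssp_max_len_aa: int = 300
    min_dup_len_bp: int = 400
    min_dup_identity: float = 0.80
    top_fraction: float = 0.10
    enrichment_alpha: float = 0.001
    qvalue_cutoff: float = 0.01
    ortholog_fold_threshold: float = 10.0

    def validate(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    out_dir: str = "parasitome_out"
    seed: int = 0
    # real inputs (all optional when synthetic config given)
    gff3: str | None = None
    genome: str | None = None
    cds: str | None = None
    proteins: str | None = None
    flags: str | None = None
    te: str | None = None
    counts: str | None = None
    design: dict[str, str] = field(default_factory=dict)
    control_label: str = "knob"
    infection_label: str = "infection"
    orthologs: str | None = None
    # synthetic data
    synthetic: GenomeConfig | None = None
    synthetic_expression: ExpressionConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            from parasitome.synth import DistSpec

            for key in ("gene_length_aa", "intergenic_bp"):
                if key in syn:
                    syn[key] = DistSpec(**syn[key])
            for key in ("planted_clusters", "planted_tandem_runs"):
                if key in syn:
                    syn[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in syn[key]
                    )
            kwargs["synthetic"] = GenomeConfig(**syn)
        if kwargs.get("synthetic_expression") is not None:
            sx = dict(kwargs["synthetic_expression"])
            for key in ("planted_up_10x", "planted_up_2x"):
                if key in sx:
                    sx[key] = frozenset(sx[key])
            kwargs["synthetic_expression"] = ExpressionConfig(**sx)
        if "thresholds" in kwargs and kwargs["thresholds"] is not None:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        return cls(**kwargs)


def _stage(report: dict, name: str):
    """Context manager logging stage timing and recording failures."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def _load_inputs(cfg: PipelineConfig, out: Path, report: dict) -> GenomeAnnotation:
    if cfg.synthetic is not None:
        syn_cfg = dataclasses.replace(
            cfg.synthetic, seed=derive_seed(cfg.seed, "genome")
        )
        ann, truth = generate_genome(syn_cfg)
        write_annotation(ann, out / "synthetic")
        with open(out / "synthetic" / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        report["synthetic"] = True
        return ann
    if cfg.gff3 is None or cfg.flags is None:
        raise ValueError("either a synthetic config or --gff3/--flags inputs required")
    report["synthetic"] = False
    return load_annotation(
        cfg.gff3,
        genome_fasta=cfg.genome,
        protein_fasta=cfg.proteins,
        cds_fasta=cfg.cds,
        flags_tsv=cfg.flags,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    cfg.thresholds.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("parasitome")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    th = cfg.thresholds

    report: dict = {"version": REPORT_VERSION, "seed": cfg.seed}
    try:
        with _stage(report, "load"):
            ann = _load_inputs(cfg, out, report)
            report["n_genes"] = ann.n_genes
            report["n_contigs"] = len(ann.genes_by_contig)

        with _stage(report, "rip"):
            rip_block = {}
            for index in ("tpa_apt", "composite"):
                scan = classify_rip_genes(ann, index=index)
                rip_block[index] = {
                    "n_affected": scan.n_affected,
                    "n_total": scan.n_total,
                    "pct_affected": scan.pct_affected,
                }
            report["rip"] = rip_block
            tpa_scan = classify_rip_genes(ann, index="tpa_apt")
            with open(out / "rip.tsv", "w") as fh:
                fh.write("gene_id\ttpa_apt\tcomposite\tcall_tpa\tcall_composite\n")
                for r in tpa_scan.results:
                    fh.write(
                        f"{r.seq_id}\t{'' if r.tpa_apt is None else f'{r.tpa_apt:.4f}'}"
                        f"\t{'' if r.composite is None else f'{r.composite:.4f}'}"
                        f"\t{r.affected_tpa}\t{r.affected_composite}\n"
                    )

        with _stage(report, "stop_codons"):
            affected = {
                r.seq_id for r in tpa_scan.results if r.affected_tpa == "affected"
            }
            unaffected = {
                r.seq_id for r in tpa_scan.results if r.affected_tpa == "unaffected"
            }

            def census_dict(gene_set):
                c = stop_codon_census(ann, gene_set)
                return dataclasses.asdict(c)

            report["stop_codons"] = {
                "all": census_dict(None),
                "rip_affected": census_dict(affected),
                "rip_unaffected": census_dict(unaffected),
            }

        with _stage(report, "tandem"):
            tandem = find_tandem_pairs(ann)
            p_value = tandem_permutation_test(
                ann, n_perm=th.n_permutations, seed=derive_seed(cfg.seed, "tandem")
            )
            report["tandem"] = {
                "n_pairs": tandem.n_pairs,
                "n_genes": tandem.n_genes,
                "n_runs": len(tandem.runs),
                "pct_genes": tandem.pct_genes,
                "p_value": p_value,
            }
            with open(out / "tandem_runs.tsv", "w") as fh:
                fh.write("contig\tfamily_id\tgene_ids\n")
                for run in tandem.runs:
                    fh.write(f"{run.contig}\t{run.family_id}\t{';'.join(run.gene_ids)}\n")

        if cfg.te is not None:
            with _stage(report, "te_proximity"):
                te = read_te_intervals(cfg.te)
                n_near, _ = te_proximity(ann, tandem, te, th.max_te_dist_bp)
                report["te_proximity"] = {
                    "n_tandem_genes_near_te": n_near,
                    "max_dist_bp": th.max_te_dist_bp,
                }

        with _stage(report, "recent_duplicates"):
            dups = recent_duplicates(
                ann, min_len_bp=th.min_dup_len_bp, min_identity=th.min_dup_identity
            )
            report["recent_duplicates"] = {
                "n_pairs": len(dups),
                "min_len_bp": th.min_dup_len_bp,
                "min_identity": th.min_dup_identity,
            }
            with open(out / "recent_duplicates.tsv", "w") as fh:
                fh.write("gene_a\tgene_b\tidentity\taligned_length\n")
                for d in dups:
                    fh.write(f"{d.gene_a}\t{d.gene_b}\t{d.identity:.4f}\t{d.aligned_length}\n")

        with _stage(report, "ssp"):
            is_ssp, n_secreted, n_ssp = classify_ssp(ann.flags, th.ssp_max_len_aa)
            report["ssp"] = {
                "n_secreted": n_secreted,
                "n_ssp": n_ssp,
                "n_ssp_cysteine_rich": cysteine_rich(
                    ann.flags, [g for g, v in is_ssp.items() if v]
                ),
            }

        with _stage(report, "clusters"):
            clusters = detect_clusters(ann, th.ssp_max_len_aa)
            with open(out / "clusters.tsv", "w") as fh:
                fh.write(
                    "cluster_id\tcontig\tn_secreted\tn_nonsecreted\tn_ssp\tmember_gene_ids\n"
                )
                for cl in clusters:
                    fh.write(
                        f"{cl.cluster_id}\t{cl.contig}\t{cl.n_secreted}\t"
                        f"{cl.n_nonsecreted}\t{cl.n_ssp}\t{';'.join(cl.member_gene_ids)}\n"
                    )

        table: ExpressionTable | None = None
        if cfg.synthetic_expression is not None:
            with _stage(report, "expression_synth"):
                sx = dataclasses.replace(
                    cfg.synthetic_expression, seed=derive_seed(cfg.seed, "expression")
                )
                table = generate_expression(ann, sx)
                write_counts_tsv(table, out / "counts.tsv")
                control, infection = sx.control_label, sx.infection_label
        elif cfg.counts is not None:
            with _stage(report, "expression_load"):
                table = read_counts_tsv(cfg.counts, cfg.design)
                control, infection = cfg.control_label, cfg.infection_label

        upregulated = None
        if table is not None:
            with _stage(report, "expression"):
                table = normalize_counts(table)
                sets = regulation_sets(table, control, infection)
                top = top_expressed(table, infection, th.top_fraction)
                sets = sets.with_top_decile(top)
                upregulated = set(sets.up10)
                rep = infection_report(
                    sets, ann.flags, alpha=th.enrichment_alpha,
                    max_len_aa=th.ssp_max_len_aa,
                )
                report["expression"] = {
                    "n_up2": len(sets.up2),
                    "n_down2": len(sets.down2),
                    "n_up10": len(sets.up10),
                    "n_down10": len(sets.down10),
                    "n_top_decile": len(top),
                    "size_factors": {
                        s: float(v) for s, v in table.size_factors.items()
                    },
                    "infection_report": rep,
                }
        else:
            report["expression"] = None

        with _stage(report, "cluster_summary"):
            report["clusters"] = cluster_summary(
                clusters, ann.flags, upregulated=upregulated,
                max_len_aa=th.ssp_max_len_aa,
            )

        if cfg.orthologs is not None:
            with _stage(report, "orthologs"):
                pairs = read_ortholog_pairs_tsv(cfg.orthologs)
                _, summary = ortholog_compare(
                    pairs,
                    fold_threshold=th.ortholog_fold_threshold,
                    qvalue_cutoff=th.qvalue_cutoff,
                )
                report["orthologs"] = summary
        else:
            report["orthologs"] = None

        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    finally:
        root.removeHandler(handler)
        handler.close()
    return report
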