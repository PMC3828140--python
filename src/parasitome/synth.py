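"""Seeded synthetic genomes and expression counts with planted ground truth.

Everything here is a pure function of (config, seed): the same config always
yields byte-identical outputs.  Planted structures are recorded in a
:class:`GroundTruth` object so downstream detectors can be scored against
the truth without external data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import numpy as np
from Bio.Seq import Seq

from parasitome.annotation import GeneFlags, GeneModel, GenomeAnnotation

STOP_CODONS = ("TAA", "TAG", "TGA")

# genes flanking a planted cluster must stay non-secreted out to this many
# slots so detection cannot merge a cluster with sprinkled secreted genes
_CLUSTER_BUFFER = 2


@dataclass(frozen=True)
class DistSpec:
    """Truncated-normal integer distribution: round(N(mean, sd)) clamped >= min."""

    mean: float
    sd: float
    min: int

    def draw(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        vals = np.rint(rng.normal(self.mean, self.sd, size=n)).astype(int)
        return np.maximum(vals, self.min)


@dataclass(frozen=True)
class GenomeConfig:
    n_contigs: int = 2
    genes_per_contig: int = 50
    gene_length_aa: DistSpec = DistSpec(mean=120.0, sd=30.0, min=60)
    intergenic_bp: DistSpec = DistSpec(mean=300.0, sd=100.0, min=50)
    gc_content: float = 0.5
    frac_secreted: float = 0.0
    frac_ssp_of_secreted: float = 0.5
    planted_clusters: tuple[tuple[int, int], ...] = ()  # (n_secreted, n_interspersed)
    planted_tandem_runs: tuple[int, ...] = ()  # run lengths >= 2
    rip_rate: float = 0.0
    rip_rate_tg: float | None = None  # optional per-target asymmetry; default = rip_rate
    stop_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # TAA, TAG, TGA
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs < 1 or self.genes_per_contig < 1:
            raise ValueError("n_contigs and genes_per_contig must be >= 1")
        for frac in (self.gc_content, self.frac_secreted, self.frac_ssp_of_secreted):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if not 0.0 <= self.rip_rate <= 1.0:
            raise ValueError("rip_rate must lie in [0, 1]")
        for n_sec, n_int in self.planted_clusters:
            if n_sec < 3:
                raise ValueError("planted clusters need >= 3 secreted members")
            if n_int < 0 or n_int > n_sec - 1:
                raise ValueError(
                    "interspersed non-secreted genes must fit singly between "
                    "consecutive secreted members (<= n_secreted - 1)"
                )
        for run in self.planted_tandem_runs:
            if run < 2:
                raise ValueError("tandem runs must have length >= 2")
        if abs(sum(self.stop_weights) - 1.0) > 1e-9 or min(self.stop_weights) < 0:
            raise ValueError("stop_weights must be a probability vector")


@dataclass(frozen=True)
class ExpressionConfig:
    n_samples_per_condition: int = 2
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05  # variance = mean + dispersion * mean^2
    planted_up_10x: frozenset[str] = frozenset()
    planted_up_2x: frozenset[str] = frozenset()
    control_label: str = "knob"
    infection_label: str = "infection"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_condition < 1:
            raise ValueError("need >= 1 sample per condition")
        if self.nb_mean <= 0:
            raise ValueError("nb_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if set(self.planted_up_10x) & set(self.planted_up_2x):
            raise ValueError("planted gene sets must be disjoint")


@dataclass
class GroundTruth:
    """Planted structures of one synthetic genome."""

    cluster_members: list[list[str]] = field(default_factory=list)  # full spans
    cluster_secreted: list[list[str]] = field(default_factory=list)
    tandem_runs: list[list[str]] = field(default_factory=list)
    rip_genes: list[str] = field(default_factory=list)
    secreted_genes: list[str] = field(default_factory=list)
    ssp_genes: list[str] = field(default_factory=list)

    @property
    def n_tandem_pairs(self) -> int:
        return sum(len(run) - 1 for run in self.tandem_runs)

    def to_dict(self) -> dict:
        return asdict(self)


def apply_rip(
    seq: str, rate: float, seed: int, rate_tg: float | None = None
) -> str:
    """Apply one round of RIP-style mutation to a duplex sequence.

    A single left-to-right pass over the *original* sequence: each forward
    strand CpA has its C replaced by T with probability ``rate``; each
    forward-strand TpG (a CpA on the reverse strand) has its G replaced by A
    with probability ``rate_tg`` (defaults to ``rate``).  Mutations never
    create new targets within the pass, and length is preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate_tg is None:
        rate_tg = rate
    elif not 0.0 <= rate_tg <= 1.0:
        raise ValueError("rate_tg must lie in [0, 1]")
    if len(seq) < 2:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    orig = arr.copy()
    ca = (orig[:-1] == ord("C")) & (orig[1:] == ord("A"))
    tg = (orig[:-1] == ord("T")) & (orig[1:] == ord("G"))
    hit_ca = ca & (rng.random(len(seq) - 1) < rate)
    hit_tg = tg & (rng.random(len(seq) - 1) < rate_tg)
    arr[:-1][hit_ca] = ord("T")  # CpA -> TpA
    arr[1:][hit_tg] = ord("A")  # TpG -> TpA
    return arr.tobytes().decode("ascii")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)
    return bases.tobytes().decode("ascii")


def _random_cds(rng: np.random.Generator, aa_len: int, cfg: GenomeConfig) -> str:
    body = "ATG" + _random_dna(rng, 3 * (aa_len - 1), cfg.gc_content)
    stop = STOP_CODONS[rng.choice(3, p=list(cfg.stop_weights))]
    return body + stop


def _cluster_pattern(n_secreted: int, n_interspersed: int) -> list[bool]:
    """Secretion pattern of a planted cluster: at most one non-secreted gene
    between consecutive secreted members; first and last members secreted."""
    gaps = [0] * (n_secreted - 1)
    for i in range(n_interspersed):
        gaps[i] = 1
    pattern = [True]
    for gap in gaps:
        pattern.extend([False] * gap)
        pattern.append(True)
    return pattern


def generate_genome(cfg: GenomeConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Build a synthetic annotated genome with planted structures."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    # --- plan per-contig slot layout -------------------------------------
    # slot value: ("plain",) | ("cluster", idx, member_pos) | ("tandem", idx)
    slots: list[list[tuple]] = [
        [("plain",)] * cfg.genes_per_contig for _ in range(cfg.n_contigs)
    ]
    cluster_spans: list[list[set[int]]] = [[] for _ in range(cfg.n_contigs)]
    cursors = [0] * cfg.n_contigs

    structures: list[tuple] = []
    for ci, (n_sec, n_int) in enumerate(cfg.planted_clusters):
        structures.append(("cluster", ci, _cluster_pattern(n_sec, n_int)))
    for ti, run_len in enumerate(cfg.planted_tandem_runs):
        structures.append(("tandem", ti, run_len))

    for kind, idx, payload in structures:
        span = len(payload) if kind == "cluster" else payload
        placed = False
        for c in range(cfg.n_contigs):
            if cursors[c] + span <= cfg.genes_per_contig:
                start = cursors[c]
                if kind == "cluster":
                    for k, is_sec in enumerate(payload):
                        slots[c][start + k] = ("cluster", idx, is_sec)
                    cluster_spans[c].append(set(range(start, start + span)))
                else:
                    for k in range(span):
                        slots[c][start + k] = ("tandem", idx)
                cursors[c] = start + span + _CLUSTER_BUFFER
                placed = True
                break
        if not placed:
            raise ValueError(
                f"planted structure ({kind} of span {span}) exceeds contig capacity"
            )

    # --- assign per-gene attributes --------------------------------------
    genes: list[GeneModel] = []
    flags: dict[str, GeneFlags] = {}
    contigs: dict[str, str] = {}
    tandem_cds: dict[int, str] = {}
    tandem_members: dict[int, list[str]] = {}
    cluster_full: dict[int, list[str]] = {}
    cluster_sec: dict[int, list[str]] = {}

    for c in range(cfg.n_contigs):
        contig_name = f"contig_{c + 1:02d}"
        # positions too close to a planted cluster stay non-secreted
        forbidden: set[int] = set()
        for span in cluster_spans[c]:
            lo, hi = min(span), max(span)
            for p in range(lo - _CLUSTER_BUFFER, hi + _CLUSTER_BUFFER + 1):
                forbidden.add(p)

        parts: list[str] = []
        pos = 0
        for g in range(cfg.genes_per_contig):
            gid = f"{contig_name}_g{g + 1:04d}"
            slot = slots[c][g]
            secreted = False
            family: str | None = None
            if slot[0] == "cluster":
                secreted = bool(slot[2])
                cluster_full.setdefault(slot[1], []).append(gid)
                if secreted:
                    cluster_sec.setdefault(slot[1], []).append(gid)
            elif slot[0] == "tandem":
                family = f"tfam_{slot[1] + 1:03d}"
                tandem_members.setdefault(slot[1], []).append(gid)
            elif g not in forbidden and rng.random() < cfg.frac_secreted:
                secreted = True

            is_ssp = secreted and rng.random() < cfg.frac_ssp_of_secreted
            if secreted:
                if is_ssp:
                    aa_len = int(
                        np.clip(
                            int(cfg.gene_length_aa.draw(rng, 1)[0]),
                            cfg.gene_length_aa.min,
                            299,
                        )
                    )
                else:
                    aa_len = max(300, int(cfg.gene_length_aa.draw(rng, 1)[0]))
            else:
                aa_len = int(cfg.gene_length_aa.draw(rng, 1)[0])

            if slot[0] == "tandem":
                # identical template per run so members are true duplicates
                if slot[1] not in tandem_cds:
                    tandem_cds[slot[1]] = _random_cds(rng, aa_len, cfg)
                cds = tandem_cds[slot[1]]
            else:
                cds = _random_cds(rng, aa_len, cfg)

            if slot[0] == "tandem" and cfg.rip_rate > 0:
                cds = apply_rip(
                    cds,
                    cfg.rip_rate,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    rate_tg=cfg.rip_rate_tg,
                )
                truth.rip_genes.append(gid)

            gap = int(cfg.intergenic_bp.draw(rng, 1)[0])
            parts.append(_random_dna(rng, gap, cfg.gc_content))
            pos += gap
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = cds if strand == "+" else str(Seq(cds).reverse_complement())
            parts.append(embedded)
            start = pos + 1
            end = pos + len(cds)
            pos = end

            protein = str(Seq(cds[:-3]).translate()) if len(cds) > 3 else ""
            genes.append(
                GeneModel(
                    gene_id=gid,
                    contig=contig_name,
                    start=start,
                    end=end,
                    strand=strand,
                    cds=cds,
                    protein=protein,
                )
            )
            plen = max(1, len(protein))
            flags[gid] = GeneFlags(
                gene_id=gid,
                secreted=secreted,
                protein_length=plen,
                cysteines=min(protein.count("C"), plen),
                family_id=family,
                category="unclassified",
            )
            if secreted:
                truth.secreted_genes.append(gid)
                if is_ssp:
                    truth.ssp_genes.append(gid)

        parts.append(_random_dna(rng, int(cfg.intergenic_bp.draw(rng, 1)[0]), cfg.gc_content))
        contigs[contig_name] = "".join(parts)

    for idx in sorted(cluster_full):
        truth.cluster_members.append(cluster_full[idx])
        truth.cluster_secreted.append(cluster_sec[idx])
    for idx in sorted(tandem_members):
        truth.tandem_runs.append(tandem_members[idx])

    ann = GenomeAnnotation(genes, flags=flags, contigs=contigs)
    ann.validate()
    return ann, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with variance = mean + dispersion * mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_expression(ann: GenomeAnnotation, cfg: ExpressionConfig):
    """Negative-binomial counts for a control and an infection condition.

    Planted genes have their infection-condition mean multiplied by 10 (or 2).
    Returns an :class:`~parasitome.expression.ExpressionTable`.
    """
    from parasitome.expression import ExpressionTable
    import pandas as pd

    cfg.validate()
    gene_ids = ann.gene_ids()
    known = set(gene_ids)
    for planted in (cfg.planted_up_10x, cfg.planted_up_2x):
        unknown = set(planted) - known
        if unknown:
            raise ValueError(f"planted genes not in annotation: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(cfg.seed)
    base = np.full(len(gene_ids), cfg.nb_mean)
    infect_mean = base.copy()
    for i, gid in enumerate(gene_ids):
        if gid in cfg.planted_up_10x:
            infect_mean[i] *= 10.0
        elif gid in cfg.planted_up_2x:
            infect_mean[i] *= 2.0

    samples: list[str] = []
    conditions: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    for rep in range(1, cfg.n_samples_per_condition + 1):
        name = f"{cfg.control_label}_{rep}"
        samples.append(name)
        conditions[name] = cfg.control_label
        columns[name] = _nb_draw(rng, base, cfg.nb_dispersion)
    for rep in range(1, cfg.n_samples_per_condition + 1):
        name = f"{cfg.infection_label}_{rep}"
        samples.append(name)
        conditions[name] = cfg.infection_label
        columns[name] = _nb_draw(rng, infect_mean, cfg.nb_dispersion)

    counts = pd.DataFrame(columns, index=gene_ids, columns=samples)
    return ExpressionTable(counts=counts, conditions=conditions)


def truth_sets(truth: GroundTruth) -> dict[str, list]:
    """Ground truth as JSON-serializable plain lists."""
    return truth.to_dict()
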