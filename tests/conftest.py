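from __future__ import annotations

import numpy as np
import pytest

from parasitome.annotation import GeneFlags, GeneModel, GenomeAnnotation


def linear_annotation(
    specs: list[dict], contig: str = "chr1", gene_bp: int = 90, gap_bp: int = 30
) -> GenomeAnnotation:
    """Lay genes left-to-right on one contig from per-gene spec dicts
    (keys: cds, secreted, family_id, protein_length, strand, gene_id)."""
    genes, flags = [], {}
    pos = 0
    for i, spec in enumerate(specs):
        gid = spec.get("gene_id", f"g{i + 1:04d}")
        cds = spec.get("cds", "")
        length = len(cds) or gene_bp
        start = pos + gap_bp + 1
        end = start + length - 1
        pos = end
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=spec.get("contig", contig),
                start=start,
                end=end,
                strand=spec.get("strand", "+"),
                cds=cds,
            )
        )
        flags[gid] = GeneFlags(
            gene_id=gid,
            secreted=spec.get("secreted", False),
            protein_length=spec.get("protein_length", max(1, length // 3)),
            family_id=spec.get("family_id"),
            cysteines=spec.get("cysteines", 0),
            category=spec.get("category", "unclassified"),
            expanded_family=spec.get("expanded_family", False),
        )
    return GenomeAnnotation(genes, flags=flags)


def pattern_annotation(pattern: str, **kw) -> GenomeAnnotation:
    """'S' = secreted, 'N' = non-secreted, e.g. 'SNSNS'."""
    return linear_annotation(
        [{"secreted": ch == "S", "protein_length": 100} for ch in pattern], **kw
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
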