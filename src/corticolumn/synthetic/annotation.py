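"""Synthetic gene-annotation fixtures: toy genes with controlled same-strand
gaps, biotypes and 3'-UTR status, plus intergenic reads placed at configured
downstream offsets (emulating the 3'-biased pileups of a sparsely annotated
genome)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..annotation import GENE_COLUMNS
from .config import GeneratorConfig

__all__ = ["generate_annotation_fixture"]


def generate_annotation_fixture(
    config: GeneratorConfig,
    n_genes_per_strand: int = 5,
    gene_length_bp: int = 2000,
    gap_bp: int = 12000,
    biotypes: tuple[str, ...] = ("protein_coding", "lncRNA"),
    utr3_fraction: float = 0.5,
    utr3_length_bp: int = 300,
    read_offsets_bp: tuple[int, ...] = (2000,),
    reads_per_offset: int = 5,
    read_length_bp: int = 100,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy annotation plus downstream intergenic reads.

    Genes are laid out on both strands of one chromosome with a fixed
    same-strand gap of ``gap_bp`` between consecutive gene bodies; biotypes
    alternate through ``biotypes`` and every other gene (per
    ``utr3_fraction``) carries an annotated 3' UTR.  For every gene and
    every entry of ``read_offsets_bp``, ``reads_per_offset`` stranded reads
    start exactly that many bases past the gene's 3' end, so the distance
    profile peaks in the configured bins.  An empty ``read_offsets_bp``
    yields an empty read set.
    """
    if gap_bp <= 0 or gene_length_bp <= 0:
        raise ValueError("gene_length_bp and gap_bp must be positive")
    rng = np.random.default_rng(config.seed + 15485863)
    genes = []
    # strands occupy separate regions so downstream reads of one strand never
    # overlap genes of the other
    for strand in ("+", "-"):
        pos = 10000 if strand == "+" else 2_000_000
        for i in range(n_genes_per_strand):
            start = pos
            end = start + gene_length_bp - 1
            has_utr3 = (i % max(int(round(1 / utr3_fraction)), 1) == 0) if utr3_fraction > 0 else False
            genes.append(
                {
                    "gene_id": f"gene_{strand}_{i}",
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "biotype": biotypes[i % len(biotypes)],
                    "has_utr3": has_utr3,
                    "utr3_length": utr3_length_bp if has_utr3 else 0,
                }
            )
            pos = end + gap_bp + 1
    gene_df = pd.DataFrame(genes, columns=GENE_COLUMNS)

    reads = []
    for _, g in gene_df.iterrows():
        for off in read_offsets_bp:
            for r in range(reads_per_offset):
                if g.strand == "+":
                    start = g.end + 1 + off  # distance 0 = first base past 3' end
                    end = start + read_length_bp - 1
                else:
                    end = g.start - 1 - off
                    start = end - read_length_bp + 1
                reads.append(
                    {
                        "chrom": chrom,
                        "start": int(start),
                        "end": int(end),
                        "name": f"read_{g.gene_id}_{off}_{r}",
                        "score": 0,
                        "strand": g.strand,
                    }
                )
    read_df = pd.DataFrame(
        reads, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return gene_df, read_df
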