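"""Shared fixtures: small constructed genomes and the canonical two-genome
worked example (16 genes each, 14 orthologs in four conserved clusters)."""

import pytest

from cgcphy.genome_model import AnnotatedGenome, Gene, SimilarityHit, attach_operons
from cgcphy.orthology import OrthologMap


def make_genome(genome_id, n_genes, prefix, *, cogs=None, operon_sizes=None,
                gene_len=900, spacing=100, sequence=None):
    """A genome of n equal-length genes laid out head to tail."""
    step = gene_len + spacing
    genes = []
    for i in range(n_genes):
        start = 1 + i * step
        genes.append(Gene(
            id=f"{prefix}{i + 1}", start=start, end=start + gene_len - 1,
            cog=None if cogs is None else cogs[i],
        ))
    genome = AnnotatedGenome.from_genes(genome_id, genes, sequence=sequence)
    if operon_sizes:
        declared, i = [], 0
        for k, size in enumerate(operon_sizes):
            declared.append((f"{prefix}op{k}",
                             [f"{prefix}{j + 1}" for j in range(i, i + size)]))
            i += size
        attach_operons(genome, declared)
    return genome


def self_hits(genome_a, genome_b, score=100.0, identity=100.0, evalue=0.0):
    """Perfect positional self-hits between two equal-size genomes."""
    return [
        SimilarityHit(ga.id, gb.id, score=score, evalue=evalue, identity=identity)
        for ga, gb in zip(genome_a.genes, genome_b.genes)
    ]


@pytest.fixture
def worked_example():
    """The canonical 16-gene two-genome configuration: a forward run, an
    inverted run, and two indel-bearing runs; 14 ortholog pairs total."""
    x = make_genome("X", 16, "x")
    y = make_genome("Y", 16, "y")
    pairs = [(f"x{i}", f"y{i}") for i in range(1, 5)]
    pairs += [("x5", "y7"), ("x6", "y6"), ("x7", "y5")]
    pairs += [("x8", "y8"), ("x9", "y9"), ("x10", "y12"), ("x11", "y13")]
    pairs += [("x12", "y14"), ("x13", "y15"), ("x16", "y16")]
    return x, y, OrthologMap("X", "Y", pairs)
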