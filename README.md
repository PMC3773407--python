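# cgcphy

Whole-genome phylogenies for prokaryotes from **conserved orthologous gene
clusters**, with explicit screening of genes putatively involved in
horizontal gene transfer (HGT).

Single-gene trees for bacteria and archaea are notoriously distorted by
HGT, paralogy and pseudogenes.  `cgcphy` instead measures how much of two
genomes' shared gene complement is *syntenically conserved*, after removing
the genes most likely to have travelled horizontally, and builds the tree
from that signal.  It is aimed at comparative genomicists working with
annotated single-chromosome genomes (gene coordinates, COG functional
categories, operon predictions and all-against-all similarity hits).

## The method

For each genome pair the pipeline runs four stages:

1. **Ortholog assignment.**  Candidate pairs are similarity hits with
   E-value ≤ 10⁻³, identity > 30 % and compatible COG categories.  A
   one-to-one matching is chosen maximizing

   Σ<sub>pairs</sub> a·A<sub>ij</sub> − b·(#operons touched in H) − c·(#operons touched in G),

   with a = 1.0, b = c = 0.5: sequence similarity is rewarded and the
   orthologs are encouraged to group into few operons (structural
   parsimony).

2. **HGT-gene elimination.**  Two screens, each gated by a three-sigma
   test against m = 10 000 random subsets of a reference panel:
   *highly conserved genes* — for ordinary species sets, genes orthologous
   in ≥ 85 % of the panel are removed (R<sub>og</sub>(G,H) = 2N<sub>O</sub>/(N<sub>G</sub>+N<sub>H</sub>)
   classifies the set); *abnormal-barcode genes* — for species sets with
   special dispersion of the genomic-evolution value
   R<sub>ge</sub> = mean(dis) + 3·sd(dis) over per-fragment 4-mer barcode
   anomaly distances, the 20 % of each genome's genes on the most anomalous
   1 kb fragments are removed.

3. **CGC distance.**  Conserved clusters are chains of ortholog pairs
   collinear (or uniformly inverted) in both genomes, tolerating one
   bounded insertion/deletion gap per cluster.  With N<sub>cgc</sub> the
   number of orthologs inside clusters,
   **D<sub>cgc</sub>(X,Y) = −log₁₀(N<sub>cgc</sub>)**.

4. **Neighbor joining** on the D<sub>cgc</sub> matrix (own deterministic
   Saitou–Nei implementation), with quartet-topology agreement against a
   Bergey-style rank taxonomy (`B12.2.3.1.3` = phylum XII, class II, …) as
   the quality measure.

A first-class synthetic-data module generates annotated genome clades along
known trees — operon structure, COG labels, gene loss, inversions, indels
and GC-shifted foreign cassettes — so every stage is testable without any
downloads.

## Worked example

The canonical configuration of two 16-gene genomes whose ortholog map
contains a collinear head, an inverted block and two indel-bearing runs:

```python
from cgcphy import (Gene, AnnotatedGenome, OrthologMap, ClusterParams,
                    conserved_clusters, n_cgc, cgcd)

def genome(gid, prefix, n):
    genes = [Gene(id=f"{prefix}{i+1}", start=1 + i*1000, end=900 + i*1000)
             for i in range(n)]
    return AnnotatedGenome.from_genes(gid, genes)

X, Y = genome("X", "x", 16), genome("Y", "y", 16)
pairs  = [(f"x{i}", f"y{i}") for i in range(1, 5)]          # collinear head
pairs += [("x5", "y7"), ("x6", "y6"), ("x7", "y5")]         # inverted block
pairs += [("x8", "y8"), ("x9", "y9"), ("x10", "y12"), ("x11", "y13")]
pairs += [("x12", "y14"), ("x13", "y15"), ("x16", "y16")]   # indel chains

clusters = conserved_clusters(OrthologMap("X", "Y", pairs), X, Y, ClusterParams())
for c in clusters:
    print(f"{c.orientation:8s} gaps={c.gap_events}  " +
          " ".join(f"{a}-{b}" for a, b in c.pairs))
count = n_cgc(clusters)
print(f"N_cgc = {count},  D_cgc = {cgcd(count):.4f}")
```

prints

```
forward  gaps=0  x1-y1 x2-y2 x3-y3 x4-y4
inverted gaps=0  x5-y7 x6-y6 x7-y5
forward  gaps=0  x8-y8 x9-y9
forward  gaps=1  x10-y12 x11-y13 x12-y14 x13-y15 x16-y16
N_cgc = 14,  D_cgc = -1.1461
```

Four conserved clusters cover 14 of the 16 genes; the two genes that sit
outside any collinear run (x14/x15 have no orthologs, x16's partner is
reached across a 2-gene gap) contribute through the gap-tolerant chain.
D<sub>cgc</sub> = −log₁₀(14) ≈ −1.1461: more shared clustered genes would
make the distance more negative.

## Command line

```
cgcphy simulate --out demo --n-leaves 6 --n-genes 80 --seed 7 \
    --loss-rate 0.1 --inversion-rate 0.3 --indel-rate 0.2
cgcphy run --manifest demo/manifest.tsv --hits-dir demo/hits \
    --out demo/results --seed 1
```

writes `distances.phylip`, `tree.nwk`, the eliminated-gene report, a
structured per-stage log and the resolved configuration.  On the clade
above the inferred Newick tree matches the generating topology exactly.
`cgcphy ablate` produces the stage-combination table (orthologs only, with
or without HGT screening, with or without clustering) and `cgcphy quartets
TREE TAXONOMY` scores any Newick tree against a taxonomy file.

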