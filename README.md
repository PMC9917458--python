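# snbp

Phylogenomic toolkit for studying the evolution of sperm nuclear basic
protein (SNBP) genes across *Drosophila*-like species sets: homolog
detection and pseudogene calling, counting-based molecular-evolution
statistics, coverage-based sex-chromosome assignment of contigs,
gain/loss/amplification event inference on species trees, and the
enrichment statistics built on top of those events. A synthetic-data
subpackage generates every input format with known ground truth, so the
whole pipeline is testable offline.

## Layout

| Module | Role |
| --- | --- |
| `snbp.simulate` | gene-family histories, codon alignments at known ω, MK count tables at known α, bimodal depth tracks, toy genomes with planted pseudogenes/deletions |
| `snbp.io` | FASTA, GFF3, newick, 12-column hit tables, depth TSV, copy-number and polymorphism tables (1-based at file boundaries, 0-based half-open internally) |
| `snbp.homology` | hit filtering (e < 1e-2, identity > 20%, bit score > 10), reciprocal-best-hit confirmation, synteny checks, translate-and-scan pseudogene calls, bit-score-decay detectability model, built-in six-frame translated Smith–Waterman backend |
| `snbp.molevol` | NG86-style counting dN/dS with Jukes–Cantor correction, unpolarized/polarized McDonald–Kreitman tests with rare-SNP filtering, Fitch/Hartigan parsimony ancestors, percentile screens |
| `snbp.sexlinkage` | 10-kb window medians, two-peak KDE threshold, female/male ratio X–Y split, Muller-element majority voting, genetic-cross linkage |
| `snbp.events` | amplification calling (≥5 copies per location), independent-event collapsing, Dollo-parsimony losses, binomial enrichment test, exact Fisher 2×2 |
| `snbp.features` | isoelectric point (Bjellqvist or EMBOSS pKa), net charge, basic-residue fraction, PWM motif scanning |

Packaged fixtures (`snbp/data/`) transcribe the published event tables:
the per-gene amplification-event list, the post-fusion fate records, and a
*montium*-clade presence/pseudogene matrix with its species tree.

## CLI

```sh
snbp simulate {history|codon|mk|coverage|genomes} --config cfg.yaml --seed N --out DIR
snbp homology --queries q.faa --genome g.fa --gene-order g.gff3 --neighbors nbr.tsv --out calls.tsv
snbp molevol dnds --aln gene.fa --out dnds.tsv
snbp molevol mk --aln alleles.fa --outgroup outgroup.fa [--polarize anc.fa] [--rare 0.05] --out mk.tsv
snbp sexlink --male-depth m.tsv [--female-depth f.tsv] --out calls.tsv
snbp events --copy-table cn.tsv --presence pres.tsv --tree sp.nwk --origins origins.tsv --out events.tsv
snbp features --faa proteins.fa --out features.tsv
```

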