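# polyprospect

Phylogeny-guided mining of bacterial **alkyne** and **polyyne** biosynthetic
gene cassettes, for natural-product genome miners who want the screening
logic of that workflow as a tested, reusable library rather than a one-off
collection of scripts.

Bacterial polyynes (cepacins, collimonins, caryoynencin, ergoynes,
protegencin) are made by a conserved **seven-gene cassette** that extends the
minimal **three-gene alkyne cassette** (*jamABC*: fatty acyl-AMP ligase,
fatty acid desaturase, acyl carrier protein) with two further desaturases, a
thioesterase and a rubredoxin. `polyprospect` detects both cassette classes
in annotated genomes and maps their diversity:

- **Homology search** — optimal Smith–Waterman/Gotoh alignment under
  BLOSUM62 (affine gaps 11/1) with Karlin–Altschul statistics,
  `E = K·m·n·e^(−λS)` (λ = 0.267, K = 0.041). Anchor genes are desaturase
  hits at `E ≤ 1e−50`.
- **Cassette mining** — 30-kbp flanking windows around each anchor; roles
  assigned best-E-first with each gene consumable by one role; a top-down
  decision table classifies windows as `none`, `alkyne`, `polyyne`, the
  `polyyne_p450_variant` (thioesterase + rubredoxin replaced by a
  cytochrome P450), `polyyne_norub` (rubredoxin absent), or
  `polyyne_split` after rescuing roles stranded near the edges of other
  contigs.
- **Phylogenetics** — pairwise-alignment distances (p, Poisson, JC69),
  neighbor joining, column-resampling bootstrap supports, plus monophyly
  testing, outgroup rooting, clade extraction and composition tables.
- **ANI species delineation** — fragment-based average nucleotide identity
  with single-linkage clustering at the conventional 95% species threshold.
- **Exact-mass checks** — molecular-formula parsing and monoisotopic adduct
  m/z (e.g. the deprotonated C18H18O2 polyyne at m/z 265.1234).
- **Synthetic truth** — a generator that plants cassettes of every variant
  class into random genomes, builds protein families at controlled
  divergence and genome pairs at controlled ANI, so every stage is testable
  against construction-time ground truth.

## Worked example

```python
from polyprospect.synthetic_data import CassetteSpec, make_role_queries, plant_cassette
from polyprospect.cassette_mining import MiningConfig, mine_genome

queries = make_role_queries(seed=1)
genome, truth = plant_cassette(CassetteSpec("polyyne_full"), seed=3, queries=queries)
(call,) = mine_genome(genome, queries, MiningConfig())
print(call.classification, sorted(call.roles))
```

prints

```
polyyne ['ACP', 'DES_2', 'DES_3', 'DES_B', 'FAAL', 'RUB', 'TE']
```

i.e. the planted seven-gene cassette is recovered as a `polyyne` call with
all roles mapped to their planted genes. The same check for a
`split`-variant genome (cassette cut at a contig boundary, thioesterase and
rubredoxin on the second contig) upgrades to `polyyne_split` with the
rescue contig recorded.

From the shell:

```
$ polyprospect mass --formula C18H18O2 --adduct "[M-H]-"
C18H18O2        [M-H]-  265.1234
```

— the calculated monoisotopic m/z of the deprotonated C18H18O2 polyyne,
matching the value expected for its [M−H]⁻ ion to four decimals. A full
panel run (`polyprospect run --panel panel.tsv --queries roles.faa --out
out/`) writes `calls.tsv`, the second-desaturase diversity tree
(`tree.nwk`) with bootstrap supports, a companion cassette tree used for
the polyyne-monophyly verdict, composition and ANI tables, species
clusters and a JSON manifest.

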