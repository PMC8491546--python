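# forefield

Contig-centric metagenome annotation and chronosequence statistics for
studying microbial succession along glacier forefields.

## The problem

When a glacier retreats it exposes bare ground that soil microbes colonise
over decades to centuries. Sampling a transect away from the ice edge — a
*chronosequence* — substitutes space for time: distant sites are older
soils. Shotgun metagenomes from such transects can show how taxonomic
diversity and functional potential (nitrogen fixation, rock weathering)
develop during early soil formation, but only after a long annotation and
statistics chain: assembled contigs must be assigned taxonomy and
gene-coding regions from protein alignments, mis-assembled (chimeric)
contigs split, read mappings turned into comparable abundance measures, and
the ecological trends tested with permutation statistics.

`forefield` implements that chain as a tested Python library:

* **annotate** — builds gene-coding regions from ranged protein-alignment
  hits (BLAST/Diamond tabular format), assigns each region a taxon by
  lowest common ancestor (LCA) over hits scoring within 10% of the best
  bitscore, detects chimeric contigs by taxonomic discordance between
  adjacent regions at phylum rank (with a 1,000-base flanking-support rule)
  and splits them, and votes a possibly partial contig lineage
  (length-weighted, strict majority) — classified at phylum but
  unclassified at genus is a legitimate outcome.
* **coverage** — per-contig base coverage (mean mapped bases per assembly
  base, units "×") from SAM or mapped-bases tables; taxon relative
  abundance; per-gene coverage; and *weighted gene coverage*
  w(s,g) = cov(s,g) / cov(s), which removes sequencing-depth differences
  between samples.
* **succession_stats** — Shannon H = −Σ pᵢ ln pᵢ and inverse Simpson
  1/D = 1/Σ pᵢ², LOWESS trend fitting, Bray–Curtis and Euclidean distance
  matrices, one-way PERMANOVA (R², pseudo-F, label-permutation p), Mantel
  tests, permutation Spearman r_s, OLS, PCA, the study's 11 ice-edge
  distance bins, and a GO-category correlation screen (keep p < 0.05 and
  |r_s| > 0.4, both strict). All permutation tests default to 9,999
  permutations, use the add-one p-value convention and are seed-exact.
* **target_genes** — configurable gene sets (nitrogenase, *obcA*, cyanide
  synthase, siderophore) selected by label pattern or GO term, genus-wise
  region counts and coverage trends, and the per-bin fraction of genera
  possessing a set.
* **simdata** — a seed-deterministic synthetic chronosequence generator
  (three forefields, programmed geochemical gradients, succession-shaped
  communities, planted gene regions, ~1% chimeric contigs) with a truth
  table, so every stage can be scored end to end.

## Worked example

`examples/` contains one narrative script per capability. For instance
`python examples/02_diversity_and_community_stats.py` prints:

```
48 soil samples; Shannon H in [2.35, 3.38] nats; inverse Simpson in [6.5, 26.4]
inverse Simpson vs distance: rs = 0.89, p = 0.0001
PERMANOVA (factor forefield): R2 = 0.45, pseudo-F = 18.6, p = 0.0001
Mantel (community vs distance): r = 0.27, p = 0.0045
```

The positive, significant Spearman r_s says community evenness rises with
distance from the ice edge (the programmed succession signal); the PERMANOVA
R² is the share of squared Bray–Curtis distance between samples explained by
which forefield they come from; the Mantel r measures distance decay of
community similarity. `examples/01_simulate_and_annotate.py` shows chimera
detection recovering the planted mis-assemblies (recall and precision 1.00
at the default 2,000-contig scale), and `examples/03_target_gene_trends.py`
shows the fraction of genera possessing nitrogenase rising from 15% to 25%
along the distance bins.

The same workflow is available as a shell pipeline:

```bash
forefield all --out run1 --seed 42          # simulate -> annotate -> abundance -> stats
forefield simulate --out inputs --seed 7    # just the synthetic input bundle
forefield stats --indir inputs --out run2   # statistics from an existing bundle
```

Ice samples are excluded from statistics by default (`--include-ice` to keep
them). Every output is a tab-separated text file regenerated byte-identically
from the same seed.

## Documentation

`docs/methods.md` describes the model and procedure in detail: the LCA and
chimera rules, the abundance currencies, the permutation conventions, what
the synthetic generator does and does not emulate, and the package's design
choices and limitations.
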