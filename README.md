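# paleodup

Tools for resolving phylogenetic conflict and detecting ancient
whole-genome duplications (WGD) in dated phylogenies, built around the
kind of questions raised by the monocot order Pandanales: which parts of
gene-tree/species-tree discordance are incomplete lineage sorting (ILS),
which are gene flow, and which lineages carry the signature of ancient
polyploidy.

The package is aimed at phylogenomics practitioners who already have
(or can simulate) gene trees and orthogroup tables and want the
downstream inference steps as tested, scriptable components.

## What it computes

**WGD detection from paralog ages** (the core method). In gene-family
trees whose leaves are individual gene copies (`sample|copy`), a node is
a *duplication* when its child subtrees share a sample (species-overlap
rule). Each duplication node contributes its age once per sample present
on both sides, giving a per-sample distribution of paralog origin times
t. A WGD leaves a heavy, tight cluster in these distributions; we fit
1-D Gaussian mixtures

&nbsp;&nbsp;&nbsp;&nbsp;f(t) = Σₖ wₖ · N(t; μₖ, σₖ²)

selecting the number of components by BIC, keep components with enough
weight, support and small σ as candidate peaks, and merge peaks across
samples when their means agree and the supporting samples exactly form a
species-tree clade — the event is then dated at the merged mean and
assigned to that clade's stem branch.

**Discordance testing.** Robinson–Foulds distances from gene trees to
the species tree, compared against the distance distribution of gene
trees simulated under the multispecies coalescent (ILS only) with a
Pearson chi-square test (Cochran pooling of small expected counts).
PhyParts-style per-node concordant / conflicting / uninformative counts.

**ILS vs gene flow per triplet.** For each rooted triplet, internal
branch lengths of each topology class are modeled as the mixture

&nbsp;&nbsp;&nbsp;&nbsp;π₁ · λe^(−λx) + π₂ · λe^(−λ(x−c)) (x ≥ c),&nbsp;&nbsp;π₁+π₂ = 1,

fit by EM with a damped ascent step on the shift c; ΔBIC =
BIC₂ − BIC₁ < −30 flags classes where ILS alone (the one-component
exponential) is insufficient and π₂ measures the gene-flow share.

**Introgression summaries.** HyDe-style hybridization tables are
filtered by the standard rule (0 < γ < 1, p < 0.05, Z > 1, all strict)
and aggregated into clade-level donor→recipient blocks with mean
inheritance probability γ.

**Synthetic data with known ground truth.** A fixed 17-taxon,
five-family reference chronogram (crown age 107.9 Mya); gene families
grown along it under birth–death duplication–loss with episodic WGD
pulses; contained-coalescent gene trees; mixture branch-length draws;
orthogroup (Proteinortho dialect) and HyDe-style tables.

## Worked example

```python
from paleodup.simulate import (REFERENCE_FAMILIES, SimulationConfig,
                               WGDPulse, make_reference_chronogram,
                               simulate_gene_families)
from paleodup.wgd import call_wgd, extract_duplication_ages

chrono = make_reference_chronogram()
clade = frozenset(REFERENCE_FAMILIES["Pandanaceae"])
cfg = SimulationConfig(dup_rate=0.0005, loss_rate=0.0,
                       wgd_pulses=[WGDPulse(clade, 80.0, 0.8)],
                       n_families=300, seed=5)
trees = [t for t in simulate_gene_families(chrono, cfg) if t is not None]
records = [r for t in trees for r in extract_duplication_ages(t)]
calls = call_wgd(records, chrono)
for c in calls:
    print(len(c.branch), round(c.age, 2), c.assignment, c.n_duplications)
```

prints

```
4 80.0 clade 944
```

one WGD call: a 4-taxon clade (the Pandanaceae-like family), dated at
80.0 Mya, assigned to the clade's stem branch, supported by 944
duplication records — the planted pulse (time 80 Mya, retention 0.8 per
lineage, 300 families) recovered on the correct branch.

The same run from the shell:

```bash
paleodup run --seed 1 --out bundle/
```

writes per-stage TSV/JSON (WGD calls, distance distributions plus the
chi-square report, concordance counts, triplet mixture fits, and
introgression blocks) under `bundle/`, each carrying the config hash.

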