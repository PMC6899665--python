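# dietmerge

Multi-marker DNA metabarcoding diet analysis for trophic generalists:
per-marker amplicon (ESV) filtering, most-inclusive-rank taxonomic
assignment, and — the core of the package — a per-sample algorithm that
merges detections from taxonomically overlapping markers into a single
non-redundant list of maximally resolved taxa, plus the dietary
descriptors used to compare markers and methods.

## The problem

Faecal metabarcoding of a generalist consumer typically uses several PCR
markers (e.g. a universal eukaryote 18S fragment, a plant trnL fragment,
arthropod 16S and COI fragments). The markers overlap in the taxa they
amplify but differ drastically in taxonomic resolution: the same ingested
beetle may appear as *Coleoptera* with 18S, *Chrysomelidae* with 16S and
a named species with COI. Naively concatenating per-marker taxa lists
inflates diversity with cross-marker duplicates; discarding all but one
marker throws away complementary detections (COI primers famously miss
Formicidae, 18S rarely resolves below family).

## The method

Within one sample, detections whose lineages nest under the prefix
relation are treated as one ingested item; lineages that conflict at any
shared rank are distinct items. Formally, a sample's detections are
partitioned into the **minimum number of groups** such that each group

* contains at most one detection per marker, and
* its lineages form a chain under lineage extension (A's named ranks are
  a prefix of B's);

each group is reported at its deepest member's lineage. Minimising the
group count is the conservative choice — it never overestimates dietary
diversity. Because molecular OTU labels are marker-local, merging is
decided independently sample by sample. The implementation is an exact
branch-and-bound over the chain-compatibility components of the sample
(samples hold few taxa, so exact search is cheap), verified against an
exhaustive set-partition oracle; a greedy first-fit fast path is
available.

Upstream of the merge, per-marker ESV tables pass a fixed cascade:
fragment-length window → one-off denoising (an ESV one edit from a more
abundant ESV that it never occurs without is a PCR/sequencing error) →
100-read PCR-failure rule → per-PCR 1% relative-abundance floor →
lowest-common-ancestor assignment from BLAST-style hit tables (all hits
within 1 identity point of the best must agree) → single-linkage MOTU
clustering at 98% identity for ESVs not resolved to species → removal of
non-dietary clades (host, parasites, bait, non-target kingdoms).

Downstream, the package computes frequency of occurrence (FOO) per taxon
or order, per-sample richness (mean ± SE), taxonomic-resolution
profiles, and Czekanowski's niche-overlap index
`1 − ½ Σᵢ |pᵢ − qᵢ|` over proportional-utilization vectors.

## Worked example

```python
from dietmerge import Detection, TaxonLabel, merge_sample, parse_lineage

def det(marker, lineage, motu=None):
    return Detection(sample="s1", marker=marker,
                     taxon=TaxonLabel(parse_lineage(lineage), motu=motu))

order = "Animalia;Arthropoda;Insecta;Coleoptera"
m = merge_sample([
    det("18S", order, motu=1),
    det("IN16STK", order + ";Chrysomelidae", motu=1),
    det("ZBJ", order + ";Chrysomelidae;Chrysomela;Chrysomela populi"),
])
print(len(m.groups), m.groups[0].representative.display)
# 1 Chrysomela populi
```

All three markers detected the same beetle, so the merged sample holds
one taxon at the finest resolution. Swap the 16S family to `Carabidae`
and the result is two taxa (`Carabidae 1` and `Chrysomela populi`):
conflicting families cannot be the same item, and the order-level 18S
detection is absorbed into one group without inflating the count.

Running `python examples/diet_descriptors.py` (115 simulated samples,
four markers) prints:

```
occurrences: 2197 -> 1481 after merging (33% redundant across markers)
  Animalia: 1429 -> 885
  Plantae: 768 -> 596

multi-marker richness: 12.88 ± 0.33 taxa/sample (n=115)
...
Czekanowski overlap 18S vs trnL (plants): 0.754
```

i.e. about a third of the raw per-marker occurrences were the same food
items seen by more than one marker, and the two plant-capable markers
estimate substantially, but not perfectly, overlapping diets.

The `dietmerge` command exposes the same functionality from the shell
(`filter`, `assign`, `merge`, `stats`, `simulate`, `run-all`); see
`dietmerge --help`.

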