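"""Merging multi-marker detections of one faecal sample.

Three markers report Coleoptera material at different depths. When the
lineages nest (order ⊂ family ⊂ species), they are one ingested item and
the merge keeps only the species; when a family conflicts, two distinct
items remain.
"""

from dietmerge import Detection, TaxonLabel, merge_sample, parse_lineage


def det(marker, lineage, motu=None):
    return Detection(sample="s1", marker=marker,
                     taxon=TaxonLabel(parse_lineage(lineage), motu=motu))


ORDER = "Animalia;Arthropoda;Insecta;Coleoptera"
CHRY = ORDER + ";Chrysomelidae"
CHRY_SP = CHRY + ";Chrysomela;Chrysomela populi"
CARA = ORDER + ";Carabidae"

consistent = [
    det("18S", ORDER, motu=1),       # universal marker: order only
    det("IN16STK", CHRY, motu=1),    # 16S: family
    det("ZBJ", CHRY_SP),             # COI: species
]
m = merge_sample(consistent)
print(f"consistent resolutions -> {len(m.groups)} taxon:",
      m.groups[0].representative.display)
# 1 group: all three detections are the same beetle, kept at species level

conflicting = [
    det("18S", ORDER, motu=1),
    det("IN16STK", CARA, motu=1),    # 16S: a DIFFERENT family
    det("ZBJ", CHRY_SP),
]
m2 = merge_sample(conflicting)
print(f"conflicting families  -> {len(m2.groups)} taxa:",
      ", ".join(g.representative.display for g in m2.groups))
# 2 groups: Carabidae and the Chrysomelidae species are distinct prey;
# the order-level 18S detection is absorbed by one of them, so the
# sample's richness stays 2.
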