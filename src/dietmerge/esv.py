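"""Per-marker ESV filtering cascade and taxonomic assignment.

Raw amplicon reads, already collapsed to exact sequence variants (ESVs)
with per-PCR read counts, are cleaned marker by marker:

1. length window — discard fragments outside the marker's expected size;
2. one-off denoising — an ESV one edit away from a more abundant ESV that
   it never occurs without is a likely PCR/sequencing error;
3. PCR failure — PCR products totalling fewer than 100 reads failed;
4. relative abundance — within each PCR, drop ESVs under 1% of its total;
5. lowest-common-ancestor assignment from a BLAST-style hit table;
6. MOTU clustering of ESVs not resolved to species (~98% identity,
   single linkage) into numbered taxa ("Carabidae 1", ...);
7. exclusion of non-dietary clades (hosts, parasites, bait, non-target
   kingdoms).

The stage order is fixed; a runner guard enforces it because the 1% filter
is defined against the PCR totals of its own input and must run exactly
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from .merge import Detection
from .taxonomy import (
    LINNAEAN,
    Lineage,
    RankLadder,
    TaxonLabel,
    is_extension,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ESVTable",
    "MarkerConfig",
    "HitTable",
    "ExclusionPolicy",
    "ProvenanceLog",
    "filter_length",
    "denoise_one_off",
    "drop_failed_pcrs",
    "relative_abundance_filter",
    "assign_lca",
    "cluster_motus",
    "exclude_taxa",
    "to_detections",
    "run_marker_pipeline",
    "sequence_identity",
]


@dataclass
class ProvenanceLog:
    """Machine-readable record of every record-level pipeline action."""

    rows: list[dict] = field(default_factory=list)

    def record(self, stage: str, record_id: str, action: str, reason: str) -> None:
        self.rows.append(
            {"stage": stage, "record_id": record_id, "action": action,
             "reason": reason}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["stage", "record_id", "action", "reason"]
        )


@dataclass(frozen=True)
class ESVTable:
    """Per-marker ESV count matrix (rows = ESVs, columns = PCR products).

    ``counts`` is indexed by ESV id with one column per sample's PCR
    product; ``sequences`` maps ESV id → uppercase ACGTN sequence.
    """

    marker: str
    sequences: Mapping[str, str]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        missing = set(self.counts.index) - set(self.sequences)
        if missing:
            raise ValueError(f"counts without sequences: {sorted(missing)[:5]}")
        bad = {
            e for e, s in self.sequences.items()
            if set(s) - set("ACGTN") or not s
        }
        if bad:
            raise ValueError(f"non-ACGTN sequences: {sorted(bad)[:5]}")

    @property
    def esv_ids(self) -> list[str]:
        return list(self.counts.index)

    def totals(self) -> pd.Series:
        """Total reads per ESV across all PCR products."""
        return self.counts.sum(axis=1)

    def pcr_totals(self) -> pd.Series:
        """Total reads per PCR product."""
        return self.counts.sum(axis=0)

    def subset(self, esv_ids: Sequence[str]) -> "ESVTable":
        keep = [e for e in self.esv_ids if e in set(esv_ids)]
        return ESVTable(
            marker=self.marker,
            sequences={e: self.sequences[e] for e in keep},
            counts=self.counts.loc[keep],
        )


@dataclass(frozen=True)
class MarkerConfig:
    """Filtering parameters for one marker.

    Defaults follow common practice for short-amplicon diet metabarcoding:
    a 100-read minimum for a PCR product to count as amplified, a 1%
    within-PCR relative-abundance floor, and 98% identity for MOTU
    clustering.
    """

    marker: str
    min_len: int
    max_len: int
    min_pcr_reads: int = 100
    rel_abundance_floor: float = 0.01
    motu_identity: float = 0.98

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if not (0 <= self.rel_abundance_floor < 1):
            raise ValueError("rel_abundance_floor must be in [0, 1)")


#: Length windows used in the Black Wheatear study, per marker.
STUDY_MARKERS = {
    "18S": MarkerConfig("18S", 94, 153),
    "IN16STK": MarkerConfig("IN16STK", 72, 119),
    "ZBJ": MarkerConfig("ZBJ", 155, 159),
    "trnL": MarkerConfig("trnL", 30, 93),
}


@dataclass(frozen=True)
class HitTable:
    """BLAST-style candidate identifications: (esv id, lineage, % identity)."""

    rows: tuple[tuple[str, Lineage, float], ...]

    def __post_init__(self) -> None:
        for esv, _, ident in self.rows:
            if not (0 <= ident <= 100):
                raise ValueError(f"identity {ident} for {esv} outside [0, 100]")

    def by_esv(self) -> dict[str, list[tuple[Lineage, float]]]:
        out: dict[str, list[tuple[Lineage, float]]] = {}
        for esv, lin, ident in self.rows:
            out.setdefault(esv, []).append((lin, ident))
        return out


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which assigned taxa are non-dietary and must be removed.

    ``allowed_kingdoms`` keeps only plant and animal detections by default.
    ``excluded_clades`` are taxon names, optionally rank-qualified as
    ``rank:Name``, dropped wherever they occur in a lineage — host birds,
    mammals, internal parasites (Nematoda), bait contamination
    (Tenebrionidae mealworms) and non-vascular plant phyla by default.
    """

    allowed_kingdoms: tuple[str, ...] = ("Plantae", "Animalia")
    excluded_clades: tuple[str, ...] = (
        "Aves",
        "Mammalia",
        "Nematoda",
        "Tenebrionidae",
        "Bryophyta",
        "Marchantiophyta",
        "Anthocerotophyta",
    )

    def excludes(self, lineage: Lineage) -> Optional[str]:
        """Reason string if the lineage is excluded, else None."""
        if lineage.kingdom not in self.allowed_kingdoms:
            return f"kingdom {lineage.kingdom} not allowed"
        for clade in self.excluded_clades:
            if ":" in clade:
                rank, name = clade.split(":", 1)
                if lineage.name_at(rank) == name:
                    return f"excluded clade {name} ({rank})"
            elif clade in lineage.names:
                return f"excluded clade {clade}"
        return None


# ---------------------------------------------------------------------------
# filtering cascade
# ---------------------------------------------------------------------------

def filter_length(
    table: ESVTable, cfg: MarkerConfig, log: Optional[ProvenanceLog] = None
) -> ESVTable:
    """Keep ESVs whose length falls in the closed window [min_len, max_len]."""
    keep = []
    for esv in table.esv_ids:
        n = len(table.sequences[esv])
        if cfg.min_len <= n <= cfg.max_len:
            keep.append(esv)
        elif log:
            log.record(
                "length", esv, "removed",
                f"length {n} outside [{cfg.min_len}, {cfg.max_len}]",
            )
    return table.subset(keep)


def _edit_distance_is_one(a: str, b: str) -> bool:
    if abs(len(a) - len(b)) > 1:
        return False
    res = edlib.align(a, b, task="distance", k=1)
    return res["editDistance"] == 1


def denoise_one_off(
    table: ESVTable, log: Optional[ProvenanceLog] = None
) -> ESVTable:
    """Remove likely PCR/sequencing error ESVs (one-off co-occurring children).

    An ESV A is removed when some ESV B exists with unit edit distance to
    A (substitution or single indel — short plant amplicons are
    length-variable), strictly fewer total reads for A than B, and no PCR
    product where A occurs without B. Decisions are made against the
    original table and applied in a single pass: removal of A never
    enables removal of C by cascade.
    """
    totals = table.totals()
    present = table.counts > 0
    remove: set[str] = set()
    ids = table.esv_ids
    for a in ids:
        for b in ids:
            if a == b or totals[a] >= totals[b]:
                continue
            if not _edit_distance_is_one(table.sequences[a], table.sequences[b]):
                continue
            # co-occurrence: everywhere A is present, B must be too
            if (present.loc[a] & ~present.loc[b]).any():
                continue
            remove.add(a)
            if log:
                log.record(
                    "denoise", a, "removed",
                    f"one edit from {b} ({totals[a]} < {totals[b]} reads), "
                    "never occurs without it",
                )
            break
    return table.subset([e for e in ids if e not in remove])


def drop_failed_pcrs(
    table: ESVTable, cfg: MarkerConfig, log: Optional[ProvenanceLog] = None
) -> ESVTable:
    """Drop PCR products with fewer than ``min_pcr_reads`` total reads."""
    totals = table.pcr_totals()
    failed = [p for p in table.counts.columns if totals[p] < cfg.min_pcr_reads]
    if log:
        for p in failed:
            log.record(
                "pcr_failure", str(p), "removed",
                f"{int(totals[p])} reads < {cfg.min_pcr_reads}",
            )
    counts = table.counts.drop(columns=failed)
    # ESVs left with zero reads everywhere disappear with their PCRs
    keep = counts.index[counts.sum(axis=1) > 0]
    return ESVTable(
        marker=table.marker,
        sequences={e: table.sequences[e] for e in keep},
        counts=counts.loc[keep],
    )


def relative_abundance_filter(
    table: ESVTable, cfg: MarkerConfig, log: Optional[ProvenanceLog] = None
) -> ESVTable:
    """Zero counts strictly below ``rel_abundance_floor`` of their PCR total.

    Totals are those of the input table (after PCR-failure removal), so
    this stage must run exactly once.
    """
    totals = table.pcr_totals()
    counts = table.counts.copy()
    for p in counts.columns:
        floor = cfg.rel_abundance_floor * totals[p]
        below = (counts[p] > 0) & (counts[p] < floor)
        if log:
            for esv in counts.index[below]:
                log.record(
                    "rel_abundance", f"{esv}@{p}", "zeroed",
                    f"{int(counts.at[esv, p])} reads < "
                    f"{cfg.rel_abundance_floor:.0%} of {int(totals[p])}",
                )
        counts.loc[below, p] = 0
    keep = counts.index[counts.sum(axis=1) > 0]
    if log:
        for esv in counts.index.difference(keep):
            log.record("rel_abundance", esv, "removed", "all counts zeroed")
    return ESVTable(
        marker=table.marker,
        sequences={e: table.sequences[e] for e in keep},
        counts=counts.loc[keep],
    )


# ---------------------------------------------------------------------------
# assignment and clustering
# ---------------------------------------------------------------------------

def assign_lca(
    hits: HitTable, tolerance: float = 1.0
) -> tuple[dict[str, Lineage], list[str]]:
    """Most-inclusive-rank assignment from candidate hits.

    Per ESV, all hits within ``tolerance`` identity percentage points of
    the best hit are considered equally plausible; the assignment is the
    lineage truncated at the deepest rank on which they all agree. An ESV
    matching two species of different genera in one family at similar
    identity is therefore assigned to the family only.

    Returns (esv → lineage, list of unassignable ESVs — no agreement even
    at the first rank).
    """
    assigned: dict[str, Lineage] = {}
    unassigned: list[str] = []
    for esv, candidates in hits.by_esv().items():
        best = max(ident for _, ident in candidates)
        retained = [lin for lin, ident in candidates if ident >= best - tolerance]
        depth = min(l.depth for l in retained)
        agree = 0
        for i in range(depth):
            if len({l.names[i] for l in retained}) == 1:
                agree = i + 1
            else:
                break
        if agree == 0:
            unassigned.append(esv)
            logger.warning("ESV %s: retained hits disagree at kingdom", esv)
        else:
            ref = retained[0]
            assigned[esv] = Lineage(ref.names[:agree], ref.ladder)
    return assigned, unassigned


def sequence_identity(a: str, b: str) -> float:
    """Pairwise identity = 1 − levenshtein / max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_motus(
    esvs: Sequence[tuple[str, str, Lineage]],
    identity: float = 0.98,
    totals: Optional[Mapping[str, float]] = None,
) -> dict[str, TaxonLabel]:
    """Cluster non-species ESVs into numbered MOTUs within each lineage.

    Within each identical-lineage group, single-linkage clustering joins
    ESVs whose pairwise identity reaches ``identity``; clusters are
    numbered 1..k by decreasing total read count (ties by smallest ESV
    id) giving labels like "Carabidae 1". Species-level ESVs must not be
    passed here (they carry no MOTU label).

    ``esvs``: (esv id, sequence, assigned lineage) triples.
    ``totals``: per-ESV total reads used for deterministic numbering
    (defaults to 0, i.e. numbering by ESV id).
    """
    totals = totals or {}
    by_lineage: dict[tuple, list[tuple[str, str]]] = {}
    for esv, seq, lin in esvs:
        if lin.is_species_level:
            raise ValueError(f"ESV {esv} is species-level; no MOTU needed")
        by_lineage.setdefault((lin.names, lin.ladder), []).append((esv, seq))

    labels: dict[str, TaxonLabel] = {}
    for (names, ladder), members in by_lineage.items():
        lin = Lineage(names, ladder)
        g = nx.Graph()
        g.add_nodes_from(e for e, _ in members)
        for i, (ea, sa) in enumerate(members):
            for eb, sb in members[i + 1:]:
                if sequence_identity(sa, sb) >= identity:
                    g.add_edge(ea, eb)
        clusters = [sorted(c) for c in nx.connected_components(g)]
        clusters.sort(
            key=lambda c: (-sum(totals.get(e, 0) for e in c), c[0])
        )
        for num, cluster in enumerate(clusters, start=1):
            for esv in cluster:
                labels[esv] = TaxonLabel(lineage=lin, motu=num)
    return labels


def exclude_taxa(
    detections: Sequence[Detection],
    policy: ExclusionPolicy,
    log: Optional[ProvenanceLog] = None,
) -> list[Detection]:
    """Drop detections of non-dietary taxa, logging each removal reason."""
    kept = []
    for d in detections:
        reason = policy.excludes(d.lineage)
        if reason is None:
            kept.append(d)
        elif log:
            log.record(
                "exclusion",
                f"{d.sample}/{d.marker}/{d.taxon.display}",
                "removed",
                reason,
            )
    return kept


def to_detections(
    table: ESVTable, labels: Mapping[str, TaxonLabel]
) -> list[Detection]:
    """Presence/absence detections: one per (sample, marker, taxon) pair.

    Multiple ESVs carrying the same TaxonLabel in a sample collapse to a
    single detection; zero counts yield none.
    """
    seen: set[tuple[str, TaxonLabel]] = set()
    out: list[Detection] = []
    for esv in table.esv_ids:
        if esv not in labels:
            continue
        taxon = labels[esv]
        row = table.counts.loc[esv]
        for sample in table.counts.columns[row > 0]:
            key = (str(sample), taxon)
            if key not in seen:
                seen.add(key)
                out.append(
                    Detection(sample=str(sample), marker=table.marker,
                              taxon=taxon)
                )
    return out


def run_marker_pipeline(
    table: ESVTable,
    cfg: MarkerConfig,
    hits: HitTable,
    policy: Optional[ExclusionPolicy] = None,
    lca_tolerance: float = 1.0,
    log: Optional[ProvenanceLog] = None,
) -> tuple[list[Detection], ESVTable]:
    """Run the full fixed-order cascade for one marker.

    Order: length → one-off denoise → PCR failure → relative abundance →
    LCA assignment → MOTU clustering → exclusion. Returns the clean
    detections and the filtered ESV table.
    """
    policy = policy or ExclusionPolicy()
    t = filter_length(table, cfg, log)
    t = denoise_one_off(t, log)
    t = drop_failed_pcrs(t, cfg, log)
    t = relative_abundance_filter(t, cfg, log)

    assigned, unassigned = assign_lca(hits, tolerance=lca_tolerance)
    if log:
        for esv in t.esv_ids:
            if esv in unassigned:
                log.record("assignment", esv, "flagged", "hits disagree at kingdom")
            elif esv not in assigned:
                log.record("assignment", esv, "flagged", "no hits")

    totals = t.totals()
    species_labels = {
        e: TaxonLabel(lineage=assigned[e])
        for e in t.esv_ids
        if e in assigned and assigned[e].is_species_level
    }
    sub_species = [
        (e, t.sequences[e], assigned[e])
        for e in t.esv_ids
        if e in assigned and not assigned[e].is_species_level
    ]
    motu_labels = cluster_motus(
        sub_species, identity=cfg.motu_identity,
        totals={e: float(totals[e]) for e in t.esv_ids},
    )
    labels = {**species_labels, **motu_labels}
    detections = to_detections(t, labels)
    detections = exclude_taxa(detections, policy, log)
    return detections, t
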