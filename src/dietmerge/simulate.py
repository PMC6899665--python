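"""Deterministic synthetic fixtures for every pipeline stage.

Two generators, both fully seeded:

* :func:`generate_detection_fixture` emulates multi-marker detection
  tables: samples ingest taxa from a shared pool, each marker reports an
  ingested taxon at a rank drawn from its own resolution distribution,
  and cross-marker redundancy is planted at a controlled rate. True taxa
  get lineages with names unique at every rank, so detections of
  different taxa never chain under the prefix relation and the expected
  post-merge count per sample is known exactly by construction.

* :func:`generate_esv_fixture` emulates per-marker ESV count tables with
  one-base-pair error structure: true ESVs (pairwise ≥3 edits apart)
  with planted error children one substitution away, strictly less
  abundant than both their parent and the per-PCR relative-abundance
  floor, and co-occurring only with their parents — exactly the
  signature the denoise + abundance filters are built to remove.

The defaults mirror a four-marker faecal metabarcoding study of an
omnivorous bird: a universal eukaryote 18S marker, a plant trnL marker
and two arthropod markers (16S and COI) with different taxonomic
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .esv import ESVTable, HitTable, MarkerConfig, STUDY_MARKERS
from .merge import Detection
from .taxonomy import LINNAEAN, Lineage, RankLadder, TaxonLabel

__all__ = [
    "MarkerSim",
    "FixtureSpec",
    "ESVFixtureSpec",
    "generate_detection_fixture",
    "generate_esv_fixture",
    "random_merge_instance",
    "DEFAULT_SPEC",
]


@dataclass(frozen=True)
class MarkerSim:
    """How one marker behaves in the detection simulator.

    ``resolution`` is a distribution over the rank at which the marker
    reports an ingested taxon; ``kingdoms`` its taxonomic scope;
    ``detect_prob`` the probability the marker recovers a taxon it is the
    primary detector for.
    """

    marker: str
    kingdoms: tuple[str, ...]
    resolution: Mapping[str, float]
    detect_prob: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.resolution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"resolution probabilities sum to {total}, not 1")


# Study-like marker behaviour: scopes and genus/species resolution shares
# (18S ~19% of plant taxa at genus/species, trnL ~54%, 16S ~31%, COI ~42%).
DEFAULT_MARKER_SIMS = (
    MarkerSim("18S", ("Plantae", "Animalia"),
              {"order": 0.40, "family": 0.41, "genus": 0.09, "species": 0.10}),
    MarkerSim("trnL", ("Plantae",),
              {"order": 0.16, "family": 0.30, "genus": 0.24, "species": 0.30}),
    MarkerSim("IN16STK", ("Animalia",),
              {"order": 0.29, "family": 0.40, "genus": 0.13, "species": 0.18}),
    MarkerSim("ZBJ", ("Animalia",),
              {"order": 0.18, "family": 0.40, "genus": 0.17, "species": 0.25}),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for the detection-table simulator.

    Defaults approximate the study design: 115 faecal samples, a pool of
    124 plant and 250 animal taxa, about 5 plant and 8 animal ingested
    taxa per sample, and a cross-marker redundancy rate (probability
    that each non-primary in-scope marker also detects an ingested
    taxon) yielding roughly a quarter of occurrences redundant.
    """

    n_samples: int = 115
    markers: tuple[MarkerSim, ...] = DEFAULT_MARKER_SIMS
    pool_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"Plantae": 124, "Animalia": 250}
    )
    mean_taxa: Mapping[str, float] = field(
        default_factory=lambda: {"Plantae": 5.3, "Animalia": 7.9}
    )
    redundancy_rate: float = 0.30
    ladder: RankLadder = LINNAEAN

    def __post_init__(self) -> None:
        if not (0 <= self.redundancy_rate <= 1):
            raise ValueError("redundancy_rate must be in [0, 1]")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


DEFAULT_SPEC = FixtureSpec()


def _taxon_pool(spec: FixtureSpec) -> list[Lineage]:
    """Species-level lineages with names unique at every rank.

    Uniqueness below kingdom guarantees that two distinct taxa are never
    prefix-compatible, which is what makes the truth table exact.
    """
    pool = []
    for kingdom, size in spec.pool_sizes.items():
        tag = kingdom[:3].lower()
        for i in range(size):
            names = [kingdom] + [
                f"{rank[:3]}_{tag}{i:04d}" for rank in spec.ladder.ranks[1:]
            ]
            pool.append(Lineage(tuple(names), spec.ladder))
    return pool


def generate_detection_fixture(
    spec: FixtureSpec = DEFAULT_SPEC, seed: int = 0
) -> tuple[list[Detection], pd.DataFrame]:
    """Simulate per-sample per-marker detections with known merge truth.

    Returns the detections plus a truth table with one row per sample:
    ``true_taxa`` (taxa detected by at least one marker — the expected
    post-merge group count), ``n_detections``, and ``redundancy``
    (detections minus true taxa, the planted cross-marker duplication).
    """
    rng = np.random.default_rng(seed)
    pool = _taxon_pool(spec)
    by_kingdom: dict[str, list[Lineage]] = {}
    for lin in pool:
        by_kingdom.setdefault(lin.kingdom, []).append(lin)

    # marker-local, sample-global MOTU registries: truncated lineage -> label
    motu_reg: dict[str, dict[tuple, int]] = {m.marker: {} for m in spec.markers}

    def label_for(marker: MarkerSim, lineage: Lineage, rank: str) -> TaxonLabel:
        trunc = lineage.truncate(rank)
        assert trunc is not None
        if trunc.is_species_level:
            return TaxonLabel(lineage=trunc)
        reg = motu_reg[marker.marker]
        key = trunc.names
        if key not in reg:
            reg[key] = len(reg) + 1
        return TaxonLabel(lineage=trunc, motu=reg[key])

    detections: list[Detection] = []
    truth_rows = []
    for s in range(spec.n_samples):
        sample = f"S{s + 1:03d}"
        detected_taxa = 0
        n_det_sample = 0
        for kingdom, taxa in by_kingdom.items():
            k = max(1, int(rng.poisson(spec.mean_taxa.get(kingdom, 0.0))))
            chosen = rng.choice(len(taxa), size=min(k, len(taxa)), replace=False)
            eligible = [m for m in spec.markers if kingdom in m.kingdoms]
            if not eligible:
                continue
            for idx in chosen:
                lineage = taxa[int(idx)]
                primary = eligible[int(rng.integers(len(eligible)))]
                reporters = []
                if rng.random() < primary.detect_prob:
                    reporters.append(primary)
                for m in eligible:
                    if m is primary:
                        continue
                    if rng.random() < spec.redundancy_rate:
                        reporters.append(m)
                if not reporters:
                    continue
                detected_taxa += 1
                for m in reporters:
                    ranks = list(m.resolution)
                    probs = np.array([m.resolution[r] for r in ranks])
                    rank = ranks[int(rng.choice(len(ranks), p=probs / probs.sum()))]
                    detections.append(
                        Detection(
                            sample=sample,
                            marker=m.marker,
                            taxon=label_for(m, lineage, rank),
                        )
                    )
                    n_det_sample += 1
        truth_rows.append(
            {
                "sample_id": sample,
                "true_taxa": detected_taxa,
                "n_detections": n_det_sample,
                "redundancy": n_det_sample - detected_taxa,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return detections, truth


# ---------------------------------------------------------------------------
# ESV-level fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ESVFixtureSpec:
    """Conditions for the ESV-table simulator (one marker at a time)."""

    marker: MarkerConfig = STUDY_MARKERS["18S"]
    n_true: int = 20
    n_pcrs: int = 12
    esvs_per_pcr: tuple[int, int] = (3, 8)
    reads_per_esv: tuple[int, int] = (500, 2000)
    error_rate: float = 0.5
    #: planted child's reads as a fraction of its parent's per-PCR count;
    #: kept well under the 1% per-PCR floor and the parent's own count
    error_abundance: float = 0.003
    force_failed_pcr: bool = True
    ladder: RankLadder = LINNAEAN

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate <= 1):
            raise ValueError("error_rate must be in [0, 1]")
        if not (0 < self.error_abundance < 0.01):
            raise ValueError("error_abundance must stay below the 1% floor")


_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _min_distance(seq: str, others: Sequence[str]) -> int:
    best = len(seq)
    for o in others:
        d = edlib.align(seq, o, task="distance", k=3)["editDistance"]
        if d != -1:
            best = min(best, d)
    return best


def _mutate_one(rng: np.random.Generator, seq: str) -> str:
    pos = int(rng.integers(len(seq)))
    alt = _BASES[int(rng.integers(4))]
    while alt == seq[pos]:
        alt = _BASES[int(rng.integers(4))]
    return seq[:pos] + alt + seq[pos + 1:]


def generate_esv_fixture(
    spec: ESVFixtureSpec = ESVFixtureSpec(), seed: int = 0
) -> tuple[ESVTable, HitTable, dict]:
    """Simulate a per-marker ESV table with planted one-off errors.

    True ESVs are random sequences inside the marker's length window,
    pairwise at least 3 edits apart, each abundant in the PCRs where it
    occurs. A fraction of them gets an error child one substitution
    away, present only in PCRs where the parent is, at
    ``error_abundance`` of the parent's count (always below both the
    parent and 1% of the PCR total). Optionally one extra PCR is forced
    under the 100-read failure threshold.

    Returns (table, hit table, truth) where ``truth`` lists
    ``true_esvs``, ``error_esvs`` and ``failed_pcrs``.
    """
    rng = np.random.default_rng(seed)
    cfg = spec.marker

    seqs: dict[str, str] = {}
    true_ids = []
    while len(true_ids) < spec.n_true:
        length = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        s = _random_seq(rng, length)
        if _min_distance(s, list(seqs.values())) >= 3:
            esv = f"ESV{len(true_ids) + 1:03d}"
            seqs[esv] = s
            true_ids.append(esv)

    pcrs = [f"S{i + 1:03d}" for i in range(spec.n_pcrs)]
    counts = pd.DataFrame(0, index=true_ids, columns=pcrs, dtype=int)
    lo, hi = spec.esvs_per_pcr
    rlo, rhi = spec.reads_per_esv
    for p in pcrs:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(true_ids), size=min(k, len(true_ids)),
                            replace=False)
        for idx in chosen:
            counts.loc[true_ids[int(idx)], p] = int(rng.integers(rlo, rhi + 1))

    # every true ESV must occur somewhere
    for esv in true_ids:
        if counts.loc[esv].sum() == 0:
            p = pcrs[int(rng.integers(len(pcrs)))]
            counts.loc[esv, p] = int(rng.integers(rlo, rhi + 1))

    # planted one-off error children
    error_ids = []
    for esv in true_ids:
        if rng.random() >= spec.error_rate:
            continue
        child = f"{esv}_err"
        child_seq = _mutate_one(rng, seqs[esv])
        # the mutation must not land within 1 edit of another true ESV
        if _min_distance(child_seq,
                         [seqs[t] for t in true_ids if t != esv]) < 2:
            continue
        seqs[child] = child_seq
        row = (counts.loc[esv] * spec.error_abundance).round().astype(int)
        row[counts.loc[esv] > 0] = row[counts.loc[esv] > 0].clip(lower=1)
        counts.loc[child] = row
        error_ids.append(child)

    failed = []
    if spec.force_failed_pcr:
        p = "S_FAIL"
        counts[p] = 0
        esv = true_ids[int(rng.integers(len(true_ids)))]
        counts.loc[esv, p] = int(rng.integers(10, cfg.min_pcr_reads - 10))
        failed.append(p)

    table = ESVTable(marker=cfg.marker, sequences=seqs, counts=counts)

    # hit table: species- or family-level identifications per true ESV;
    # children inherit the parent's hits at slightly lower identity
    pool = _taxon_pool(FixtureSpec(pool_sizes={"Animalia": spec.n_true},
                                   ladder=spec.ladder))
    rows = []
    lineages: dict[str, Lineage] = {}
    for i, esv in enumerate(true_ids):
        lin = pool[i]
        if rng.random() < 0.5:  # family-level only
            lin = Lineage(lin.names[:5], lin.ladder)
        lineages[esv] = lin
        rows.append((esv, lin, float(rng.uniform(98.0, 100.0))))
    for child in error_ids:
        parent = child[:-4]
        rows.append((child, lineages[parent],
                     float(rng.uniform(96.0, 98.0))))
    hits = HitTable(rows=tuple(rows))

    truth = {
        "true_esvs": sorted(true_ids),
        "error_esvs": sorted(error_ids),
        "failed_pcrs": failed,
    }
    return table, hits, truth


# ---------------------------------------------------------------------------
# adversarial merge instances (oracle cross-checking)
# ---------------------------------------------------------------------------

def random_merge_instance(
    rng: np.random.Generator,
    max_detections: int = 8,
    max_markers: int = 4,
    n_names_per_rank: int = 2,
    ladder: RankLadder = LINNAEAN,
) -> list[Detection]:
    """A random single-sample merge instance with heavy lineage overlap.

    Lineages are drawn from a tiny name alphabet (``n_names_per_rank``
    choices at each rank) so that prefix chains and rank conflicts are
    both common — the adversarial regime for the minimum-partition
    search. Duplicate (marker, taxon) pairs are discarded, preserving the
    within-marker uniqueness invariant.
    """
    markers = [f"M{i + 1}" for i in range(int(rng.integers(2, max_markers + 1)))]
    n = int(rng.integers(1, max_detections + 1))
    detections: list[Detection] = []
    seen: set[tuple[str, tuple, Optional[int]]] = set()
    depth_max = len(ladder)
    for _ in range(4 * n):
        if len(detections) >= n:
            break
        depth = int(rng.integers(3, depth_max + 1))
        names = tuple(
            f"{ladder.ranks[i][:3]}{int(rng.integers(n_names_per_rank))}"
            for i in range(depth)
        )
        lineage = Lineage(names, ladder)
        motu = None if lineage.is_species_level else int(rng.integers(1, 3))
        marker = markers[int(rng.integers(len(markers)))]
        key = (marker, names, motu)
        if key in seen:
            continue
        seen.add(key)
        detections.append(
            Detection(sample="S1", marker=marker,
                      taxon=TaxonLabel(lineage=lineage, motu=motu))
        )
    return detections
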