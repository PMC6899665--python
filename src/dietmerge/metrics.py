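"""Dietary descriptors and method-comparison statistics.

Computed on presence/absence detections or merged samples: frequency of
occurrence (FOO) per taxon or order, per-sample richness with standard
errors, taxonomic-resolution profiles, and Czekanowski's niche overlap
index between methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .merge import Detection, MergedSample
from .taxonomy import Lineage, RankLadder

__all__ = [
    "MethodProfile",
    "frequency_of_occurrence",
    "richness_per_sample",
    "czekanowski",
    "overlap_matrix",
    "resolution_profile",
]


@dataclass(frozen=True)
class MethodProfile:
    """Frequency-of-occurrence profile of one method (marker, morphology,
    or the multi-marker consensus): taxon → fraction of that method's
    samples containing it. The denominator is the number of samples the
    method produced a usable result for."""

    method: str
    foo: Mapping[str, float]
    n_samples: int

    def __post_init__(self) -> None:
        bad = {t: f for t, f in self.foo.items() if not (0 <= f <= 1)}
        if bad:
            raise ValueError(f"frequencies outside [0,1]: {bad}")


def _sample_taxa(
    samples: Sequence[Union[MergedSample, Detection]],
    level: Optional[str],
) -> dict[str, set[str]]:
    """Per-sample sets of taxon keys at the requested level.

    ``level=None`` keys by full taxon label (lineage + MOTU number);
    a rank name keys by the lineage truncated to that rank, so two MOTUs
    of one family count once at family level.
    """
    out: dict[str, set[str]] = {}
    def add(sample: str, lineage: Lineage, display: str) -> None:
        taxa = out.setdefault(sample, set())
        if level is None:
            taxa.add(display)
        else:
            trunc = lineage.truncate(level)
            if trunc is not None:
                taxa.add(trunc.format())

    for item in samples:
        if isinstance(item, MergedSample):
            for g in item.groups:
                add(item.sample, g.representative.lineage,
                    f"{g.representative.lineage.format()}|{g.representative.motu or ''}")
        elif isinstance(item, Detection):
            add(item.sample, item.lineage,
                f"{item.lineage.format()}|{item.taxon.motu or ''}")
        else:
            raise TypeError(f"unsupported item {type(item)!r}")
    return out


def frequency_of_occurrence(
    samples: Sequence[Union[MergedSample, Detection]],
    level: Optional[str] = None,
    method: str = "method",
    n_samples: Optional[int] = None,
) -> MethodProfile:
    """FOO per taxon (or per truncated rank): fraction of samples with ≥1
    detection. ``n_samples`` overrides the denominator when some analysed
    samples contained no detections at all."""
    per_sample = _sample_taxa(samples, level)
    n = n_samples if n_samples is not None else len(per_sample)
    if n == 0:
        raise ValueError("frequency_of_occurrence needs at least one sample")
    counts: dict[str, int] = {}
    for taxa in per_sample.values():
        for t in taxa:
            counts[t] = counts.get(t, 0) + 1
    return MethodProfile(
        method=method,
        foo={t: c / n for t, c in sorted(counts.items())},
        n_samples=n,
    )


def richness_per_sample(
    samples: Sequence[MergedSample],
    level: str = "taxon",
) -> tuple[pd.Series, float, float]:
    """Per-sample taxon (or per-rank) richness, with mean ± standard error.

    ``level="taxon"`` counts merge groups — species plus higher-rank
    MOTUs, the study's definition of taxa per sample. A rank name counts
    distinct lineages truncated at that rank. SE = sample SD / sqrt(n).
    """
    if level == "taxon":
        counts = pd.Series(
            {m.sample: m.richness for m in samples}, dtype=float
        ).sort_index()
    else:
        per_sample = _sample_taxa(samples, level)
        counts = pd.Series(
            {m.sample: len(per_sample.get(m.sample, set())) for m in samples},
            dtype=float,
        ).sort_index()
    n = len(counts)
    mean = float(counts.mean()) if n else 0.0
    se = float(counts.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return counts, mean, se


def czekanowski(
    a: MethodProfile, b: MethodProfile, normalize: bool = True
) -> float:
    """Czekanowski's overlap index between two methods.

    ``1 − 0.5 Σ_i |p_ai − p_bi|`` over the union of taxa (missing taxa
    contribute 0). With ``normalize=True`` (default) each method's FOO
    vector is first divided by its sum — the proportional-utilization
    convention of niche-overlap null-model analyses; ``normalize=False``
    uses raw FOO values. Ranges from 0 (disjoint diets) to 1 (identical).
    """
    taxa = sorted(set(a.foo) | set(b.foo))
    if not taxa:
        raise ValueError("both profiles are empty")
    pa = np.array([a.foo.get(t, 0.0) for t in taxa])
    pb = np.array([b.foo.get(t, 0.0) for t in taxa])
    if pa.sum() == 0 or pb.sum() == 0:
        raise ValueError("a profile with all-zero FOO has no utilization")
    if normalize:
        pa = pa / pa.sum()
        pb = pb / pb.sum()
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def overlap_matrix(
    profiles: Sequence[MethodProfile], normalize: bool = True
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Czekanowski indices across methods."""
    names = [p.method for p in profiles]
    m = pd.DataFrame(np.eye(len(profiles)), index=names, columns=names)
    for i, p in enumerate(profiles):
        for j in range(i + 1, len(profiles)):
            v = czekanowski(p, profiles[j], normalize=normalize)
            m.iloc[i, j] = m.iloc[j, i] = v
    return m


def resolution_profile(
    samples: Sequence[MergedSample],
) -> pd.DataFrame:
    """Counts of distinct taxa and of occurrences per deepest assigned rank.

    A taxon's resolution is the deepest rank of its representative
    lineage; occurrences count (sample, taxon) pairs. Returns a frame
    indexed by rank with columns ``taxa`` and ``occurrences``.
    """
    if not samples:
        return pd.DataFrame(columns=["taxa", "occurrences"])
    ladder = samples[0].groups[0].representative.lineage.ladder if any(
        s.groups for s in samples
    ) else None
    taxa_by_rank: dict[str, set] = {}
    occ_by_rank: dict[str, int] = {}
    for s in samples:
        for g in s.groups:
            rank = g.representative.lineage.deepest_rank
            key = (g.representative.lineage.names, g.representative.motu)
            taxa_by_rank.setdefault(rank, set()).add(key)
            occ_by_rank[rank] = occ_by_rank.get(rank, 0) + 1
    ranks = list(ladder.ranks) if ladder else sorted(taxa_by_rank)
    rows = {
        r: {"taxa": len(taxa_by_rank.get(r, set())),
            "occurrences": occ_by_rank.get(r, 0)}
        for r in ranks
        if r in taxa_by_rank
    }
    return pd.DataFrame.from_dict(rows, orient="index")[["taxa", "occurrences"]]
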