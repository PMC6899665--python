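"""Per-sample integration of detections from taxonomically overlapping markers.

Different barcoding markers recover the same ingested item at different
taxonomic depths. Within one sample, a detection whose lineage is a prefix
of another marker's finer detection is taken to be the same item, and the
group keeps the finest lineage; lineages that conflict at any shared rank
are distinct items. Formally each sample's detections are partitioned into
the minimum number of groups such that every group contains at most one
detection per marker and its lineages form a chain under the prefix
relation. Minimising the group count is the conservative choice: it never
overestimates dietary diversity. MOTU identities are marker-local, so
merging is decided independently sample by sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .taxonomy import Lineage, TaxonLabel, is_extension

__all__ = [
    "Detection",
    "MergeGroup",
    "MergedSample",
    "merge_sample",
    "merge_all",
    "merge_oracle",
    "occurrence_reduction",
]


@dataclass(frozen=True)
class Detection:
    """One taxon observed in one sample by one marker."""

    sample: str
    marker: str
    taxon: TaxonLabel

    @property
    def lineage(self) -> Lineage:
        return self.taxon.lineage


@dataclass(frozen=True)
class MergeGroup:
    """A set of detections judged to be one ingested item.

    Members come from distinct markers and their lineages form a chain
    under the prefix relation; the representative is the deepest member
    (ties between identical lineages are immaterial — the lineage is the
    same).
    """

    members: tuple[Detection, ...]
    representative: TaxonLabel

    @property
    def n_markers(self) -> int:
        return len({d.marker for d in self.members})


@dataclass(frozen=True)
class MergedSample:
    """The post-integration taxa list for one sample."""

    sample: str
    groups: tuple[MergeGroup, ...]

    @property
    def richness(self) -> int:
        """Taxon richness = number of groups (species + higher-rank MOTUs)."""
        return len(self.groups)


class DuplicateDetectionError(ValueError):
    """A (sample, marker) carried the same TaxonLabel twice."""


def _chain_compatible(group: Sequence[Detection], d: Detection) -> bool:
    """Can ``d`` join ``group`` while keeping it a marker-disjoint chain?"""
    for m in group:
        if m.marker == d.marker:
            return False
        if not (
            is_extension(m.lineage, d.lineage)
            or is_extension(d.lineage, m.lineage)
        ):
            return False
    return True


def _canonical_order(detections: Iterable[Detection]) -> list[Detection]:
    """Deterministic processing order: deepest lineages first.

    Sorting by decreasing depth means every detection added to a group is
    a prefix of (or equal to) some member already there, which makes the
    chain check cheap and the branch-and-bound effective.
    """
    return sorted(
        detections,
        key=lambda d: (
            -d.lineage.depth,
            d.lineage.format(),
            d.marker,
            -1 if d.taxon.motu is None else d.taxon.motu,
        ),
    )


def _group_key(groups: Sequence[Sequence[Detection]]) -> tuple:
    """Tie-break key for a complete partition (higher is preferred).

    Among minimum-cardinality partitions prefer the one maximising summed
    representative depth, then the lexicographically smallest sorted tuple
    of representative lineage strings.
    """
    reps = []
    depth_sum = 0
    for g in groups:
        rep = max(g, key=lambda d: d.lineage.depth)
        depth_sum += rep.lineage.depth
        reps.append(rep.lineage.format())
    # negate the string sort by inverting comparison later; build a key that
    # sorts "better" partitions higher: (depth_sum, reversed-lex preference)
    return (depth_sum, tuple(sorted(reps)))


def _better(key_a: tuple, key_b: tuple) -> bool:
    """True if partition key_a beats key_b (depth first, then lex-smaller)."""
    if key_a[0] != key_b[0]:
        return key_a[0] > key_b[0]
    return key_a[1] < key_b[1]


def _validate(detections: Sequence[Detection]) -> None:
    seen: set[tuple[str, str, TaxonLabel]] = set()
    for d in detections:
        k = (d.sample, d.marker, d.taxon)
        if k in seen:
            raise DuplicateDetectionError(
                f"duplicate taxon {d.taxon.display!r} for marker "
                f"{d.marker!r} in sample {d.sample!r}"
            )
        seen.add(k)


def _components(ordered: Sequence[Detection]) -> list[list[Detection]]:
    """Connected components of the pairwise chain-compatibility graph.

    Two detections that are never chain-compatible can never share a
    group, so the minimum partition decomposes additively over
    components; solving per component keeps the exact search fast even
    when a sample holds many mutually incompatible taxa.
    """
    n = len(ordered)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = ordered[i], ordered[j]
            if a.marker != b.marker and (
                is_extension(a.lineage, b.lineage)
                or is_extension(b.lineage, a.lineage)
            ):
                parent[find(i)] = find(j)
    comps: dict[int, list[Detection]] = {}
    for i, d in enumerate(ordered):
        comps.setdefault(find(i), []).append(d)
    # deterministic component order: by first member in canonical order
    return [comps[k] for k in sorted(comps, key=lambda k: min(
        i for i in range(n) if find(i) == k))]


def _search_min_partition(
    ordered: Sequence[Detection],
) -> list[list[Detection]]:
    """Exact minimum chain partition by depth-first branch and bound.

    Detections are assigned in canonical order to an existing compatible
    group or a new group; branches that cannot beat the best complete
    partition found so far are pruned. All minimum partitions reachable
    under the canonical order are compared under the deterministic
    tie-break.
    """
    n = len(ordered)
    best_count = n + 1
    best_key: Optional[tuple] = None
    best: Optional[list[list[Detection]]] = None

    groups: list[list[Detection]] = []

    def recurse(i: int) -> None:
        nonlocal best_count, best_key, best
        if len(groups) > best_count:
            return
        if i == n:
            if not groups:
                return
            key = _group_key(groups)
            if len(groups) < best_count or (
                len(groups) == best_count
                and (best_key is None or _better(key, best_key))
            ):
                best_count = len(groups)
                best_key = key
                best = [list(g) for g in groups]
            return
        d = ordered[i]
        for g in groups:
            if _chain_compatible(g, d):
                g.append(d)
                recurse(i + 1)
                g.pop()
        if len(groups) < best_count:
            groups.append([d])
            recurse(i + 1)
            groups.pop()

    recurse(0)
    assert best is not None or n == 0
    return best or []


def _greedy_partition(ordered: Sequence[Detection]) -> list[list[Detection]]:
    """First-fit greedy over the canonical order (fast path, may be
    suboptimal on adversarial instances; the exact search is the default)."""
    groups: list[list[Detection]] = []
    for d in ordered:
        for g in groups:
            if _chain_compatible(g, d):
                g.append(d)
                break
        else:
            groups.append([d])
    return groups


def _to_merged(sample: str, raw_groups: list[list[Detection]]) -> MergedSample:
    merged = []
    for g in raw_groups:
        rep = max(g, key=lambda d: (d.lineage.depth, d.lineage.format()))
        members = tuple(
            sorted(g, key=lambda d: (d.marker, d.lineage.format()))
        )
        merged.append(MergeGroup(members=members, representative=rep.taxon))
    merged.sort(key=lambda g: (g.representative.lineage.format(),
                               g.representative.motu or 0))
    return MergedSample(sample=sample, groups=tuple(merged))


def merge_sample(
    detections: Sequence[Detection], exact: bool = True
) -> MergedSample:
    """Merge one sample's multi-marker detections into a minimal taxa list.

    Parameters
    ----------
    detections
        All detections of a single sample (any order).
    exact
        Use the exact branch-and-bound search (default). ``False`` selects
        the greedy first-fit fast path.

    Returns
    -------
    MergedSample
        A partition of the detections into marker-disjoint chains of
        minimum cardinality; its group count is the sample's taxon
        richness.
    """
    detections = list(detections)
    if not detections:
        raise ValueError("merge_sample requires at least one detection")
    samples = {d.sample for d in detections}
    if len(samples) > 1:
        raise ValueError(f"detections span multiple samples: {sorted(samples)}")
    _validate(detections)
    ordered = _canonical_order(detections)
    if exact:
        raw = []
        for comp in _components(ordered):
            raw.extend(_search_min_partition(comp))
    else:
        raw = _greedy_partition(ordered)
    return _to_merged(detections[0].sample, raw)


def merge_all(
    detections: Iterable[Detection], exact: bool = True
) -> list[MergedSample]:
    """Apply :func:`merge_sample` independently to every sample.

    MOTU identities are never linked across samples: the same pair of
    labels may merge in one sample and not in another.
    """
    by_sample: dict[str, list[Detection]] = {}
    for d in detections:
        by_sample.setdefault(d.sample, []).append(d)
    return [
        merge_sample(by_sample[s], exact=exact) for s in sorted(by_sample)
    ]


def _partitions(items: list):
    """All set partitions of ``items`` (exhaustive, exponential)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1:]
        yield part + [[first]]


def merge_oracle(detections: Sequence[Detection]) -> int:
    """Exact minimum group count by exhaustive partition enumeration.

    Independent verification oracle for :func:`merge_sample`; refuses
    instances above 12 detections (Bell numbers grow too fast).
    """
    detections = list(detections)
    if len(detections) > 12:
        raise ValueError("oracle limited to 12 detections")
    if not detections:
        return 0
    _validate(detections)

    def valid(block: list[Detection]) -> bool:
        for a, b in itertools.combinations(block, 2):
            if a.marker == b.marker:
                return False
            if not (
                is_extension(a.lineage, b.lineage)
                or is_extension(b.lineage, a.lineage)
            ):
                return False
        return True

    best = len(detections)
    for part in _partitions(detections):
        if len(part) < best and all(valid(b) for b in part):
            best = len(part)
    return best


def occurrence_reduction(
    before: Sequence[Detection], after: Sequence[MergedSample]
) -> dict:
    """Account for how many per-marker occurrences the merge collapsed.

    Returns totals before (detections) and after (groups), overall and by
    kingdom of the representative lineage.
    """
    summary: dict = {
        "before": len(before),
        "after": sum(len(m.groups) for m in after),
        "by_kingdom": {},
    }
    kingdoms = sorted(
        {d.lineage.kingdom for d in before}
        | {g.representative.lineage.kingdom for m in after for g in m.groups}
    )
    for k in kingdoms:
        summary["by_kingdom"][k] = {
            "before": sum(1 for d in before if d.lineage.kingdom == k),
            "after": sum(
                1
                for m in after
                for g in m.groups
                if g.representative.lineage.kingdom == k
            ),
        }
    summary["reduction"] = summary["before"] - summary["after"]
    return summary
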