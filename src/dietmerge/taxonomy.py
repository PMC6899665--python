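"""Taxonomic lineages at heterogeneous resolution.

Dietary metabarcoding markers identify the same ingested item at very
different depths: a universal 18S amplicon may only say "Coleoptera",
while a COI amplicon resolves the species. This module represents such
lineages as prefixes of a fixed rank ladder and decides when one lineage
is a refinement (extension) of another — the relation the multi-marker
merge reasons over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: Placeholder prefix for gap-filled ranks: "unk_<rank>_<childname>".
PLACEHOLDER_FMT = "unk_{rank}_{child}"

DEFAULT_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class LadderMismatchError(ValueError):
    """Two lineages aligned to different rank ladders were compared."""


class LineageParseError(ValueError):
    """A lineage string could not be parsed."""


@dataclass(frozen=True)
class RankLadder:
    """Ordered rank names, most inclusive first.

    The ladder is fixed for a run; every :class:`Lineage` is aligned to a
    prefix of it. Defaults to the seven Linnaean ranks.
    """

    ranks: tuple[str, ...] = DEFAULT_RANKS

    def __post_init__(self) -> None:
        if len(set(self.ranks)) != len(self.ranks) or not self.ranks:
            raise ValueError("ranks must be non-empty and unique")

    def __len__(self) -> int:
        return len(self.ranks)

    def index(self, rank: str) -> int:
        return self.ranks.index(rank)

    @property
    def species_index(self) -> int:
        """Index of the deepest rank (species on the default ladder)."""
        return len(self.ranks) - 1


LINNAEAN = RankLadder()


@dataclass(frozen=True)
class Lineage:
    """A taxon path from the top of the ladder down to some rank.

    ``names[i]`` is the taxon at ``ladder.ranks[i]``. The path may stop at
    any rank (truncation encodes limited resolution) but has no internal
    gaps: an unknown intermediate rank is filled with a deterministic
    placeholder token derived from its nearest named descendant, so the
    same gap in two input rows yields the same lineage.
    """

    names: tuple[str, ...]
    ladder: RankLadder = LINNAEAN

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("lineage must name at least one rank")
        if len(self.names) > len(self.ladder):
            raise ValueError(
                f"lineage depth {len(self.names)} exceeds ladder "
                f"length {len(self.ladder)}"
            )
        if any(not n for n in self.names):
            raise ValueError("lineage names must be non-empty strings")

    @property
    def depth(self) -> int:
        return len(self.names)

    @property
    def deepest_rank(self) -> str:
        return self.ladder.ranks[self.depth - 1]

    @property
    def deepest_name(self) -> str:
        return self.names[-1]

    @property
    def kingdom(self) -> str:
        return self.names[0]

    @property
    def is_species_level(self) -> bool:
        return self.depth == len(self.ladder)

    def truncate(self, rank: str) -> Optional["Lineage"]:
        """Lineage cut at ``rank``, or ``None`` if not resolved that deep."""
        idx = self.ladder.index(rank)
        if self.depth <= idx:
            return None
        return Lineage(self.names[: idx + 1], self.ladder)

    def name_at(self, rank: str) -> Optional[str]:
        idx = self.ladder.index(rank)
        return self.names[idx] if idx < self.depth else None

    def format(self, sep: str = ";") -> str:
        return sep.join(self.names)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.format()


def _check_same_ladder(a: Lineage, b: Lineage) -> None:
    if a.ladder != b.ladder:
        raise LadderMismatchError("lineages aligned to different rank ladders")


def is_extension(coarse: Lineage, fine: Lineage) -> bool:
    """True iff ``fine`` refines ``coarse`` (prefix relation, equality ok).

    Placeholder tokens are ordinary names: they match only themselves, so a
    gap-filled rank never spuriously matches a genuinely named one.
    """
    _check_same_ladder(coarse, fine)
    if coarse.depth > fine.depth:
        return False
    return fine.names[: coarse.depth] == coarse.names


def deepest_common_rank(a: Lineage, b: Lineage) -> Optional[str]:
    """Deepest rank at which the two lineages agree; None if they share none."""
    _check_same_ladder(a, b)
    common = -1
    for i in range(min(a.depth, b.depth)):
        if a.names[i] != b.names[i]:
            break
        common = i
    return a.ladder.ranks[common] if common >= 0 else None


def placeholder(rank: str, child: str) -> str:
    """Deterministic token for an unknown rank, derived from its child name."""
    return PLACEHOLDER_FMT.format(rank=rank, child=child)


def is_placeholder(name: str) -> bool:
    return name.startswith("unk_")


def parse_lineage(
    text: str, ladder: RankLadder = LINNAEAN, sep: str = ";"
) -> Lineage:
    """Parse a delimited lineage string into a :class:`Lineage`.

    Trailing empty fields are ignored (they encode "not resolved deeper").
    An internal gap is filled with a placeholder derived from the nearest
    named rank below it, and logged, so parsing is reproducible.
    """
    if not text or not text.strip():
        raise LineageParseError("empty lineage string")
    fields = [f.strip() for f in text.split(sep)]
    # drop trailing empties
    while fields and not fields[-1]:
        fields.pop()
    if not fields:
        raise LineageParseError(f"lineage {text!r} has no named ranks")
    if len(fields) > len(ladder):
        raise LineageParseError(
            f"lineage {text!r} deeper than ladder ({len(ladder)} ranks)"
        )
    names: list[str] = list(fields)
    # fill internal gaps from the nearest named descendant
    next_named = None
    for i in range(len(names) - 1, -1, -1):
        if names[i]:
            next_named = names[i]
        else:
            assert next_named is not None  # trailing empties already dropped
            names[i] = placeholder(ladder.ranks[i], next_named)
            logger.warning(
                "gap at rank %s in lineage %r filled with placeholder %r",
                ladder.ranks[i],
                text,
                names[i],
            )
    return Lineage(tuple(names), ladder)


def format_lineage(lineage: Lineage, sep: str = ";") -> str:
    return lineage.format(sep)


@dataclass(frozen=True)
class TaxonLabel:
    """A taxon as reported by one marker: lineage plus marker-local MOTU.

    When an amplicon cannot be resolved to species, co-occurring similar
    sequences are clustered into molecular OTUs and numbered within their
    lineage ("Carabidae 1", "Carabidae 2"). The MOTU number is present iff
    the lineage stops above species; labels are marker-local — the same
    number under two markers never implies identity.
    """

    lineage: Lineage
    motu: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lineage.is_species_level and self.motu is not None:
            raise ValueError("species-level taxa carry no MOTU label")
        if not self.lineage.is_species_level and self.motu is None:
            raise ValueError(
                "taxa above species level require a MOTU label "
                f"(lineage {self.lineage.format()!r})"
            )

    @property
    def display(self) -> str:
        if self.motu is None:
            return self.lineage.deepest_name
        return f"{self.lineage.deepest_name} {self.motu}"

    def __str__(self) -> str:  # pragma: no cover
        return self.display
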