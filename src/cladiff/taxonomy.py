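"""Taxonomy rank paths.

Microbial features arrive as semicolon-delimited taxonomy strings, either
Greengenes-prefixed (``k__Bacteria;p__Firmicutes;...``) or bare
(``Bacteria;Firmicutes;...``).  A :class:`RankPath` is the validated,
hashable form used throughout the package: an ordered tuple of non-empty
rank names starting at kingdom (level 1) with no gaps, at most seven ranks
deep (kingdom, phylum, class, order, family, genus, species).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
MAX_DEPTH = 7


class TaxonomyParseError(ValueError):
    """Raised for malformed taxonomy strings."""


@dataclass(frozen=True, order=True)
class RankPath:
    """An ordered taxonomy path from kingdom down to some rank.

    Parameters
    ----------
    ranks : tuple of str
        Non-empty rank names, position i = taxonomy level i+1.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise TaxonomyParseError("empty taxonomy path")
        if len(self.ranks) > MAX_DEPTH:
            raise TaxonomyParseError(
                f"taxonomy path deeper than {MAX_DEPTH} ranks: {self.ranks!r}"
            )
        if any(not r for r in self.ranks):
            raise TaxonomyParseError(f"empty rank inside path: {self.ranks!r}")

    @property
    def depth(self) -> int:
        return len(self.ranks)

    @property
    def name(self) -> str:
        """The last (most resolved) rank name."""
        return self.ranks[-1]

    def prefix(self, level: int) -> "RankPath":
        """The ancestor path truncated to ``level`` ranks (1-based)."""
        if not 1 <= level <= self.depth:
            raise ValueError(f"level {level} outside 1..{self.depth}")
        return RankPath(self.ranks[:level])

    @property
    def parent(self) -> "RankPath | None":
        return RankPath(self.ranks[:-1]) if self.depth > 1 else None

    def is_ancestor_of(self, other: "RankPath") -> bool:
        return other.depth > self.depth and other.ranks[: self.depth] == self.ranks

    def rank_at(self, level_name: str) -> str | None:
        """Rank name at a named level (e.g. ``"family"``), or None if unresolved."""
        i = RANK_NAMES.index(level_name)
        return self.ranks[i] if i < self.depth else None

    def __iter__(self) -> Iterator[str]:
        return iter(self.ranks)

    def __str__(self) -> str:
        return ";".join(
            f"{RANK_PREFIXES[i]}{r}" for i, r in enumerate(self.ranks)
        )


def parse_taxonomy_string(s: str, dialect: str = "greengenes") -> RankPath:
    """Parse a semicolon-delimited taxonomy string into a :class:`RankPath`.

    Parameters
    ----------
    s : str
        e.g. ``"k__Bacteria;p__Firmicutes"`` (greengenes dialect) or
        ``"Bacteria;Firmicutes"`` (bare dialect).
    dialect : {"greengenes", "bare"}
        Whether rank prefixes (``k__`` ... ``s__``) are present and checked.

    An empty rank (``"s__"`` or trailing ``";;"``) terminates the path;
    a non-empty rank *after* an empty one is an error, since it would leave
    a feature without an unambiguous parent in the cladogram.
    """
    if not s or not s.strip():
        raise TaxonomyParseError("empty taxonomy string")
    parts = [p.strip() for p in s.strip().rstrip(";").split(";")]
    if len(parts) > MAX_DEPTH:
        raise TaxonomyParseError(f"more than {MAX_DEPTH} ranks in {s!r}")

    names: list[str] = []
    if dialect == "greengenes":
        for i, part in enumerate(parts):
            expected = RANK_PREFIXES[i]
            if not part.startswith(expected):
                # tolerate a bare empty cell but nothing else
                if part == "":
                    names.append("")
                    continue
                raise TaxonomyParseError(
                    f"rank {i + 1} of {s!r}: expected prefix {expected!r}, got {part!r}"
                )
            names.append(part[len(expected):].strip())
    elif dialect == "bare":
        names = parts
    else:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")

    # empty rank truncates; anything non-empty beyond it is malformed
    depth = len(names)
    for i, nm in enumerate(names):
        if nm == "":
            depth = i
            break
    for nm in names[depth:]:
        if nm != "":
            raise TaxonomyParseError(
                f"non-empty rank after an empty rank in {s!r}"
            )
    if depth == 0:
        raise TaxonomyParseError(f"no resolved ranks in {s!r}")
    return RankPath(tuple(names[:depth]))
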