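"""Genome representation, GRIMM-dialect I/O and marker partitioning.

A genome is a set of linear and circular chromosomes over signed markers.
Marker identifiers are arbitrary tokens (gene names, synteny-block ids,
integers); a leading ``-`` denotes reverse orientation.  Duplicated
markers are a hard error: the distance model is undefined for them.

The file dialect is GRIMM-compatible: an optional ``>name`` header line,
then one chromosome per non-blank, non-``#`` line, whitespace-separated
signed markers terminated by ``$`` (linear) or ``@`` (circular).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

_ID_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")


class GenomeError(ValueError):
    """Raised for malformed genome text or model-invariant violations."""


@dataclass(frozen=True, order=True)
class SignedMarker:
    """A marker id together with its reading orientation."""

    id: str
    forward: bool = True

    def reverse(self) -> "SignedMarker":
        return SignedMarker(self.id, not self.forward)

    def __str__(self) -> str:
        return self.id if self.forward else "-" + self.id

    @staticmethod
    def parse(token: str) -> "SignedMarker":
        forward = True
        if token.startswith("-"):
            forward = False
            token = token[1:]
        if not _ID_RE.match(token):
            raise GenomeError(f"invalid marker token: {token!r}")
        return SignedMarker(token, forward)


@dataclass(frozen=True)
class Chromosome:
    """An ordered sequence of signed markers, linear or circular.

    A circular chromosome's reading is invariant under rotation and
    under full reversal with sign flip; equality and hashing go through
    :meth:`canonical`.
    """

    markers: tuple[SignedMarker, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.markers:
            raise GenomeError("empty chromosome")

    def reversed(self) -> "Chromosome":
        return Chromosome(tuple(m.reverse() for m in reversed(self.markers)), self.circular)

    def canonical(self) -> tuple:
        """Canonical key: orientation-free for linear, rotation- and
        orientation-free for circular chromosomes."""
        fwd = tuple((m.id, m.forward) for m in self.markers)
        rev = tuple((m.id, m.forward) for m in self.reversed().markers)
        if not self.circular:
            return ("L", min(fwd, rev))
        best = None
        for seq in (fwd, rev):
            for i in range(len(seq)):
                rot = seq[i:] + seq[:i]
                if best is None or rot < best:
                    best = rot
        return ("C", best)

    def equivalent(self, other: "Chromosome") -> bool:
        return self.circular == other.circular and self.canonical() == other.canonical()


@dataclass
class Genome:
    """A named collection of chromosomes with globally unique marker ids."""

    name: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for m in chrom.markers:
                if m.id in seen:
                    raise GenomeError(
                        f"duplicated marker {m.id!r} in genome {self.name!r}"
                    )
                seen.add(m.id)

    def marker_ids(self) -> set[str]:
        return {m.id for c in self.chromosomes for m in c.markers}

    def iter_markers(self) -> Iterator[SignedMarker]:
        for c in self.chromosomes:
            yield from c.markers

    def canonical(self) -> frozenset:
        """Multiset-free canonical fingerprint (marker ids are unique, so
        a set of canonical chromosomes identifies the genome)."""
        return frozenset(c.canonical() for c in self.chromosomes)

    def equivalent(self, other: "Genome") -> bool:
        return self.canonical() == other.canonical()


@dataclass(frozen=True)
class MarkerPartition:
    """The common markers of a pair plus each genome's unique markers."""

    common: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.common)


def _parse_one(text: str, default_name: str) -> Genome:
    name = default_name
    chromosomes: list[Chromosome] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            name = line[1:].strip() or default_name
            continue
        tokens = line.split()
        if tokens[-1] not in ("$", "@"):
            raise GenomeError(
                f"line {lineno}: chromosome not terminated by '$' or '@'"
            )
        if len(tokens) == 1:
            raise GenomeError(f"line {lineno}: empty chromosome")
        circular = tokens[-1] == "@"
        try:
            markers = tuple(SignedMarker.parse(t) for t in tokens[:-1])
        except GenomeError as exc:
            raise GenomeError(f"line {lineno}: {exc}") from None
        chromosomes.append(Chromosome(markers, circular))
    return Genome(name, chromosomes)


def parse_genome(text: str, default_name: str = "genome") -> Genome:
    """Parse a single GRIMM-dialect genome file."""
    return _parse_one(text, default_name)


def parse_genomes(text_a: str, text_b: str) -> tuple[Genome, Genome]:
    """Parse and validate a pair of genome files."""
    return _parse_one(text_a, "A"), _parse_one(text_b, "B")


def write_genome(g: Genome) -> str:
    """Serialize a genome; round-trips through :func:`parse_genome` up to
    chromosome order, circular rotation and whole-chromosome reversal."""
    lines = [f">{g.name}"]
    for chrom in g.chromosomes:
        body = " ".join(str(m) for m in chrom.markers)
        lines.append(f"{body} {'@' if chrom.circular else '$'}")
    return "\n".join(lines) + "\n"


def partition_markers(a: Genome, b: Genome) -> MarkerPartition:
    """Split marker ids into common (occur in both genomes) and unique sets."""
    ids_a, ids_b = a.marker_ids(), b.marker_ids()
    return MarkerPartition(
        common=frozenset(ids_a & ids_b),
        unique_a=frozenset(ids_a - ids_b),
        unique_b=frozenset(ids_b - ids_a),
    )


def genome_from_lists(
    name: str, chromosomes: Iterable[tuple[list[str | int], bool]]
) -> Genome:
    """Convenience constructor: each entry is (marker tokens, circular).

    Tokens may be ints or strings, with ``-`` prefix (or negative int)
    for reverse orientation.
    """
    chroms = []
    for markers, circular in chromosomes:
        signed = []
        for t in markers:
            if isinstance(t, int):
                signed.append(SignedMarker(str(abs(t)), t > 0))
            else:
                signed.append(SignedMarker.parse(str(t)))
        chroms.append(Chromosome(tuple(signed), circular))
    return Genome(name, chroms)
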