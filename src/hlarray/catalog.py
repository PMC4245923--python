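"""Allele catalogs.

HLA class I alleles are named ``LOCUS*GG:PP`` (e.g. ``A*02:01``): the first
numeric field is the allele group, which in array-based typing plays the role
of the classical serotype and is the unit of the first calling stage; the
second field gives protein-level (4-digit) resolution.  A catalog holds the
nucleotide sequence of every allele the array was designed against.  The
genotype-calling stages additionally require that all alleles of one locus are
mutually aligned column-for-column (equal length, no indels), so that a probe
anchored at position *p* of one allele can be compared with the probe anchored
at *p* of any other allele of the same locus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CatalogError, InvalidSequenceError

_DNA = frozenset("ACGT")
_NAME_RE = re.compile(r"^(?P<locus>[A-Za-z0-9\-]+)\*(?P<group>[0-9A-Za-z]+):(?P<protein>[0-9A-Za-z]+)$")

MIN_PROBE_LENGTH = 20


def parse_allele_name(name: str) -> tuple[str, str, str]:
    """Split ``LOCUS*GG:PP`` into (locus, allele group, protein field).

    Raises :class:`CatalogError` if the name does not follow the nomenclature.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise CatalogError(f"allele name {name!r} does not parse as LOCUS*GG:PP")
    return m.group("locus"), m.group("group"), m.group("protein")


def validate_dna(sequence: str) -> str:
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    if set(sequence) - _DNA:
        bad = sorted(set(sequence) - _DNA)
        raise InvalidSequenceError(f"non-ACGT characters in sequence: {bad}")
    return sequence


@dataclass(frozen=True)
class AlleleSequence:
    """One catalog entry: a named, validated nucleotide sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        parse_allele_name(self.name)
        validate_dna(self.sequence)
        if len(self.sequence) < MIN_PROBE_LENGTH:
            raise CatalogError(
                f"{self.name}: sequence shorter than the minimum probe length "
                f"({len(self.sequence)} < {MIN_PROBE_LENGTH})"
            )

    @property
    def locus(self) -> str:
        return parse_allele_name(self.name)[0]

    @property
    def serotype(self) -> str:
        """Allele-group prefix, e.g. ``A*02`` for ``A*02:01``."""
        locus, group, _ = parse_allele_name(self.name)
        return f"{locus}*{group}"

    def __len__(self) -> int:
        return len(self.sequence)


class AlleleCatalog:
    """An ordered collection of alleles with locus/serotype indexing."""

    def __init__(self, alleles: Iterable[AlleleSequence]):
        self.alleles: list[AlleleSequence] = list(alleles)
        if not self.alleles:
            raise CatalogError("empty allele catalog")
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogError(f"duplicate allele names in catalog: {dupes}")
        self._by_name = {a.name: a for a in self.alleles}

    # -- lookup ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self) -> Iterator[AlleleSequence]:
        return iter(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> AlleleSequence:
        try:
            return self._by_name[name]
        except KeyError:
            raise CatalogError(f"allele {name!r} absent from catalog") from None

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.alleles:
            seen.setdefault(a.locus, None)
        return list(seen)

    def serotypes(self, locus: str) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.alleles:
            if a.locus == locus:
                seen.setdefault(a.serotype, None)
        return list(seen)

    def serotype_members(self, serotype: str) -> list[AlleleSequence]:
        members = [a for a in self.alleles if a.serotype == serotype]
        if not members:
            raise CatalogError(f"serotype {serotype!r} has no alleles in catalog")
        return members

    def locus_members(self, locus: str) -> list[AlleleSequence]:
        return [a for a in self.alleles if a.locus == locus]

    def require_aligned(self, locus: str) -> int:
        """Return the shared alignment length of a locus.

        Genotype-stage comparisons treat the probe anchor as an alignment
        column, which requires all sequences of the locus to have equal length.
        """
        lengths = {len(a) for a in self.locus_members(locus)}
        if len(lengths) != 1:
            raise CatalogError(
                f"locus {locus}: sequences are not mutually aligned "
                f"(lengths {sorted(lengths)}); supply pre-aligned equal-length sequences"
            )
        return lengths.pop()

    # -- IO --------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "AlleleCatalog":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise CatalogError(f"no FASTA records in {path}")
        return cls(AlleleSequence(r.id, str(r.seq).upper()) for r in records)

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(a.sequence), id=a.name, description="") for a in self.alleles]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class SerogroupTable:
    """Mapping serotype -> serogroup id.

    Serogroups cluster serotypes that are so similar (e.g. A*03/A*11) that they
    routinely survive serotype elimination together; the genotype stage builds
    one comparison vector per serogroup cluster.  Serotypes missing from the
    table are treated as singleton serogroups.
    """

    groups: dict[str, str] = field(default_factory=dict)

    def group_of(self, serotype: str) -> str:
        return self.groups.get(serotype, serotype)

    def cluster(self, serotypes: Iterable[str]) -> dict[str, list[str]]:
        """Cluster a set of serotypes by serogroup, preserving input order."""
        out: dict[str, list[str]] = {}
        for st in serotypes:
            out.setdefault(self.group_of(st), []).append(st)
        return out

    @classmethod
    def from_tsv(cls, path) -> "SerogroupTable":
        groups: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                st, grp = line.split("\t")[:2]
                groups[st] = grp
        return cls(groups)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for st in sorted(self.groups):
                fh.write(f"{st}\t{self.groups[st]}\n")
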