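"""Stage 1: serotype determination.

For every allele x, Neg(x) counts the allele's probe placements whose unique
probe is negative; present alleles have few negative probes, absent ones have
many (unless masked by shared probes).  Per serotype the k best-supported
alleles are averaged::

    Neg(ST) = sum(Neg(x)) / k,   Neg(x) ranked ascending, k = min(5, N)

Serotypes are ranked ascending by Neg(ST); the locus is called homozygous when
the runner-up trails the leader by at least 20 negative probes, and serotypes
ranked behind second place are eliminated when their margin over the leader
exceeds MaxDifference.  The stage is engineered for zero false negatives: the
top two serotypes are never eliminated, and pairs known to be
indistinguishable at serotype level are exempt from elimination and passed on
to genotype determination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import AlleleCatalog
from .errors import CatalogError
from .probes import ProbeSet

HOMOZYGOUS_MARGIN = 20.0
DEFAULT_MAX_DIFFERENCE = 30.0


def count_negatives(
    allele: str,
    calls: np.ndarray,
    probeset: ProbeSet,
    exclude: np.ndarray | None = None,
) -> int:
    """Neg(x): number of the allele's placements whose probe call is negative.

    ``calls`` is the binarized positive/negative vector over unique probes;
    ``exclude`` optionally masks uninformative probes out of the count.  A
    fully masked absent allele (every probe shared with a present allele)
    yields 0 — the pathology that motivates the later validation flags.
    """
    try:
        pids = probeset.allele_probes[allele]
    except KeyError:
        raise CatalogError(f"allele {allele!r} absent from probe set") from None
    neg = ~calls[pids]
    if exclude is not None:
        neg &= ~exclude[pids]
    return int(neg.sum())


@dataclass
class SerotypeScore:
    serotype: str
    neg_st: float
    allele_negs: dict[str, int]
    k: int
    rank: int | None = None

    @property
    def min_allele_neg(self) -> int:
        return min(self.allele_negs.values())


def serotype_score(serotype: str, allele_negs: dict[str, int], k_mode: str = "min") -> SerotypeScore:
    """Average the k smallest Neg(x) of the serotype's alleles.

    ``k_mode='min'`` uses k = min(5, N) (the five best-supported alleles);
    ``k_mode='max'`` uses k = max(5, N), i.e. a plain mean for N >= 5.
    """
    if not allele_negs:
        raise CatalogError(f"serotype {serotype!r} has no alleles to score")
    n = len(allele_negs)
    if k_mode == "min":
        k = min(5, n)
    elif k_mode == "max":
        k = min(max(5, n), n)  # cannot average more alleles than exist
    else:
        raise CatalogError(f"unknown k_mode {k_mode!r}")
    smallest = sorted(allele_negs.values())[:k]
    return SerotypeScore(serotype, float(sum(smallest)) / k, dict(allele_negs), k)


def rank_serotypes(locus: str, scores: list[SerotypeScore]) -> list[SerotypeScore]:
    """Ascending Neg(ST); ties broken by smaller min Neg(x), then serotype id."""
    ranked = sorted(scores, key=lambda s: (s.neg_st, s.min_allele_neg, s.serotype))
    for i, s in enumerate(ranked):
        s.rank = i + 1
    return ranked


@dataclass
class LocusCall:
    locus: str
    surviving: list[SerotypeScore]
    homozygous_flag: bool = False
    elimination_log: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def surviving_serotypes(self) -> list[str]:
        return [s.serotype for s in self.surviving]


def call_homozygous(ranked: list[SerotypeScore], margin: float = HOMOZYGOUS_MARGIN) -> LocusCall:
    """Keep only ST1 when Neg(ST2) - Neg(ST1) >= margin (inclusive)."""
    if not ranked:
        raise CatalogError("no ranked serotypes")
    locus = ranked[0].serotype.split("*")[0]
    if len(ranked) == 1:
        # a single-serotype locus is trivially a homozygous candidate
        return LocusCall(locus, list(ranked), homozygous_flag=True)
    diff = ranked[1].neg_st - ranked[0].neg_st
    if diff >= margin:
        log = [(s.serotype, "homozygous", diff) for s in ranked[1:]]
        return LocusCall(locus, [ranked[0]], homozygous_flag=True, elimination_log=log)
    return LocusCall(locus, list(ranked))


def eliminate_redundant(
    call: LocusCall,
    max_difference: dict[tuple[str, str], float] | None = None,
    default_max_difference: float = DEFAULT_MAX_DIFFERENCE,
    exempt_pairs: frozenset[frozenset[str]] = frozenset(),
) -> LocusCall:
    """Remove serotypes ranked behind second place with excessive margins.

    ST2 (ranked > 2) is removed when Neg(ST2) - Neg(ST1) exceeds
    MaxDifference(ST1, ST2); pairs listed as never-distinguishable are exempt
    and passed to genotyping.  The top two serotypes are never removed.
    """
    if len(call.surviving) <= 2:
        return call
    ranked = call.surviving
    st1 = ranked[0]
    keep = list(ranked[:2])
    log = list(call.elimination_log)
    for st2 in ranked[2:]:
        pair = frozenset((st1.serotype, st2.serotype))
        if pair in exempt_pairs:
            keep.append(st2)
            continue
        md = default_max_difference
        if max_difference is not None:
            md = max_difference.get((st1.serotype, st2.serotype), default_max_difference)
        margin = st2.neg_st - st1.neg_st
        if margin > md:
            log.append((st2.serotype, "redundant", margin))
        else:
            keep.append(st2)
    return LocusCall(call.locus, keep, call.homozygous_flag, log)


def serotype_locus(
    locus: str,
    allele_negs: dict[str, dict[str, int]],
    homozygous_margin: float = HOMOZYGOUS_MARGIN,
    max_difference: dict[tuple[str, str], float] | None = None,
    default_max_difference: float = DEFAULT_MAX_DIFFERENCE,
    exempt_pairs: frozenset[frozenset[str]] = frozenset(),
    k_mode: str = "min",
) -> LocusCall:
    """Full Stage 1 for one locus: score, rank, homozygosity, elimination.

    ``allele_negs`` maps serotype -> {allele: Neg(x)}.
    """
    scores = [serotype_score(st, negs, k_mode) for st, negs in allele_negs.items()]
    ranked = rank_serotypes(locus, scores)
    call = call_homozygous(ranked, homozygous_margin)
    return eliminate_redundant(call, max_difference, default_max_difference, exempt_pairs)


def locus_allele_negatives(
    locus: str,
    catalog: AlleleCatalog,
    calls: np.ndarray,
    probeset: ProbeSet,
    exclude: np.ndarray | None = None,
) -> dict[str, dict[str, int]]:
    """Neg(x) for every allele of a locus, grouped by serotype."""
    out: dict[str, dict[str, int]] = {}
    for allele in catalog.locus_members(locus):
        out.setdefault(allele.serotype, {})[allele.name] = count_negatives(
            allele.name, calls, probeset, exclude
        )
    return out
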