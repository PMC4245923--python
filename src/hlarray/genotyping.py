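"""Stages 2 and 3: genotype determination and ambiguity removal.

Within each serogroup cluster of surviving serotypes, alleles are compared
pairwise: at every alignment position where two alleles anchor different
probes, the allele with the larger probe signal scores a win, and AvgWins(x)
is the mean win count of x over all opponents in scope.  Together with Neg(x)
these form the comparison vector — the array's signature for that serogroup —
which is either matched against knowledgebase templates or fed to the
knowledge-based rule Weight(x) = AvgWins(x) - Neg(x) > WeightThreshold(x).

When more than two alleles per locus (or more than six overall) survive,
ambiguity removal enumerates candidate genotypes and compares them with the
genotype comparison algorithm: Sig(G, p) sums the covered probe signals of
G's alleles at alignment position p, the larger sum wins the position, and
every genotype scoring within 20 wins of the best is reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import CatalogError, GenotypeError
from .probes import ProbeSet

AMBIGUITY_MARGIN = 20.0
DEFAULT_WEIGHT_THRESHOLD = 0.0
GENOTYPE_ENUMERATION_CAP = 10_000

# genotype: locus -> tuple of allele names (1 = homozygous, 2 = heterozygous)
Genotype = dict[str, tuple[str, ...]]


def _allele_tracks(alleles: list[str], probeset: ProbeSet) -> dict[str, np.ndarray]:
    tracks = {}
    for a in alleles:
        try:
            tracks[a] = probeset.allele_probes[a]
        except KeyError:
            raise CatalogError(f"allele {a!r} absent from probe set") from None
    lengths = {t.size for t in tracks.values()}
    if len(lengths) > 1:
        raise CatalogError(
            "alleles are not mutually aligned (probe tracks of different length); "
            "supply pre-aligned sequences"
        )
    return tracks


def pairwise_wins(x: str, y: str, values: np.ndarray, probeset: ProbeSet) -> tuple[int, int]:
    """Wins(x vs y) and Wins(y vs x) over alignment positions with differing probes."""
    tracks = _allele_tracks([x, y], probeset)
    px, py = tracks[x], tracks[y]
    differ = px != py
    sx, sy = values[px[differ]], values[py[differ]]
    return int(np.sum(sx > sy)), int(np.sum(sy > sx))


def allele_avg_wins(
    alleles: list[str],
    values: np.ndarray,
    probeset: ProbeSet,
) -> dict[str, float]:
    """AvgWins(x): mean of Wins(x vs y) over every opponent y in scope."""
    if len(alleles) == 1:
        return {alleles[0]: 0.0}
    tracks = _allele_tracks(alleles, probeset)
    wins = {a: 0.0 for a in alleles}
    for x, y in itertools.combinations(alleles, 2):
        wx, wy = pairwise_wins(x, y, values, probeset)
        wins[x] += wx
        wins[y] += wy
    n_opp = len(alleles) - 1
    return {a: w / n_opp for a, w in wins.items()}


@dataclass
class ComparisonVector:
    """Signature of the probe signals over one serogroup cluster.

    ``scope`` is 'serogroup' when the cluster holds two or more surviving
    serotypes (vector Vs over all their alleles) and 'serotype' when it holds
    a single serotype (vector Va over that serotype's alleles).  Entries are
    in canonical (sorted allele name) order so vectors are comparable across
    arrays.
    """

    scope: str  # 'serogroup' | 'serotype'
    key: str  # serogroup id
    array_id: str
    alleles: list[str]
    avg_wins: np.ndarray
    negs: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.avg_wins, self.negs]).astype(float)

    def weights(self) -> dict[str, float]:
        return {
            a: float(w - n) for a, w, n in zip(self.alleles, self.avg_wins, self.negs)
        }

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "key": self.key,
            "alleles": list(self.alleles),
            "avg_wins": [float(x) for x in self.avg_wins],
            "negs": [int(x) for x in self.negs],
        }

    @classmethod
    def from_dict(cls, d: dict, array_id: str) -> "ComparisonVector":
        return cls(
            d["scope"],
            d["key"],
            array_id,
            list(d["alleles"]),
            np.array(d["avg_wins"], dtype=float),
            np.array(d["negs"], dtype=float),
        )


def build_comparison_vector(
    serogroup_key: str,
    serotypes: list[str],
    catalog,
    values: np.ndarray,
    probeset: ProbeSet,
    allele_negs: dict[str, int],
    array_id: str = "",
) -> ComparisonVector:
    """Vs over a multi-serotype serogroup, Va over a singleton serogroup."""
    scope = "serogroup" if len(serotypes) >= 2 else "serotype"
    alleles = sorted(
        a.name for st in serotypes for a in catalog.serotype_members(st)
    )
    avg = allele_avg_wins(alleles, values, probeset)
    return ComparisonVector(
        scope,
        serogroup_key,
        array_id,
        alleles,
        np.array([avg[a] for a in alleles]),
        np.array([allele_negs[a] for a in alleles], dtype=float),
    )


def weight_based_selection(
    alleles: list[str],
    avg_wins: dict[str, float],
    negs: dict[str, int],
    weight_thresholds: dict[str, float] | None = None,
    default_threshold: float = DEFAULT_WEIGHT_THRESHOLD,
) -> list[str]:
    """Alleles with Weight(x) = AvgWins(x) - Neg(x) strictly above threshold."""
    selected = []
    for a in alleles:
        thr = default_threshold
        if weight_thresholds is not None and a in weight_thresholds:
            thr = weight_thresholds[a]
        if avg_wins[a] - negs[a] > thr:
            selected.append(a)
    return selected


# ---------------------------------------------------------------------------
# genotype comparison
# ---------------------------------------------------------------------------

def _normalize_genotype(g: Genotype) -> Genotype:
    """Validate shape and reduce to the involved allele set per locus.

    A homozygous locus involves one allele: its probes are summed once, so a
    heterozygous candidate's extra positive probes genuinely outscore it (the
    documented behaviour when a masked decoy competes with a homozygote).
    """
    out: Genotype = {}
    for locus, alleles in g.items():
        uniq = tuple(sorted(set(alleles)))
        if not 1 <= len(uniq) <= 2 or len(tuple(alleles)) > 2:
            raise GenotypeError(f"locus {locus}: a genotype carries at most two alleles")
        out[locus] = uniq
    return out


def _genotype_signal(g: Genotype, values: np.ndarray, probeset: ProbeSet) -> dict[str, np.ndarray]:
    """Sig(G, p) per locus: summed covered-probe signals of the involved alleles."""
    sig: dict[str, np.ndarray] = {}
    for locus, alleles in g.items():
        tracks = _allele_tracks(list(alleles), probeset)
        sig[locus] = sum(values[tracks[a]] for a in alleles)
    return sig


def genotype_wins(
    g1: Genotype,
    g2: Genotype,
    values: np.ndarray,
    probeset: ProbeSet,
) -> tuple[int, int]:
    """Position-wise win counts between two genotypes.

    At each alignment position p the genotype with the larger Sig(G, p) scores
    a win; equal sums score neither.  Returns (Wins(G1 vs G2), Wins(G2 vs G1)).
    """
    n1, n2 = _normalize_genotype(g1), _normalize_genotype(g2)
    if set(n1) != set(n2):
        raise GenotypeError("genotypes cover different locus sets")
    if all(n1[l] == n2[l] for l in n1):
        raise GenotypeError("genotypes have identical allele content")
    s1 = _genotype_signal(n1, values, probeset)
    s2 = _genotype_signal(n2, values, probeset)
    w1 = w2 = 0
    for locus in n1:
        a, b = s1[locus], s2[locus]
        w1 += int(np.sum(a > b))
        w2 += int(np.sum(b > a))
    return w1, w2


@dataclass
class GenotypeCandidate:
    alleles: Genotype
    wins: float
    flags: set[str]
    provenance: str  # 'template-match' | 'knowledge-based'

    def allele_list(self) -> list[str]:
        return [a for locus in sorted(self.alleles) for a in self.alleles[locus]]


def _locus_pairs(cands: list[str]) -> list[tuple[str, ...]]:
    pairs: list[tuple[str, ...]] = [(a,) for a in cands]
    pairs += list(itertools.combinations(cands, 2))
    return pairs


def resolve_ambiguity(
    candidates: dict[str, list[str]],
    values: np.ndarray,
    probeset: ProbeSet,
    margin: float = AMBIGUITY_MARGIN,
    cap: int = GENOTYPE_ENUMERATION_CAP,
) -> list[tuple[Genotype, float]]:
    """Enumerate legal genotypes from candidate alleles and keep the winners.

    Every locus genotype (pair or homozygote) is scored round-robin against
    the other genotypes of the same locus with :func:`genotype_wins`; locus
    genotypes within ``margin`` wins of the locus maximum survive, and the
    reported full genotypes are the cross-locus combinations of survivors
    (loci share no alignment columns, so pairwise genotype wins decompose
    exactly into per-locus sums).  With at most two candidates everywhere and
    at most six overall, the single implied genotype passes through unscored.
    """
    loci = sorted(candidates)
    for locus, cands in candidates.items():
        if not cands:
            raise GenotypeError(f"locus {locus}: no candidate alleles")
    total = sum(len(c) for c in candidates.values())
    if total <= 6 and all(len(c) <= 2 for c in candidates.values()):
        g: Genotype = {l: tuple(sorted(candidates[l])) for l in loci}
        return [(g, 0.0)]

    survivors: dict[str, list[tuple[tuple[str, ...], float]]] = {}
    n_combos = 1
    for locus in loci:
        pairs = _locus_pairs(sorted(candidates[locus]))
        if len(pairs) == 1:
            survivors[locus] = [(pairs[0], 0.0)]
            continue
        wins = np.zeros(len(pairs))
        for i, j in itertools.combinations(range(len(pairs)), 2):
            gi = {locus: pairs[i]}
            gj = {locus: pairs[j]}
            if sorted(_normalize_genotype(gi)[locus]) == sorted(_normalize_genotype(gj)[locus]):
                continue
            wi, wj = genotype_wins(gi, gj, values, probeset)
            wins[i] += wi
            wins[j] += wj
        best = wins.max()
        survivors[locus] = [
            (pairs[i], float(wins[i])) for i in np.argsort(-wins) if wins[i] >= best - margin
        ]
        n_combos *= len(survivors[locus])
        if n_combos > cap:
            raise GenotypeError(
                f"genotype enumeration exceeds cap ({n_combos} > {cap}); "
                "tighten the weight thresholds to shrink the candidate set"
            )
    results: list[tuple[Genotype, float]] = []
    for combo in itertools.product(*(survivors[l] for l in loci)):
        g = {l: pair for l, (pair, _) in zip(loci, combo)}
        results.append((g, float(sum(w for _, w in combo))))
    results.sort(key=lambda gw: -gw[1])
    return results


def frequency_tiebreak(
    genotypes: list[tuple[Genotype, float]],
    freqs: dict[str, float] | None,
    floor: float = 1e-6,
) -> list[tuple[Genotype, float]]:
    """Reorder win-tied genotypes by population plausibility.

    Among reported genotypes, ranks by the product of allele population
    frequencies (descending, stable w.r.t. the wins order); alleles absent
    from the table get a rarity floor.  Without a table the order is
    unchanged.
    """
    if freqs is None or not genotypes:
        return list(genotypes)

    def product(g: Genotype) -> float:
        p = 1.0
        for alleles in g.values():
            for a in alleles:
                p *= freqs.get(a, floor)
        return p

    return sorted(genotypes, key=lambda gw: -product(gw[0]))
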