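"""Template knowledgebase: storage, matching, and empirical tables.

Every confirmed typing contributes a template: the array's normalized signal
vector, its serotype composition, its per-serogroup comparison vectors and
the validated genotype.  New arrays are first compared against the templates
whole-array: a Pearson correlation above 0.975 together with zero serotype
mismatches establishes identity with the template (the query inherits its
genotype); r > 0.95 with zero mismatches is still a match; high correlation
with serotype mismatches is rejected — reproducing the decision rule that all
true repeat pairs had zero serotype mismatches while mismatched pairs had
2-12.  As templates accumulate, per-probe positivity thresholds, per-allele
weight thresholds and the MaxNeg / MaxDifference serotype tables are
re-derived empirically from the stored data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ComparisonError, IncompatibilityError
from .genotyping import ComparisonVector, Genotype
from .probes import ProbeSet
from .signals import (
    ArraySignals,
    ThresholdTable,
    array_correlation,
    compute_thresholds,
)

R_IDENTITY = 0.975
R_MATCH = 0.95
TOP_N_TEMPLATES = 5


def serotype_mismatch_count(calls_a: dict[str, set[str]], calls_b: dict[str, set[str]]) -> int:
    """Sum over loci of the symmetric difference of serotype sets.

    0 iff both arrays carry the same serotype composition; two fully disjoint
    three-locus heterozygotes reach the maximum of 12.
    """
    if set(calls_a) != set(calls_b):
        raise ComparisonError(
            f"locus sets differ: {sorted(calls_a)} vs {sorted(calls_b)}"
        )
    return sum(len(set(calls_a[l]) ^ set(calls_b[l])) for l in calls_a)


def _genotype_serotypes(genotype: Genotype) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for locus, alleles in genotype.items():
        out[locus] = {a.rsplit(":", 1)[0] for a in alleles}
    return out


@dataclass
class Template:
    """A typed array stored for matching."""

    array_id: str
    genotype: Genotype
    signal: ArraySignals  # normalized stage
    vectors: list[ComparisonVector] = field(default_factory=list)
    serotype_scores: dict[str, float] = field(default_factory=dict)  # serotype -> Neg(ST)
    metadata: dict = field(default_factory=dict)

    @property
    def serotypes(self) -> dict[str, set[str]]:
        return _genotype_serotypes(self.genotype)

    def present_alleles(self) -> set[str]:
        return {a for alleles in self.genotype.values() for a in alleles}


@dataclass
class MatchDecision:
    kind: str  # 'identity' | 'match' | 'none'
    template_id: str | None = None
    r: float | None = None
    mismatches: int | None = None
    correlations: list[tuple[str, float]] = field(default_factory=list)


class Knowledgebase:
    """Templates bound to one probe design, with derived empirical tables."""

    def __init__(self, probeset_fingerprint: str):
        self.probeset_fingerprint = probeset_fingerprint
        self.templates: list[Template] = []

    def __len__(self) -> int:
        return len(self.templates)

    # -- growth ----------------------------------------------------------
    def add_template(
        self,
        array: ArraySignals,
        genotype: Genotype,
        probeset: ProbeSet | None = None,
        vectors: list[ComparisonVector] | None = None,
        serotype_scores: dict[str, float] | None = None,
        flags: set[str] | None = None,
        metadata: dict | None = None,
    ) -> "Knowledgebase":
        """Append a validated typing; idempotent for identical (id, genotype)."""
        if probeset is not None and probeset.fingerprint != self.probeset_fingerprint:
            raise IncompatibilityError(
                "array was processed with a different probe design than this knowledgebase"
            )
        if flags:
            raise IncompatibilityError(
                f"template {array.array_id!r} carries unresolved validation flags: {sorted(flags)}"
            )
        for t in self.templates:
            if t.array_id == array.array_id:
                if t.genotype == genotype:
                    return self  # idempotent re-add
                raise IncompatibilityError(
                    f"array id {array.array_id!r} already stored with a different genotype"
                )
        self.templates.append(
            Template(
                array.array_id,
                {l: tuple(a) for l, a in genotype.items()},
                array,
                list(vectors or []),
                dict(serotype_scores or {}),
                dict(metadata or {}),
            )
        )
        return self

    # -- matching --------------------------------------------------------
    def match_template(
        self,
        query: ArraySignals,
        serotype_calls: dict[str, set[str]],
        r_identity: float = R_IDENTITY,
        r_match: float = R_MATCH,
        log: bool = False,
    ) -> MatchDecision:
        """Whole-array template matching (correlation + serotype mismatches)."""
        if not self.templates:
            return MatchDecision("none")
        scored = []
        for t in self.templates:
            r = array_correlation(query, t.signal, log=log)
            scored.append((r, t))
        scored.sort(key=lambda rt: -rt[0])
        correlations = [(t.array_id, r) for r, t in scored]
        for r, t in scored:
            if r <= r_match:
                break
            try:
                mm = serotype_mismatch_count(serotype_calls, t.serotypes)
            except ComparisonError:
                continue
            if mm == 0:
                kind = "identity" if r > r_identity else "match"
                return MatchDecision(kind, t.array_id, r, mm, correlations)
        best_r, best_t = scored[0]
        try:
            best_mm = serotype_mismatch_count(serotype_calls, best_t.serotypes)
        except ComparisonError:
            best_mm = None
        return MatchDecision("none", best_t.array_id, best_r, best_mm, correlations)

    def allele_lookup(
        self,
        vector: ComparisonVector,
        top_n: int = TOP_N_TEMPLATES,
    ) -> tuple[set[str], list[tuple[str, float]]]:
        """Candidate alleles from the top-N correlated templates of same scope.

        Templates whose stored vector covers the same serogroup and allele set
        are ranked by Pearson correlation of the comparison vectors; an allele
        is a candidate iff it is a present allele of at least one of the top N
        templates.  A query of an absent serotype tends to match templates
        containing none of its alleles, yielding an empty candidate set.
        """
        scored: list[tuple[float, Template]] = []
        q = vector.vector
        for t in self.templates:
            for tv in t.vectors:
                if tv.key != vector.key or tv.alleles != vector.alleles:
                    continue
                v = tv.vector
                if np.std(q) == 0 or np.std(v) == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(q, v)[0, 1])
                scored.append((r, t))
        scored.sort(key=lambda rt: -rt[0])
        top = scored[:top_n]
        in_scope = set(vector.alleles)
        candidates: set[str] = set()
        for _, t in top:
            candidates |= t.present_alleles() & in_scope
        return candidates, [(t.array_id, r) for r, t in top]

    # -- empirical tables ------------------------------------------------
    def empirical_thresholds(self, probeset: ProbeSet) -> ThresholdTable:
        return compute_thresholds([t.signal for t in self.templates], probeset)

    def weight_thresholds(self, default: float = 0.0) -> dict[str, float]:
        """Per-allele WeightThreshold(x): midpoint of present/absent Weight modes."""
        present: dict[str, list[float]] = {}
        absent: dict[str, list[float]] = {}
        for t in self.templates:
            truth = t.present_alleles()
            for v in t.vectors:
                for a, w in v.weights().items():
                    (present if a in truth else absent).setdefault(a, []).append(w)
        out: dict[str, float] = {}
        for a in set(present) | set(absent):
            if a in present and a in absent:
                lo, hi = max(absent[a]), min(present[a])
                out[a] = (lo + hi) / 2.0 if lo < hi else default
            else:
                out[a] = default
        return out

    def max_neg(self) -> dict[str, float]:
        """MaxNeg(ST): maximal observed Neg(ST) among templates where ST is present."""
        out: dict[str, float] = {}
        for t in self.templates:
            present = {st for sts in t.serotypes.values() for st in sts}
            for st, neg in t.serotype_scores.items():
                if st in present:
                    out[st] = max(out.get(st, -np.inf), neg)
        return out

    def max_difference_default(self, fallback: float = 30.0) -> float:
        """Global MaxDifference: minimum observed present/absent Neg(ST) margin."""
        margins = []
        for t in self.templates:
            present = {st for sts in t.serotypes.values() for st in sts}
            by_locus: dict[str, list[tuple[str, float]]] = {}
            for st, neg in t.serotype_scores.items():
                by_locus.setdefault(st.split("*")[0], []).append((st, neg))
            for locus, entries in by_locus.items():
                p = [n for st, n in entries if st in present]
                a = [n for st, n in entries if st not in present]
                if p and a:
                    margins.append(min(a) - max(p))
        return float(min(margins)) if margins else fallback

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        """Write kb.json + a dense signals.tsv (probe x template matrix)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        doc = {
            "probeset_fingerprint": self.probeset_fingerprint,
            "templates": [
                {
                    "array_id": t.array_id,
                    "genotype": {l: list(a) for l, a in sorted(t.genotype.items())},
                    "serotype_scores": {k: t.serotype_scores[k] for k in sorted(t.serotype_scores)},
                    "vectors": [v.to_dict() for v in t.vectors],
                    "metadata": t.metadata,
                }
                for t in self.templates
            ],
        }
        (directory / "kb.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
        if self.templates:
            mat = pd.DataFrame(
                {t.array_id: t.signal.values for t in self.templates}
            )
            mat.insert(0, "probe_id", np.arange(len(mat)))
            # %.17g guarantees bit-exact float round-trip through the TSV
            mat.to_csv(directory / "signals.tsv", sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, directory) -> "Knowledgebase":
        directory = Path(directory)
        doc = json.loads((directory / "kb.json").read_text())
        kb = cls(doc["probeset_fingerprint"])
        signals = None
        sig_path = directory / "signals.tsv"
        if sig_path.exists():
            signals = pd.read_csv(
                sig_path, sep="\t", float_precision="round_trip"
            ).set_index("probe_id")
        for td in doc["templates"]:
            aid = td["array_id"]
            values = signals[aid].to_numpy() if signals is not None else np.empty(0)
            kb.templates.append(
                Template(
                    aid,
                    {l: tuple(a) for l, a in td["genotype"].items()},
                    ArraySignals(aid, "normalized", values),
                    [ComparisonVector.from_dict(vd, aid) for vd in td["vectors"]],
                    dict(td["serotype_scores"]),
                    dict(td.get("metadata", {})),
                )
            )
        return kb
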